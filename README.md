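# pxdscout

Candidate-variant discovery for an autosomal-recessive disease from a small
number of affected whole-genome sequences — the strategy that mapped a canine
paroxysmal dyskinesia in Soft-Coated Wheaten Terriers to a homozygous *PIGN*
missense variant (c.398C>T, p.T133I).

The package is for geneticists working on Mendelian traits in inbred
populations (dog breeds being the canonical example) who have one or a few
affected genomes, a growing collection of control genomes, and a genotyping
cohort for validation. It provides, as a tested library plus a thin CLI:

1. **Consequence annotation** — strand-aware CDS coordinate mapping, codon
   translation under the standard genetic code, splice-signal detection, and
   compact HGVS c./p. nomenclature.
2. **Homozygosity filtering** — an embedded multi-genome variant store and
   the three candidate-causality criteria: a variant is retained iff it is
   (i) predicted to alter the amino-acid sequence of a gene product
   (splice-signal variants included), (ii) homozygous for the alternate
   allele in the affected genome, and (iii) absent, at any zygosity, from
   every control genome.
3. **Cross-case intersection** — candidates from independent affected
   genomes intersected on (contig, pos, ref, alt), plus the candidate-count
   *trajectory* as controls accumulate (non-increasing by construction).
4. **Cohort genotyping** — an angle-space cluster caller for two-channel
   endpoint fluorescence (allelic-discrimination assays), recessive
   segregation checks per breed stratum, the control allele frequency
   (2·hom_alt + het)/(2n), and an exact two-sided Fisher test of hom_alt vs.
   rest against affected vs. unaffected.
5. **Conservation** — residue composition of an ortholog-alignment column at
   the focal codon and the set of evolutionarily tolerated residues.
6. **Synthetic studies** — a seeded generator producing every input the
   pipeline consumes (reference FASTA, BED12 gene models, per-genome VCFs,
   cohort and fluorescence TSVs, aligned FASTA) with a planted causal
   variant and a truth manifest, so the whole analysis is testable without
   any sequence download.

## Worked example

Generate a synthetic study (two affected genomes, twenty controls, a few
hundred background variants each, a planted homozygous missense variant) and
run the full analysis:

```sh
pxdscout simulate --seed 5 --out study
pxdscout run --config study/config.yaml
```

which prints:

```
pxdscout run summary
====================

control genomes in store: 20
case case1: 573 variants -> 3 candidates in 2 genes
case case2: 563 variants -> 2 candidates in 2 genes
trajectory (first case): 165 128 105 88 71 54 45 36 28 20 17 15 12 10 10 5 5 4 4 3
variants common to all cases: 1
  chr1:11443 G>A gene016 missense c.398C>T p.T133I
segregation: consistent_recessive=True fisher_p=2.35742e-16 control allele freq=0.009375
conservation column: S:2 T:146 (gaps 0)
  variant residue I: never observed across species
```

Reading the output: each case's variants collapse to a handful of candidates
under the three criteria; the trajectory shows the candidate count shrinking
as each control genome joins the store (165 with one control, 3 with all
twenty); the only variant common to both cases is the planted one — a G>A
substitution that, on the coding strand of `gene016`, is c.398C>T and turns
codon 133 from ACC (threonine) into ATC (isoleucine), hence p.T133I. The
genotyping cohort segregates consistently with recessive inheritance (every
affected sample homozygous alternate, no unaffected one), and the ortholog
column shows only threonine (146 species) and serine (2 species) — the
variant residue isoleucine has never been observed.

Individual stages are available as `annotate`, `filter`, `intersect`,
`trajectory`, `genotype-call`, `segregation` and `conserve` subcommands, and
as plain library functions (`pxdscout.filter_candidates`,
`pxdscout.segregation_check`, ...).

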