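# Methods

## The discovery model

The pipeline assumes a fully penetrant autosomal-recessive trait in a closed
breeding population. Under that model the causal variant must be homozygous
for the alternate allele in every affected genome, and — if it is rare and
breed-private — absent from unrelated control genomes. Combined with the
requirement that a causal variant plausibly damages a gene product, this
yields the three filter criteria applied to each affected genome's calls:

1. amino-acid-altering consequence (missense, nonsense, stop-loss,
   frameshift, in-frame indel, or disruption of a splice signal);
2. homozygous-alternate genotype in the affected genome;
3. no observation, at any zygosity, in any control genome.

Criterion 3 deliberately treats heterozygous control observations as
disqualifying: under strict recessive inheritance controls may carry one
copy, but a variant seen in controls at appreciable frequency is unlikely to
be the breed-private causal allele, and the strictest reading makes the
filter monotone in the control set. Candidates from independent cases are
then intersected on the normalized key (contig, pos, ref, alt). Missing
genotype calls in a case VCF are excluded (logged), i.e. treated as not
homozygous. No quality gate is applied by default; upstream error correction
is assumed done.

Both the filter and the trajectory are monotone: adding a control genome can
only remove candidates, so the candidate count as controls accumulate is
non-increasing and the final set is independent of insertion order. The
control store is an embedded in-memory index (variant key → observing
genomes) persistable to JSON; no database server is involved.

## Consequence annotation

Genomic positions are 1-based in all I/O (VCF convention); internal
intervals are 0-based half-open (BED convention). One transcript model per
gene: ordered exons plus genomic CDS bounds. Coding positions count along
the coding strand, so `genomic_to_cds` and `cds_to_genomic` are exact
inverses on the CDS for both strands; codon index and offset are
`((cds_pos − 1) // 3) + 1` and `((cds_pos − 1) mod 3) + 1`.

Substitutions in the CDS are translated codon-wise with the standard genetic
code (Biopython); there is no special handling of start-codon gain/loss —
such variants are classified by their codon effect. Length-changing variants
touching the CDS are frameshift unless the length difference is a multiple
of three (in-frame indel). Intronic substitutions within `splice_window`
bases of an exon boundary are splice_donor on the 5′ side of the intron and
splice_acceptor on the 3′ side, in transcription direction; the window
defaults to the two canonical intronic bases (GT/AG positions) and is
configurable because "splice signal" has no single universal extent.
Multi-allelic VCF records are decomposed and left-normalized (shared-flank
trimming plus left-shifting of indels through repeat tracts) before
annotation, so variant identity is well defined; indels are supported for
filtering completeness, with simplified HGVS (`c.<pos>del`, `p.<codon>fs`).
HGVS protein output uses one-letter codes by default (`p.T133I`) with a
three-letter option (`p.Thr133Ile`).

## Genotype calling from endpoint fluorescence

Allelic-discrimination assays report two endpoint intensities per sample:
a reference-allele probe channel and a variant-allele probe channel.
Genotype clusters separate by the angle of the intensity vector —
homozygous-reference near 0°, heterozygous near 45°, homozygous-variant near
90° — so the caller runs a small k-means in angle space seeded at those
canonical angles (at most three clusters; empty clusters keep their seed).
Samples are left uncalled when their total intensity falls below
`min_total_frac` (default 0.1) of the cohort median total (failed
amplification) or their angle lies more than `max_angle_dev` (default 20°)
from the nearest cluster centre. Both thresholds are relative, so calls are
invariant to uniform rescaling of both channels. At the 5–10 % channel noise
typical of endpoint reads the clusters are separated by ≥ 40° against an
angular spread of ≈ 6°, which is why accuracy stays above 99 %.

Segregation is tabulated per breed stratum (free-text labels; crossbred
samples such as Whoodles are ordinary rows — no pedigree inference).
Recessive consistency means no called affected sample lacking the hom_alt
genotype and no unaffected hom_alt. The control allele frequency is
(2·hom_alt + het) / (2·n called controls), reported per stratum and pooled.
Association uses the recessive coding (hom_alt vs. rest × affected vs.
unaffected) and a two-sided Fisher exact test computed by exact integer
hypergeometric summation over the fixed-margins distribution: every table
probability is a ratio of binomial coefficients, and the two-sided tail sums
those not exceeding the observed table's probability. Because the arithmetic
is exact there is no tie-tolerance parameter; the test suite checks the
implementation against an exhaustive fixed-margins enumeration in rational
arithmetic (all tables with n ≤ 60) and against scipy on random tables. A
degenerate margin gives p = 1. Only one pre-specified site is ever tested,
so no multiple-testing correction is applied.

## Conservation

Input is a pre-computed ortholog residue alignment (aligned FASTA) and a
focal column mapped to the codon of interest; the package does not build
alignments. Residues are counted case-insensitively at the column, gaps
(`-`, `.`) tallied separately; the tolerated set is the residues with count
≥ `min_count` (default 1, i.e. "ever observed"), monotone non-increasing in
the threshold. A variant amino acid outside the tolerated set is flagged as
never observed across the aligned species. No phylogenetic weighting or
substitution-matrix scoring is attempted.

## The synthetic-data generator

The generator emulates the discovery design so all stages run without
downloads. Defaults describe a realistic desk-scale study:

- **Reference and genes** — 2 contigs × 50 kb; 30 non-overlapping genes of
  3 exons, 900 bp CDS (300 codons), 120 bp introns, random strand. The CDS
  coincides with the exons (no UTRs by default; UTR handling is exercised by
  unit fixtures).
- **Planted causal variant** — one gene drawn at random receives the codon
  ACC at codon 133; the planted substitution is C>T at codon offset 2
  (coding strand), i.e. c.398C>T, ACC→ATC, p.T133I — the worked example's
  geometry. The variant is written homozygous-alternate into every case and
  into no control.
- **Background variation** — pools of coding hom-alt, coding het and
  non-coding hom-alt variants placed uniformly over CDS / non-exonic
  positions (avoiding the planted codon). Each pool variant gets a founder
  genome plus each other genome independently with probability
  `p_share` = 0.15; pool sizes are chosen so expected per-genome counts hit
  the configured rates (150 het coding, 250 hom coding, 150 hom non-coding —
  several hundred variants per genome). With `guarantee_recovery` (default)
  any hom-alt coding variant that lands in every case but no control is
  forced into one random control, making the filter-and-intersect outcome
  exactly the planted variant; switching it off allows ambiguous studies.
- **Cohort** — genotype counts are exact partitions of the configured
  per-breed sizes (not Bernoulli draws), so printed cohort compositions are
  reproduced without sampling error. `generate_paper_like_cohort` emits the
  published-scale validation cohort: 25 affected homozygotes (22 SCWT + 3
  Whoodles), 682 SCWT controls (15 het / 667 hom-ref), 388 Poodles and 132
  other-breed dogs, 1227 samples. (The source reports 665 archived
  disease-free SCWT in one place and 682 genotyped SCWT controls in another;
  the genotyping-section counts 682/15/667 are used here.) Fluorescence is
  drawn from cluster centres (1000, 60) / (700, 700) / (60, 1000) with
  Gaussian channel noise of sd = noise_sd × 1000 (default 5 %), truncated at
  zero.
- **Alignment** — a 15-column alignment whose focal column carries the
  configured composition (default 146 T + 2 S) in permuted row order, with
  broadly conserved flanking columns (5 % per-species substitutions).

A single `numpy` Generator seeded from the scenario seed drives everything;
identical seeds give byte-identical files. What the generator does *not*
emulate: sequencing error and false-positive calls (every written variant is
real), linkage disequilibrium and haplotype structure, population allele
frequencies, indel-rich repeat regions, transcript isoforms, and assay
artefacts beyond symmetric Gaussian noise. Passing tests therefore
demonstrate the logic of the filter, caller and statistics — not robustness
to upstream calling noise, which the original study handled by adding
control genomes and by Sanger confirmation.

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale by design: recovery
is demonstrated over 50 seeded studies of 22 genomes × ~550 variants each
(the published discovery operated on millions of variants per genome — the
logic is identical, the store merely larger); the Fisher implementation is
swept against the exhaustive oracle for every 2×2 table with n ≤ 60; caller
accuracy is averaged over 1000 cohorts of 200 samples. Reports print floats
to six significant digits in stable key order so repeated runs are
byte-identical. Degenerate inputs are defined: empty control store (filter
criterion 3 vacuous), zero controls (empty trajectory), all-zero
fluorescence (all no_call with a warning), all-gap alignment columns (empty
composition, gaps reported), degenerate Fisher margins (p = 1).

## Known limitations

- One transcript model per gene; no isoform resolution, no regulatory
  annotation, no protein-impact scores.
- No compound-heterozygous mode: the inheritance model is strictly
  homozygous-recessive.
- Splice-signal extent is a simple ±k intronic window, not a motif model.
- The caller assumes three angularly separated clusters; assays with allele
  dropout or extreme cluster rotation would need re-seeding.
- The conservation module counts residues; it does not weight by phylogeny,
  so dense clades inflate apparent constraint.
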