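"""Seeded synthetic study generator.

Emulates the discovery design end to end: a small reference assembly with
non-overlapping multi-exon gene models; affected ("case") genomes carrying a
planted homozygous missense variant that no control genome carries;
background variants shared between genomes under a configurable sharing
model; a breed-stratified genotyping cohort with two-channel endpoint
fluorescence drawn from the genotype clusters; and an ortholog alignment
column with controlled residue composition.  Everything derives from one
integer seed, and identical seeds yield byte-identical files.

Defaults mirror the study conditions: two affected genomes, twenty control
genomes, a few hundred background variants per genome, a planted codon-133
Thr->Ile substitution (ACC->ATC), and an alignment column of 146 threonines
plus 2 serines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .annotate import Consequence, ConsequenceCall, classify_variant, cds_to_genomic
from .conservation import OrthologAlignment
from .filtering import GenomeObservation, Zygosity
from .genome import (COMPLEMENT, GeneIndex, GeneModel, InputError,
                     ReferenceAssembly, Variant)
from . import io as pxio

BASES = np.array(list("ACGT"))

#: endpoint-fluorescence cluster centres (reference channel, variant channel)
FLUORESCENCE_CENTERS = {
    "hom_ref": (1000.0, 60.0),
    "het": (700.0, 700.0),
    "hom_alt": (60.0, 1000.0),
}

DEFAULT_COHORT: Dict[str, Dict[str, int]] = {
    # breed -> counts; affected samples are homozygous for the variant allele
    "SCWT": {"affected_hom_alt": 10, "unaffected_het": 3, "unaffected_hom_ref": 97},
    "Poodle": {"unaffected_hom_ref": 40},
    "other": {"unaffected_hom_ref": 20},
}

DEFAULT_ALIGNMENT_COMPOSITION: Dict[str, int] = {"T": 146, "S": 2}


@dataclass
class SyntheticScenario:
    """Full specification of one synthetic study; all randomness from ``seed``."""

    seed: int = 42
    # reference + gene models
    n_contigs: int = 2
    contig_length: int = 50_000
    n_genes: int = 30
    exons_per_gene: int = 3
    cds_length: int = 900
    intron_length: int = 120
    gene_gap: int = 200
    # planted recessive causal variant (coding-strand codon notation)
    causal_codon_index: int = 133
    causal_codon_offset: int = 2
    causal_ref_codon: str = "ACC"   # Thr
    causal_alt_base: str = "T"      # ACC -> ATC = Ile (missense)
    # genomes
    n_cases: int = 2
    n_controls: int = 20
    het_coding_per_genome: float = 150.0
    hom_coding_per_genome: float = 250.0
    hom_noncoding_per_genome: float = 150.0
    p_share: float = 0.15
    guarantee_recovery: bool = True
    # cohort + fluorescence
    cohort_spec: Dict[str, Dict[str, int]] = field(
        default_factory=lambda: {b: dict(v) for b, v in DEFAULT_COHORT.items()}
    )
    fluorescence_noise_sd: float = 0.05
    # ortholog alignment
    alignment_composition: Dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_ALIGNMENT_COMPOSITION)
    )
    alignment_width: int = 15
    alignment_focal_column: int = 8

    def validate(self) -> None:
        if self.cds_length % 3 != 0:
            raise InputError("cds_length must be a multiple of 3")
        if self.cds_length < 3 * self.causal_codon_index:
            raise InputError(
                f"cds_length {self.cds_length} too short for planted codon "
                f"{self.causal_codon_index}"
            )
        if self.causal_codon_offset not in (1, 2, 3):
            raise InputError("causal_codon_offset must be 1, 2 or 3")
        if len(self.causal_ref_codon) != 3:
            raise InputError("causal_ref_codon must be a codon")
        if self.causal_ref_codon[self.causal_codon_offset - 1] == self.causal_alt_base:
            raise InputError("causal alt base equals the reference codon base")
        if not 0 <= self.p_share <= 1:
            raise InputError("p_share must be in [0, 1]")
        if self.n_cases < 1:
            raise InputError("need at least one case genome")


@dataclass
class ScenarioBundle:
    """In-memory result of one generation run plus its truth manifest."""

    scenario: SyntheticScenario
    assembly: ReferenceAssembly
    genes: List[GeneModel]
    causal_variant: Variant
    causal_call: ConsequenceCall
    causal_gene: GeneModel
    cases: List[GenomeObservation]
    controls: List[GenomeObservation]
    cohort: pd.DataFrame          # sample_id, breed, phenotype, genotype (truth),
                                  # channel_ref, channel_alt
    alignment: OrthologAlignment
    truth_variants: pd.DataFrame  # genome_id, contig, pos, ref, alt, zygosity, is_causal
    proteins: Dict[str, str] = field(default_factory=dict)  # gene_id -> translated CDS

    @property
    def gene_index(self) -> GeneIndex:
        return GeneIndex(self.genes)


# ---------------------------------------------------------------------------

def _build_assembly_and_genes(s: SyntheticScenario, rng: np.random.Generator
                              ) -> Tuple[List[List[str]], List[GeneModel]]:
    contigs = [
        list(rng.choice(BASES, size=s.contig_length))
        for _ in range(s.n_contigs)
    ]
    exon_size = s.cds_length // s.exons_per_gene
    sizes = [exon_size] * (s.exons_per_gene - 1)
    sizes.append(s.cds_length - sum(sizes))
    footprint = s.cds_length + (s.exons_per_gene - 1) * s.intron_length
    genes: List[GeneModel] = []
    cursors = [100] * s.n_contigs
    for i in range(s.n_genes):
        ci = i % s.n_contigs
        start = cursors[ci]
        if start + footprint + 100 > s.contig_length:
            raise InputError(
                "contig_length too small for the requested gene count/layout"
            )
        exons = []
        pos = start
        for sz in sizes:
            exons.append((pos, pos + sz))
            pos += sz + s.intron_length
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(f"gene{i:03d}", f"chr{ci + 1}", strand, tuple(exons),
                      exons[0][0], exons[-1][1])
        )
        cursors[ci] = start + footprint + s.gene_gap
    return contigs, genes


def _plant_causal(s: SyntheticScenario, rng: np.random.Generator,
                  contigs: List[List[str]], genes: List[GeneModel]
                  ) -> Tuple[GeneModel, Variant]:
    gene = genes[int(rng.integers(len(genes)))]
    ci = int(gene.contig.removeprefix("chr")) - 1
    cds_base = 3 * (s.causal_codon_index - 1)
    # write the reference codon into the assembly (coding strand)
    for off in range(3):
        gpos = cds_to_genomic(gene, cds_base + off + 1)  # 1-based genomic
        base = s.causal_ref_codon[off]
        if gene.strand == "-":
            base = base.translate(COMPLEMENT)
        contigs[ci][gpos - 1] = base
    cds_pos = cds_base + s.causal_codon_offset
    gpos = cds_to_genomic(gene, cds_pos)
    ref = s.causal_ref_codon[s.causal_codon_offset - 1]
    alt = s.causal_alt_base
    if gene.strand == "-":
        ref = ref.translate(COMPLEMENT)
        alt = alt.translate(COMPLEMENT)
    return gene, Variant(gene.contig, gpos, ref, alt)


def _coding_positions(genes: Sequence[GeneModel]) -> List[Tuple[str, int]]:
    out = []
    for g in genes:
        for cs, ce in g.cds_intervals:
            out.extend((g.contig, p + 1) for p in range(cs, ce))
    return out


def _noncoding_positions(s: SyntheticScenario, genes: Sequence[GeneModel]) -> List[Tuple[str, int]]:
    exonic: Dict[str, set] = {f"chr{i + 1}": set() for i in range(s.n_contigs)}
    for g in genes:
        for es, ee in g.exons:
            exonic[g.contig].update(range(es, ee))
    out = []
    for i in range(s.n_contigs):
        name = f"chr{i + 1}"
        ex = exonic[name]
        out.extend((name, p + 1) for p in range(s.contig_length) if p not in ex)
    return out


def _pool_size(expected_per_genome: float, n_genomes: int, p_share: float) -> int:
    mean_carriers = 1.0 + (n_genomes - 1) * p_share
    return max(0, round(expected_per_genome * n_genomes / mean_carriers))


def _assign_carriers(rng: np.random.Generator, n_pool: int, n_genomes: int,
                     p_share: float) -> List[np.ndarray]:
    """For each pool variant: indices of carrier genomes (founder + shared)."""
    out = []
    for _ in range(n_pool):
        founder = int(rng.integers(n_genomes))
        carriers = {founder}
        shared = rng.random(n_genomes) < p_share
        carriers.update(int(i) for i in np.flatnonzero(shared))
        out.append(np.array(sorted(carriers)))
    return out


def _draw_variants(rng: np.random.Generator, contigs: Mapping[str, str],
                   positions: List[Tuple[str, int]], n: int,
                   forbidden: set) -> List[Variant]:
    usable = [i for i, cp in enumerate(positions) if cp not in forbidden]
    if n > len(usable):
        raise InputError("not enough sites for the requested background variant pool")
    chosen = rng.choice(len(usable), size=n, replace=False)
    variants = []
    for idx in sorted(int(c) for c in chosen):
        contig, pos = positions[usable[idx]]
        ref = contigs[contig][pos - 1]
        alt = str(rng.choice(BASES[BASES != ref]))
        variants.append(Variant(contig, pos, ref, alt))
    return variants


def generate_scenario(scenario: SyntheticScenario) -> ScenarioBundle:
    """Generate the full synthetic study described by ``scenario``.

    The planted causal variant is homozygous-alternate in every case genome,
    absent from every control genome, and missense under the generated gene
    model.  With ``guarantee_recovery`` any background homozygous coding
    variant shared by all cases is forced into at least one control, so the
    filter-and-intersect pipeline recovers exactly the planted variant.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    contig_lists, genes = _build_assembly_and_genes(scenario, rng)
    causal_gene, causal_variant = _plant_causal(scenario, rng, contig_lists, genes)
    contigs = {f"chr{i + 1}": "".join(c) for i, c in enumerate(contig_lists)}
    assembly = ReferenceAssembly(contigs)
    causal_call = classify_variant(assembly, causal_gene, causal_variant)
    assert causal_call.category is Consequence.MISSENSE, "planted variant must be missense"

    n_genomes = scenario.n_cases + scenario.n_controls
    genome_ids = [f"case{i + 1}" for i in range(scenario.n_cases)] + [
        f"control{i + 1:02d}" for i in range(scenario.n_controls)
    ]
    roles = ["case"] * scenario.n_cases + ["control"] * scenario.n_controls

    coding_sites = _coding_positions(genes)
    noncoding_sites = _noncoding_positions(scenario, genes)
    causal_codon_sites = {
        (causal_gene.contig,
         cds_to_genomic(causal_gene, 3 * (scenario.causal_codon_index - 1) + o + 1))
        for o in range(3)
    }

    n_hom_coding = _pool_size(scenario.hom_coding_per_genome, n_genomes, scenario.p_share)
    n_het_coding = _pool_size(scenario.het_coding_per_genome, n_genomes, scenario.p_share)
    n_hom_noncod = _pool_size(scenario.hom_noncoding_per_genome, n_genomes, scenario.p_share)

    coding_pool = _draw_variants(
        rng, contigs, coding_sites, n_hom_coding + n_het_coding, causal_codon_sites
    )
    hom_coding_pool = coding_pool[:n_hom_coding]
    het_coding_pool = coding_pool[n_hom_coding:]
    noncod_pool = _draw_variants(rng, contigs, noncoding_sites, n_hom_noncod, set())

    calls: List[Dict[Variant, Zygosity]] = [dict() for _ in range(n_genomes)]
    case_idx = set(range(scenario.n_cases))
    control_idx = list(range(scenario.n_cases, n_genomes))

    for pool, zyg in ((hom_coding_pool, Zygosity.HOM_ALT),
                      (het_coding_pool, Zygosity.HET),
                      (noncod_pool, Zygosity.HOM_ALT)):
        carriers = _assign_carriers(rng, len(pool), n_genomes, scenario.p_share)
        for v, carr in zip(pool, carriers):
            carr_set = set(int(i) for i in carr)
            if (scenario.guarantee_recovery and zyg is Zygosity.HOM_ALT
                    and case_idx <= carr_set and not (carr_set - case_idx)
                    and control_idx):
                # shared by every case but absent from controls: would mimic the
                # causal variant, so force one control to carry it
                carr_set.add(int(rng.choice(control_idx)))
            for gi in carr_set:
                calls[gi][v] = zyg

    for gi in case_idx:
        calls[gi][causal_variant] = Zygosity.HOM_ALT

    observations = [
        GenomeObservation(gid, role, c)
        for gid, role, c in zip(genome_ids, roles, calls)
    ]
    cases = observations[: scenario.n_cases]
    controls = observations[scenario.n_cases:]

    cohort = _generate_cohort(scenario.cohort_spec, rng, scenario.fluorescence_noise_sd)
    alignment = _generate_alignment(scenario, rng)
    truth = _truth_frame(observations, causal_variant)
    return ScenarioBundle(
        scenario=scenario, assembly=assembly, genes=genes,
        causal_variant=causal_variant, causal_call=causal_call,
        causal_gene=causal_gene, cases=cases, controls=controls,
        cohort=cohort, alignment=alignment, truth_variants=truth,
        proteins={g.gene_id: g.protein(assembly) for g in genes},
    )


def _truth_frame(observations: Sequence[GenomeObservation],
                 causal: Variant) -> pd.DataFrame:
    rows = []
    for obs in observations:
        for v in sorted(obs.calls):
            rows.append(
                {
                    "genome_id": obs.genome_id, "role": obs.role,
                    "contig": v.contig, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                    "zygosity": obs.calls[v].value,
                    "is_causal": int(v == causal),
                }
            )
    return pd.DataFrame(
        rows, columns=["genome_id", "role", "contig", "pos", "ref", "alt",
                       "zygosity", "is_causal"]
    )


# ---------------------------------------------------------------------------
# cohort + fluorescence

def fluorescence_from_genotypes(genotypes: Sequence[str], rng: np.random.Generator,
                                noise_sd: float) -> np.ndarray:
    """Two-channel endpoint intensities for true genotypes.

    Gaussian noise with standard deviation ``noise_sd`` times the full signal
    (1000 units) on each channel, truncated at zero.
    """
    centers = np.array([FLUORESCENCE_CENTERS[g] for g in genotypes])
    noise = rng.normal(0.0, noise_sd * 1000.0, size=centers.shape)
    return np.clip(centers + noise, 0.0, None)


def _expand_cohort_spec(spec: Mapping[str, Mapping[str, int]]) -> List[Tuple[str, str, str]]:
    """(breed, phenotype, genotype) rows from exact per-breed counts."""
    rows = []
    for breed in spec:
        for key, n in spec[breed].items():
            phenotype, _, genotype = key.partition("_")
            if phenotype not in ("affected", "unaffected", "unknown"):
                raise InputError(f"cohort spec key {key!r}: bad phenotype")
            if genotype not in ("hom_ref", "het", "hom_alt"):
                raise InputError(f"cohort spec key {key!r}: bad genotype")
            rows.extend((breed, phenotype, genotype) for _ in range(int(n)))
    return rows


def _generate_cohort(spec: Mapping[str, Mapping[str, int]], rng: np.random.Generator,
                     noise_sd: float) -> pd.DataFrame:
    rows = _expand_cohort_spec(spec)
    df = pd.DataFrame(rows, columns=["breed", "phenotype", "genotype"])
    df.insert(0, "sample_id", [f"s{i + 1:04d}" for i in range(len(df))])
    fluo = fluorescence_from_genotypes(df["genotype"], rng, noise_sd)
    df["channel_ref"] = np.round(fluo[:, 0], 2)
    df["channel_alt"] = np.round(fluo[:, 1], 2)
    return df


PAPER_LIKE_COHORT: Dict[str, Dict[str, int]] = {
    "SCWT": {"affected_hom_alt": 22, "unaffected_het": 15, "unaffected_hom_ref": 667},
    "Whoodle": {"affected_hom_alt": 3},
    "Poodle": {"unaffected_hom_ref": 388},
    "other": {"unaffected_hom_ref": 132},
}


def generate_paper_like_cohort(seed: int, noise_sd: float = 0.05) -> pd.DataFrame:
    """The published genotyping cohort with synthetic fluorescence.

    25 affected homozygotes (22 SCWT + 3 Whoodles), 682 control SCWT of which
    15 heterozygous and 667 homozygous reference, 388 Poodles and 132 dogs of
    other breeds all homozygous reference — 1227 samples.  Counts are exact
    partitions, so the printed cohort is reproduced without sampling error.
    """
    rng = np.random.default_rng(seed)
    return _generate_cohort(PAPER_LIKE_COHORT, rng, noise_sd)


# ---------------------------------------------------------------------------
# ortholog alignment

RESIDUES = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def _generate_alignment(s: SyntheticScenario, rng: np.random.Generator) -> OrthologAlignment:
    comp = s.alignment_composition
    n_rows = sum(comp.values())
    focal = []
    for res, n in comp.items():
        focal.extend([res] * n)
    focal = [focal[i] for i in rng.permutation(n_rows)]
    # flanking columns: broadly conserved, occasional per-species substitution
    columns = []
    for c in range(s.alignment_width):
        if c == s.alignment_focal_column - 1:
            columns.append(focal)
            continue
        consensus = str(rng.choice(RESIDUES))
        col = [
            consensus if rng.random() > 0.05 else str(rng.choice(RESIDUES))
            for _ in range(n_rows)
        ]
        columns.append(col)
    rows = tuple(
        (f"species_{i + 1:04d}", "".join(columns[c][i] for c in range(s.alignment_width)))
        for i in range(n_rows)
    )
    return OrthologAlignment(rows, s.alignment_focal_column)


# ---------------------------------------------------------------------------
# on-disk layout

def write_scenario(bundle: ScenarioBundle, outdir: str | Path) -> Dict[str, Path]:
    """Write every pipeline input plus the truth manifest under ``outdir``.

    Returns the path of each artefact; also drops a ready-to-run pipeline
    config (``config.yaml``) referencing the written files.
    """
    out = Path(outdir)
    (out / "vcf").mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    paths["reference"] = out / "reference.fa"
    pxio.write_fasta_assembly(bundle.assembly, paths["reference"])
    paths["genes"] = out / "genes.bed"
    pxio.write_bed12(bundle.genes, paths["genes"])

    case_paths, control_paths = [], []
    for obs in bundle.cases + bundle.controls:
        p = out / "vcf" / f"{obs.genome_id}.vcf"
        pxio.write_genome_vcf(obs, bundle.assembly, p)
        (case_paths if obs.role == "case" else control_paths).append(p)
    paths["cohort"] = out / "cohort.tsv"
    cohort_in = bundle.cohort[["sample_id", "breed", "phenotype",
                               "channel_ref", "channel_alt"]]
    cohort_in.to_csv(paths["cohort"], sep="\t", index=False)
    paths["cohort_truth"] = out / "truth_cohort.tsv"
    bundle.cohort.to_csv(paths["cohort_truth"], sep="\t", index=False)
    paths["alignment"] = out / "orthologs.fa"
    pxio.write_alignment_fasta(bundle.alignment, paths["alignment"])
    paths["truth_variants"] = out / "truth_variants.tsv"
    bundle.truth_variants.to_csv(paths["truth_variants"], sep="\t", index=False)

    config = {
        "reference": str(paths["reference"]),
        "gene_models": str(paths["genes"]),
        "case_vcfs": [str(p) for p in case_paths],
        "control_vcfs": [str(p) for p in control_paths],
        "cohort": str(paths["cohort"]),
        "alignment": str(paths["alignment"]),
        "alignment_focal_column": bundle.scenario.alignment_focal_column,
        "variant_aa": bundle.causal_call.alt_aa,
        "splice_window": 2,
        "seed": bundle.scenario.seed,
        "output_dir": str(out / "results"),
    }
    paths["config"] = out / "config.yaml"
    paths["config"].write_text(yaml.safe_dump(config, sort_keys=True))
    truth_summary = {
        "causal_variant": {
            "contig": bundle.causal_variant.contig,
            "pos": bundle.causal_variant.pos,
            "ref": bundle.causal_variant.ref,
            "alt": bundle.causal_variant.alt,
            "gene": bundle.causal_gene.gene_id,
            "hgvs_c": bundle.causal_call.hgvs_c,
            "hgvs_p": bundle.causal_call.hgvs_p,
        },
        "seed": bundle.scenario.seed,
    }
    paths["truth"] = out / "truth.yaml"
    paths["truth"].write_text(yaml.safe_dump(truth_summary, sort_keys=True))
    return paths
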