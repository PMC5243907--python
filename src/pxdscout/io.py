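"""Readers and writers for the formats the pipeline consumes and emits.

FASTA goes through Bio.SeqIO and VCF through pysam; gene models are read
from BED12 or from a minimal GFF3 (gene/exon/CDS features, one transcript
per gene).  All VCF output is uncompressed VCF 4.2 with consequence
annotations in the INFO keys CSQCAT / HGVSC / HGVSP.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import ConsequenceCall
from .conservation import OrthologAlignment
from .filtering import CandidateSet, GenomeObservation, Zygosity
from .genome import (GeneModel, InputError, ReferenceAssembly, Variant,
                     decompose_vcf_alleles)
from .genotyping import FluorescenceRecord

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta_assembly(path: str | Path) -> ReferenceAssembly:
    contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not contigs:
        raise InputError(f"no sequences in FASTA {path}")
    return ReferenceAssembly(contigs)


def write_fasta_assembly(assembly: ReferenceAssembly, path: str | Path,
                         width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in assembly.contigs.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    del width  # Bio.SeqIO wraps at its default width


def read_alignment_fasta(path: str | Path, focal_column: int) -> OrthologAlignment:
    rows = tuple(
        (rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    )
    return OrthologAlignment(rows, focal_column)


def write_alignment_fasta(alignment: OrthologAlignment, path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in alignment.rows]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# Gene models

def read_bed12(path: str | Path) -> List[GeneModel]:
    """BED12 -> gene models; blocks are exons, thickStart/End the CDS bounds."""
    genes: List[GeneModel] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 12:
            raise InputError(f"{path}:{ln}: BED12 requires 12 columns, got {len(f)}")
        chrom, start, _end, name = f[0], int(f[1]), int(f[2]), f[3]
        strand = f[5]
        thick_start, thick_end = int(f[6]), int(f[7])
        n_blocks = int(f[9])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        starts = [int(x) for x in f[11].rstrip(",").split(",")]
        if len(sizes) != n_blocks or len(starts) != n_blocks:
            raise InputError(f"{path}:{ln}: block count mismatch")
        exons = tuple((start + s, start + s + z) for s, z in zip(starts, sizes))
        genes.append(GeneModel(name, chrom, strand, exons, thick_start, thick_end))
    return genes


def write_bed12(genes: Iterable[GeneModel], path: str | Path) -> None:
    lines = []
    for g in genes:
        start, end = g.span
        sizes = ",".join(str(e - s) for s, e in g.exons)
        starts = ",".join(str(s - start) for s, e in g.exons)
        lines.append(
            "\t".join(
                [
                    g.contig, str(start), str(end), g.gene_id, "0", g.strand,
                    str(g.cds_start), str(g.cds_end), "0",
                    str(len(g.exons)), sizes, starts,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _gff_attributes(field: str) -> Dict[str, str]:
    out = {}
    for item in field.strip().split(";"):
        if not item:
            continue
        k, _, v = item.partition("=")
        out[k.strip()] = v.strip()
    return out


def read_gff3(path: str | Path) -> List[GeneModel]:
    """Minimal GFF3 reader: gene features with exon and CDS children.

    Children are attached to the gene named by their Parent attribute (or by
    gene_id); one transcript model per gene.
    """
    strand_of: Dict[str, str] = {}
    contig_of: Dict[str, str] = {}
    exons: Dict[str, List[Tuple[int, int]]] = {}
    cds: Dict[str, List[Tuple[int, int]]] = {}
    order: List[str] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) != 9:
            raise InputError(f"{path}:{ln}: GFF3 requires 9 columns")
        seqid, _src, ftype, start, end, _score, strand, _frame, attrs = f
        a = _gff_attributes(attrs)
        iv = (int(start) - 1, int(end))  # GFF is 1-based closed
        if ftype == "gene":
            gid = a.get("ID") or a.get("gene_id")
            if not gid:
                raise InputError(f"{path}:{ln}: gene feature without ID")
            order.append(gid)
            strand_of[gid] = strand
            contig_of[gid] = seqid
        elif ftype in ("exon", "CDS"):
            gid = a.get("Parent") or a.get("gene_id")
            if not gid:
                raise InputError(f"{path}:{ln}: {ftype} feature without Parent")
            (exons if ftype == "exon" else cds).setdefault(gid, []).append(iv)
    genes = []
    for gid in order:
        if gid not in exons:
            raise InputError(f"gene {gid} has no exon features")
        if gid not in cds:
            raise InputError(f"gene {gid} has no CDS features")
        ex = tuple(sorted(exons[gid]))
        cds_ivs = sorted(cds[gid])
        genes.append(
            GeneModel(gid, contig_of[gid], strand_of[gid], ex,
                      cds_ivs[0][0], cds_ivs[-1][1])
        )
    return genes


def read_gene_models(path: str | Path) -> List[GeneModel]:
    """Dispatch on extension: .bed -> BED12, .gff/.gff3 -> GFF3."""
    suffix = Path(path).suffix.lower()
    if suffix == ".bed":
        return read_bed12(path)
    if suffix in (".gff", ".gff3"):
        return read_gff3(path)
    raise InputError(f"unrecognised gene-model format for {path}")


# ---------------------------------------------------------------------------
# VCF

_INFO_LINES = [
    ('CSQCAT', 'String', 'Predicted consequence category'),
    ('HGVSC', 'String', 'HGVS coding-DNA notation'),
    ('HGVSP', 'String', 'HGVS protein notation'),
    ('GENE', 'String', 'Gene model harbouring the variant'),
]


def _vcf_header(assembly: ReferenceAssembly, sample: Optional[str]) -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    for name, seq in assembly.contigs.items():
        h.contigs.add(name, length=len(seq))
    for key, vtype, desc in _INFO_LINES:
        h.info.add(key, 1, vtype, desc)
    h.formats.add("GT", 1, "String", "Genotype")
    if sample is not None:
        h.add_sample(sample)
    return h


def write_genome_vcf(obs: GenomeObservation, assembly: ReferenceAssembly,
                     path: str | Path,
                     annotations: Optional[Mapping[Variant, ConsequenceCall]] = None) -> None:
    """One genome's calls as a single-sample uncompressed VCF."""
    header = _vcf_header(assembly, obs.genome_id)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for v in sorted(obs.calls):
            zyg = obs.calls[v]
            rec = vf.new_record(
                contig=v.contig, start=v.pos - 1, alleles=(v.ref, v.alt), filter="PASS"
            )
            if annotations and v in annotations:
                call = annotations[v]
                rec.info["CSQCAT"] = call.category.value
                rec.info["HGVSC"] = call.hgvs_c
                rec.info["HGVSP"] = call.hgvs_p
                if call.gene_id:
                    rec.info["GENE"] = call.gene_id
            rec.samples[obs.genome_id]["GT"] = (1, 1) if zyg is Zygosity.HOM_ALT else (0, 1)
            vf.write(rec)


def read_genome_vcf(path: str | Path, assembly: ReferenceAssembly, role: str,
                    genome_id: Optional[str] = None) -> GenomeObservation:
    """Load a VCF into a genome observation.

    Multi-allelic records are decomposed into normalized biallelic variants;
    the zygosity of each alternate allele is the number of times it occurs in
    the GT call (2 -> hom_alt, 1 -> het).  Records with missing genotypes are
    excluded and logged; without a sample column every record is taken as
    homozygous alternate (site-list VCF).
    """
    calls: Dict[Variant, Zygosity] = {}
    n_missing = 0
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        if genome_id is None:
            genome_id = samples[0] if samples else Path(path).stem
        for rec in vf:
            alts = list(rec.alts or ())
            if not alts:
                continue
            variants = decompose_vcf_alleles(
                assembly, rec.contig, rec.pos, rec.ref, alts
            )
            if not samples:
                for v in variants:
                    calls[v] = Zygosity.HOM_ALT
                continue
            gt = rec.samples[samples[0]].get("GT")
            if gt is None or any(a is None for a in gt):
                n_missing += 1
                continue
            by_alt = {}
            for vi, alt in enumerate(alts, start=1):
                n_copies = sum(1 for a in gt if a == vi)
                if n_copies:
                    by_alt[alt] = n_copies
            for v, alt in zip(variants, [a for a in alts if a not in (".", "*", "<NON_REF>")]):
                if alt in by_alt:
                    calls[v] = Zygosity.HOM_ALT if by_alt[alt] >= 2 else Zygosity.HET
    if n_missing:
        log.info("%s: %d record(s) with missing genotype excluded", path, n_missing)
    return GenomeObservation(genome_id, role, calls)


# ---------------------------------------------------------------------------
# Tabular outputs

def candidates_to_frame(s: CandidateSet) -> pd.DataFrame:
    rows = [
        {
            "contig": v.contig, "pos": v.pos, "ref": v.ref, "alt": v.alt,
            "gene": c.gene_id or ".", "category": c.category.value,
            "hgvs_c": c.hgvs_c, "hgvs_p": c.hgvs_p,
        }
        for v, c in sorted(s.variants.items())
    ]
    return pd.DataFrame(
        rows, columns=["contig", "pos", "ref", "alt", "gene", "category", "hgvs_c", "hgvs_p"]
    )


def write_candidates_tsv(s: CandidateSet, path: str | Path) -> None:
    candidates_to_frame(s).to_csv(path, sep="\t", index=False)


def write_trajectory_csv(counts: List[int], path: str | Path) -> None:
    pd.DataFrame(
        {"n_controls": range(1, len(counts) + 1), "n_candidates": counts}
    ).to_csv(path, index=False)


def read_cohort_tsv(path: str | Path) -> pd.DataFrame:
    """Cohort table with sample_id, breed, phenotype and either a genotype
    column or channel_ref/channel_alt intensity columns."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "breed", "phenotype"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"cohort TSV {path} missing columns {sorted(missing)}")
    has_gt = "genotype" in df.columns
    has_fluo = {"channel_ref", "channel_alt"} <= set(df.columns)
    if not (has_gt or has_fluo):
        raise InputError(
            f"cohort TSV {path} needs a genotype column or channel_ref/channel_alt"
        )
    return df


def fluorescence_records(df: pd.DataFrame) -> List[FluorescenceRecord]:
    return [
        FluorescenceRecord(str(r.sample_id), float(r.channel_ref), float(r.channel_alt))
        for r in df.itertuples(index=False)
    ]
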