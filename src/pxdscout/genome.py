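"""Core genomic value types: reference assembly, gene models, variants.

Coordinate conventions follow the common file formats: genomic positions are
1-based in all I/O (VCF style) while internal intervals are 0-based half-open
(BED style).  A :class:`GeneModel` carries one transcript per gene — exon
structure plus the genomic bounds of the coding region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

from Bio.Seq import Seq

DNA_ALPHABET = frozenset("ACGTN")
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class InputError(ValueError):
    """Malformed or mutually inconsistent inputs (bad contig, ref mismatch...)."""


@dataclass(frozen=True)
class ReferenceAssembly:
    """An in-memory reference genome: contig name -> uppercase DNA string."""

    contigs: Dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise InputError(f"contig {name!r} has an empty sequence")
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise InputError(f"contig {name!r} contains non-DNA symbols {sorted(bad)}")

    def sequence(self, contig: str) -> str:
        try:
            return self.contigs[contig]
        except KeyError:
            raise InputError(f"unknown contig {contig!r}") from None

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Slice [start, end) 0-based from a contig."""
        seq = self.sequence(contig)
        if start < 0 or end > len(seq):
            raise InputError(
                f"interval [{start},{end}) outside contig {contig!r} of length {len(seq)}"
            )
        return seq[start:end]


@dataclass(frozen=True)
class GeneModel:
    """One transcript model: ordered exons and the genomic CDS bounds.

    ``exons`` are 0-based half-open genomic intervals sorted by start and
    non-overlapping; ``cds_start``/``cds_end`` bound the coding region in
    genomic space (the CDS itself is the intersection of the exons with that
    interval).  ``strand`` is '+' or '-'.
    """

    gene_id: str
    contig: str
    strand: str
    exons: Tuple[Tuple[int, int], ...]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise InputError(f"gene {self.gene_id}: strand must be '+' or '-'")
        exons = tuple(tuple(e) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        if not exons:
            raise InputError(f"gene {self.gene_id}: no exons")
        for s, e in exons:
            if e <= s:
                raise InputError(f"gene {self.gene_id}: empty or inverted exon ({s},{e})")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise InputError(f"gene {self.gene_id}: exons unsorted or overlapping")
        if not (self.span[0] <= self.cds_start < self.cds_end <= self.span[1]):
            raise InputError(f"gene {self.gene_id}: CDS bounds outside exon span")
        if self.cds_length % 3 != 0:
            raise InputError(
                f"gene {self.gene_id}: CDS length {self.cds_length} not a multiple of 3"
            )

    @property
    def span(self) -> Tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def cds_intervals(self) -> List[Tuple[int, int]]:
        """Exon pieces inside [cds_start, cds_end), genomic order."""
        out = []
        for s, e in self.exons:
            cs, ce = max(s, self.cds_start), min(e, self.cds_end)
            if cs < ce:
                out.append((cs, ce))
        return out

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)

    def cds_sequence(self, assembly: ReferenceAssembly) -> str:
        """Spliced CDS on the coding strand (reverse-complemented for '-')."""
        seq = "".join(assembly.fetch(self.contig, s, e) for s, e in self.cds_intervals)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    def protein(self, assembly: ReferenceAssembly) -> str:
        return str(Seq(self.cds_sequence(assembly)).translate())


@dataclass(frozen=True, order=True)
class Variant:
    """A biallelic substitution or indel at a 1-based genomic position."""

    contig: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise InputError("variant position must be 1-based positive")
        if not self.ref or not self.alt:
            raise InputError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise InputError("ref and alt are identical")

    @property
    def key(self) -> Tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def check_reference(self, assembly: ReferenceAssembly) -> None:
        obs = assembly.fetch(self.contig, self.pos - 1, self.pos - 1 + len(self.ref))
        if obs != self.ref:
            raise InputError(
                f"{self.contig}:{self.pos} ref allele {self.ref!r} does not match "
                f"assembly sequence {obs!r}"
            )


def _trim_alleles(pos: int, ref: str, alt: str) -> Tuple[int, str, str]:
    # shared suffix first, then shared prefix; keep at least one base each
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def normalize_variant(assembly: ReferenceAssembly, contig: str, pos: int,
                      ref: str, alt: str) -> Variant:
    """Left-normalize a (possibly redundant) allele pair against the reference.

    Trims shared flanks, then left-shifts pure insertions/deletions through
    repeat tracts until the representation is leftmost, re-anchoring indels on
    the preceding reference base (VCF convention).
    """
    seq = assembly.sequence(contig)
    pos, ref, alt = _trim_alleles(pos, ref, alt)
    if len(ref) != len(alt):
        # reduce to anchored form: ref/alt share first base for indels
        if len(ref) > 1 and len(alt) > 1:
            pass  # complex substitution, leave as trimmed
        else:
            # left-shift while the bases entering and leaving the window agree
            while pos > 1 and ref[-1] == alt[-1]:
                prev = seq[pos - 2]
                ref = prev + ref[:-1]
                alt = prev + alt[:-1]
                pos -= 1
            if ref[0] != alt[0]:
                # ensure an anchor base precedes a pure ins/del
                if pos > 1 and (len(ref) == 0 or len(alt) == 0):
                    prev = seq[pos - 2]
                    ref, alt, pos = prev + ref, prev + alt, pos - 1
    v = Variant(contig, pos, ref, alt)
    v.check_reference(assembly)
    return v


def decompose_vcf_alleles(assembly: ReferenceAssembly, contig: str, pos: int,
                          ref: str, alts: List[str]) -> List[Variant]:
    """Split a multi-allelic VCF record into normalized biallelic variants."""
    out = []
    for alt in alts:
        if alt in (".", "*", "<NON_REF>") or alt == ref:
            continue
        out.append(normalize_variant(assembly, contig, pos, ref, alt))
    return out


@dataclass
class GeneIndex:
    """Lookup of gene models by contig with span search."""

    genes: List[GeneModel]
    _by_contig: Dict[str, List[GeneModel]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise InputError("duplicate gene_ids in gene set")
        by: Dict[str, List[GeneModel]] = {}
        for g in self.genes:
            by.setdefault(g.contig, []).append(g)
        for lst in by.values():
            lst.sort(key=lambda g: g.span)
        self._by_contig = by

    def overlapping(self, contig: str, start0: int, end0: int) -> List[GeneModel]:
        """Genes whose span intersects the 0-based half-open interval."""
        return [
            g
            for g in self._by_contig.get(contig, [])
            if g.span[0] < end0 and start0 < g.span[1]
        ]
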