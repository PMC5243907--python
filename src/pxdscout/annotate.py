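"""Coding-consequence prediction and HGVS nomenclature.

Classifies a variant against a gene model into the usual consequence
categories (missense, synonymous, nonsense, splice donor/acceptor, ...) by
translating the affected codon on the coding strand with the standard genetic
code, and renders compact HGVS c./p. strings such as ``c.398C>T`` /
``p.T133I``.  Splice signals default to the two canonical intronic bases at
each exon boundary; the window is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Tuple

from Bio.Data.IUPACData import protein_letters_1to3
from Bio.Seq import Seq

from .genome import (COMPLEMENT, GeneIndex, GeneModel, InputError,
                     ReferenceAssembly, Variant)


class Consequence(str, Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    STOP_LOSS = "stop_loss"
    SPLICE_DONOR = "splice_donor"
    SPLICE_ACCEPTOR = "splice_acceptor"
    INTRONIC = "intronic"
    UTR = "utr"
    INTERGENIC = "intergenic"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"


#: categories predicted to alter the protein product, including variants that
#: disrupt exon-splicing signals
AMINO_ACID_ALTERING = frozenset(
    {
        Consequence.MISSENSE,
        Consequence.NONSENSE,
        Consequence.STOP_LOSS,
        Consequence.FRAMESHIFT,
        Consequence.INFRAME_INDEL,
        Consequence.SPLICE_DONOR,
        Consequence.SPLICE_ACCEPTOR,
    }
)


@dataclass(frozen=True)
class ConsequenceCall:
    """Predicted effect of one variant on one gene model."""

    category: Consequence
    gene_id: Optional[str] = None
    cds_pos: Optional[int] = None
    codon_index: Optional[int] = None
    codon_offset: Optional[int] = None
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None
    hgvs_c: str = "."
    hgvs_p: str = "."


def is_amino_acid_altering(call: ConsequenceCall) -> bool:
    """True iff the predicted consequence alters the amino-acid sequence
    of the gene product (splice-signal disruption included)."""
    return call.category in AMINO_ACID_ALTERING


def codon_coordinates(cds_pos: int) -> Tuple[int, int]:
    """Map a 1-based coding position to (codon_index, codon_offset), both 1-based.

    >>> codon_coordinates(398)
    (133, 2)
    """
    if cds_pos < 1:
        raise InputError(f"cds_pos must be >= 1, got {cds_pos}")
    return (cds_pos - 1) // 3 + 1, (cds_pos - 1) % 3 + 1


def genomic_to_cds(model: GeneModel, pos: int) -> Optional[int]:
    """1-based genomic position -> 1-based coding position, or None outside the CDS.

    Coding positions count along the coding strand, so for '-' strand genes
    position 1 is the genomically rightmost CDS base.
    """
    if pos < 1:
        raise InputError("genomic position must be 1-based positive")
    g0 = pos - 1
    offset = 0
    for s, e in model.cds_intervals:
        if s <= g0 < e:
            fwd = offset + (g0 - s) + 1
            return fwd if model.strand == "+" else model.cds_length - fwd + 1
        offset += e - s
    return None


def cds_to_genomic(model: GeneModel, cds_pos: int) -> int:
    """Inverse of :func:`genomic_to_cds` for positions inside the CDS."""
    if not 1 <= cds_pos <= model.cds_length:
        raise InputError(
            f"cds_pos {cds_pos} outside CDS of length {model.cds_length}"
        )
    fwd = cds_pos if model.strand == "+" else model.cds_length - cds_pos + 1
    offset = 0
    for s, e in model.cds_intervals:
        if fwd <= offset + (e - s):
            return s + (fwd - offset - 1) + 1
        offset += e - s
    raise AssertionError("unreachable: cds_pos inside bounds")


def _aa3(aa: str) -> str:
    if aa == "*":
        return "Ter"
    return protein_letters_1to3.get(aa, "Xaa")


def _format_p(ref_aa: str, codon: int, alt_aa: str, category: Consequence,
              three_letter: bool) -> str:
    r, a = (_aa3(ref_aa), _aa3(alt_aa)) if three_letter else (ref_aa, alt_aa)
    if category is Consequence.SYNONYMOUS:
        return f"p.{r}{codon}="
    if category is Consequence.FRAMESHIFT:
        return f"p.{r}{codon}fs"
    return f"p.{r}{codon}{a}"


def _intronic_hgvs_c(model: GeneModel, g0: int, ref_c: str, alt_c: str) -> str:
    """c. notation with intron offsets relative to the nearest CDS edge base."""
    # nearest coding base on each side in genomic space
    left = right = None
    for s, e in model.cds_intervals:
        if e <= g0:
            left = e - 1
        if right is None and s > g0:
            right = s
    anchor = None
    if left is not None and (right is None or g0 - left <= right - g0):
        anchor, off = left, g0 - left
    elif right is not None:
        anchor, off = right, g0 - right
    if anchor is None:
        return "."
    cpos = genomic_to_cds(model, anchor + 1)
    if cpos is None:
        return "."
    if model.strand == "-":
        off = -off
    sign = "+" if off > 0 else "-"
    return f"c.{cpos}{sign}{abs(off)}{ref_c}>{alt_c}"


def classify_variant(assembly: ReferenceAssembly, model: GeneModel, v: Variant,
                     splice_window: int = 2, three_letter: bool = False) -> ConsequenceCall:
    """Predict the consequence of ``v`` on ``model``.

    Substitutions inside the CDS are translated codon-wise on the coding
    strand; intronic substitutions within ``splice_window`` bases of an exon
    boundary are splice_donor/splice_acceptor depending on which side of the
    intron they fall (strand-aware); length-changing variants touching the CDS
    are frameshift unless the length difference is a multiple of 3.
    """
    if splice_window < 0:
        raise InputError("splice_window must be >= 0")
    v.check_reference(assembly)
    if v.contig != model.contig:
        return ConsequenceCall(Consequence.INTERGENIC)
    g0 = v.pos - 1
    var_start, var_end = g0, g0 + len(v.ref)
    span_s, span_e = model.span
    if var_end <= span_s or var_start >= span_e:
        return ConsequenceCall(Consequence.INTERGENIC)

    if v.is_snv:
        return _classify_snv(assembly, model, v, splice_window, three_letter)
    return _classify_indel(model, v, splice_window)


def _splice_side(model: GeneModel, g0: int, splice_window: int) -> Optional[Consequence]:
    """Donor/acceptor call for an intronic position near an exon boundary."""
    for (s1, e1), (s2, e2) in zip(model.exons, model.exons[1:]):
        if not (e1 <= g0 < s2):
            continue
        near_left = g0 - e1 < splice_window          # adjacent to upstream-in-genome exon
        near_right = s2 - g0 <= splice_window
        if near_left:
            return Consequence.SPLICE_DONOR if model.strand == "+" else Consequence.SPLICE_ACCEPTOR
        if near_right:
            return Consequence.SPLICE_ACCEPTOR if model.strand == "+" else Consequence.SPLICE_DONOR
        return None
    return None


def _classify_snv(assembly: ReferenceAssembly, model: GeneModel, v: Variant,
                  splice_window: int, three_letter: bool) -> ConsequenceCall:
    g0 = v.pos - 1
    cds_pos = genomic_to_cds(model, v.pos)
    if cds_pos is not None:
        codon_idx, codon_off = codon_coordinates(cds_pos)
        cds_seq = model.cds_sequence(assembly)
        codon = cds_seq[(codon_idx - 1) * 3: codon_idx * 3]
        ref_c, alt_c = v.ref, v.alt
        if model.strand == "-":
            ref_c = ref_c.translate(COMPLEMENT)
            alt_c = alt_c.translate(COMPLEMENT)
        assert codon[codon_off - 1] == ref_c, "CDS sequence inconsistent with variant ref"
        new_codon = codon[: codon_off - 1] + alt_c + codon[codon_off:]
        ref_aa = str(Seq(codon).translate())
        alt_aa = str(Seq(new_codon).translate())
        if ref_aa == alt_aa:
            cat = Consequence.SYNONYMOUS
        elif alt_aa == "*":
            cat = Consequence.NONSENSE
        elif ref_aa == "*":
            cat = Consequence.STOP_LOSS
        else:
            cat = Consequence.MISSENSE
        return ConsequenceCall(
            category=cat,
            gene_id=model.gene_id,
            cds_pos=cds_pos,
            codon_index=codon_idx,
            codon_offset=codon_off,
            ref_aa=ref_aa,
            alt_aa=alt_aa,
            hgvs_c=f"c.{cds_pos}{ref_c}>{alt_c}",
            hgvs_p=_format_p(ref_aa, codon_idx, alt_aa, cat, three_letter),
        )

    in_exon = any(s <= g0 < e for s, e in model.exons)
    ref_c, alt_c = v.ref, v.alt
    if model.strand == "-":
        ref_c = ref_c.translate(COMPLEMENT)
        alt_c = alt_c.translate(COMPLEMENT)
    if in_exon:
        return ConsequenceCall(Consequence.UTR, gene_id=model.gene_id)
    splice = _splice_side(model, g0, splice_window)
    cat = splice if splice is not None else Consequence.INTRONIC
    return ConsequenceCall(
        cat, gene_id=model.gene_id, hgvs_c=_intronic_hgvs_c(model, g0, ref_c, alt_c)
    )


def _classify_indel(model: GeneModel, v: Variant, splice_window: int) -> ConsequenceCall:
    g0 = v.pos - 1
    # the anchored base is unchanged; the affected interval starts after it
    aff_start = g0 + 1 if v.ref[0] == v.alt[0] else g0
    aff_end = g0 + len(v.ref)
    if aff_end <= aff_start:
        aff_end = aff_start + 1  # pure insertion: point between bases
    touches = lambda s, e: s < aff_end and aff_start < e  # noqa: E731
    if any(touches(s, e) for s, e in model.cds_intervals):
        shift = len(v.alt) - len(v.ref)
        cat = Consequence.INFRAME_INDEL if shift % 3 == 0 else Consequence.FRAMESHIFT
        first_coding = next(
            (p for p in range(aff_start, aff_end)
             if genomic_to_cds(model, p + 1) is not None),
            None,
        )
        cds_pos = codon_idx = codon_off = None
        hgvs_p = "."
        if first_coding is not None:
            cds_pos = genomic_to_cds(model, first_coding + 1)
            codon_idx, codon_off = codon_coordinates(cds_pos)
            hgvs_p = f"p.{codon_idx}fs" if cat is Consequence.FRAMESHIFT else "."
        kind = "del" if len(v.alt) < len(v.ref) else ("ins" if len(v.alt) > len(v.ref) else "delins")
        hgvs_c = f"c.{cds_pos}{kind}" if cds_pos is not None else "."
        return ConsequenceCall(
            cat, gene_id=model.gene_id, cds_pos=cds_pos, codon_index=codon_idx,
            codon_offset=codon_off, hgvs_c=hgvs_c, hgvs_p=hgvs_p,
        )
    if any(touches(s, e) for s, e in model.exons):
        return ConsequenceCall(Consequence.UTR, gene_id=model.gene_id)
    for p in range(aff_start, aff_end):
        splice = _splice_side(model, p, splice_window)
        if splice is not None:
            return ConsequenceCall(splice, gene_id=model.gene_id)
    return ConsequenceCall(Consequence.INTRONIC, gene_id=model.gene_id)


def annotate_variant(assembly: ReferenceAssembly, index: GeneIndex, v: Variant,
                     splice_window: int = 2, three_letter: bool = False) -> ConsequenceCall:
    """Classify ``v`` against the gene (if any) whose span contains it.

    With non-overlapping gene models at most one gene matches; if several
    overlap the leftmost is used.
    """
    genes = index.overlapping(v.contig, v.pos - 1, v.pos - 1 + len(v.ref))
    if not genes:
        return ConsequenceCall(Consequence.INTERGENIC)
    return classify_variant(assembly, genes[0], v, splice_window, three_letter)
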