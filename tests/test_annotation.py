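"""Coordinate mapping, codon arithmetic and consequence classification."""

import pytest
from hypothesis import given, settings, strategies as st

from pxdscout.annotate import (Consequence, ConsequenceCall, annotate_variant,
                               cds_to_genomic, classify_variant,
                               codon_coordinates, genomic_to_cds,
                               is_amino_acid_altering)
from pxdscout.genome import (COMPLEMENT, GeneIndex, GeneModel, InputError,
                             ReferenceAssembly, Variant, normalize_variant)


@pytest.mark.parametrize(
    "cds_pos,expected",
    [(398, (133, 2)), (1, (1, 1)), (3, (1, 3)), (4, (2, 1)), (399, (133, 3))],
)
def test_codon_coordinates(cds_pos, expected):
    assert codon_coordinates(cds_pos) == expected


def test_codon_coordinates_rejects_nonpositive():
    with pytest.raises(InputError):
        codon_coordinates(0)


@given(st.integers(min_value=1, max_value=3000))
@settings(derandomize=True)
def test_codon_coordinates_match_triplet_scan(cds_pos):
    """Codon arithmetic agrees with literally walking consecutive triplets."""
    pos = 0
    for codon_index in range(1, cds_pos // 3 + 2):
        for offset in (1, 2, 3):
            pos += 1
            if pos == cds_pos:
                assert codon_coordinates(cds_pos) == (codon_index, offset)
                return
    raise AssertionError("scan never reached cds_pos")


def test_genomic_to_cds_plus_strand(plus_gene):
    assert genomic_to_cds(plus_gene, 101) == 1        # first coding base
    assert genomic_to_cds(plus_gene, 498) == 398      # 101 + 398 - 1
    assert genomic_to_cds(plus_gene, 50) is None      # upstream of the gene


def test_genomic_to_cds_intron(minus_gene_assembly):
    _, gene = minus_gene_assembly
    assert genomic_to_cds(gene, 300) is None          # intron between the exons


@pytest.mark.parametrize("gene_fixture", ["plus_gene", "minus_gene"])
def test_cds_genomic_round_trip(gene_fixture, plus_gene, minus_gene_assembly, request):
    gene = plus_gene if gene_fixture == "plus_gene" else minus_gene_assembly[1]
    for cds_pos in range(1, gene.cds_length + 1):
        g = cds_to_genomic(gene, cds_pos)
        assert genomic_to_cds(gene, g) == cds_pos


def test_missense_call_t133i(tiny_assembly, plus_gene):
    """C>T at offset 2 of the ACC codon 133 gives Thr->Ile with the published HGVS."""
    v = Variant("chrT", 100 + 397 + 1, "C", "T")  # CDS position 398
    call = classify_variant(tiny_assembly, plus_gene, v)
    assert call.category is Consequence.MISSENSE
    assert (call.cds_pos, call.codon_index, call.codon_offset) == (398, 133, 2)
    assert (call.ref_aa, call.alt_aa) == ("T", "I")
    assert call.hgvs_c == "c.398C>T"
    assert call.hgvs_p == "p.T133I"
    three = classify_variant(tiny_assembly, plus_gene, v, three_letter=True)
    assert three.hgvs_p == "p.Thr133Ile"


def test_synonymous_call_acc_act(tiny_assembly, plus_gene):
    """C>T at offset 3 of ACC yields ACT, still threonine."""
    v = Variant("chrT", 100 + 398 + 1, "C", "T")  # CDS position 399
    call = classify_variant(tiny_assembly, plus_gene, v)
    assert call.category is Consequence.SYNONYMOUS
    assert call.hgvs_p == "p.T133="


def test_splice_and_intron_calls(minus_gene_assembly):
    assembly, gene = minus_gene_assembly
    seq = assembly.sequence("chrM")
    # first intronic base after exon 1 end (genomic 250, 0-based): on the minus
    # strand that is the acceptor side of the intron
    pos = 251
    v = Variant("chrM", pos, seq[pos - 1], "A" if seq[pos - 1] != "A" else "C")
    assert classify_variant(assembly, gene, v).category is Consequence.SPLICE_ACCEPTOR
    # last intronic base before exon 2 start: donor side on the minus strand
    pos = 350
    v = Variant("chrM", pos, seq[pos - 1], "A" if seq[pos - 1] != "A" else "C")
    assert classify_variant(assembly, gene, v).category is Consequence.SPLICE_DONOR
    # mid-intron
    pos = 300
    v = Variant("chrM", pos, seq[pos - 1], "A" if seq[pos - 1] != "A" else "C")
    assert classify_variant(assembly, gene, v).category is Consequence.INTRONIC
    # window of zero disables splice calls
    pos = 251
    v = Variant("chrM", pos, seq[pos - 1], "A" if seq[pos - 1] != "A" else "C")
    assert classify_variant(assembly, gene, v, splice_window=0).category is Consequence.INTRONIC


def test_indel_classification(tiny_assembly, plus_gene):
    seq = tiny_assembly.sequence("chrT")
    # 1-bp deletion inside the CDS -> frameshift
    v = Variant("chrT", 200, seq[199:201], seq[199])
    assert classify_variant(tiny_assembly, plus_gene, v).category is Consequence.FRAMESHIFT
    # 3-bp deletion inside the CDS -> inframe
    v = Variant("chrT", 200, seq[199:203], seq[199])
    assert classify_variant(tiny_assembly, plus_gene, v).category is Consequence.INFRAME_INDEL


def test_ref_mismatch_raises(tiny_assembly, plus_gene):
    seq = tiny_assembly.sequence("chrT")
    wrong = "A" if seq[150] != "A" else "G"
    with pytest.raises(InputError):
        classify_variant(tiny_assembly, plus_gene, Variant("chrT", 151, wrong, "T"))


def test_strand_symmetry(tiny_assembly, plus_gene):
    """Classifying against the mirrored minus-strand gene on the
    reverse-complemented assembly gives identical consequence calls."""
    seq = tiny_assembly.sequence("chrT")
    L = len(seq)
    rc = seq.translate(COMPLEMENT)[::-1]
    mirror_assembly = ReferenceAssembly({"chrT": rc})
    s, e = plus_gene.exons[0]
    mirror_gene = GeneModel("geneP", "chrT", "-", ((L - e, L - s),), L - e, L - s)
    for pos in range(101, 701, 17):
        ref = seq[pos - 1]
        alt = {"A": "C", "C": "T", "G": "A", "T": "G"}[ref]
        fwd = classify_variant(tiny_assembly, plus_gene, Variant("chrT", pos, ref, alt))
        mpos = L - pos + 1
        mv = Variant("chrT", mpos, ref.translate(COMPLEMENT), alt.translate(COMPLEMENT))
        rev = classify_variant(mirror_assembly, mirror_gene, mv)
        assert (fwd.category, fwd.cds_pos, fwd.codon_index, fwd.codon_offset,
                fwd.ref_aa, fwd.alt_aa, fwd.hgvs_c, fwd.hgvs_p) == (
               rev.category, rev.cds_pos, rev.codon_index, rev.codon_offset,
               rev.ref_aa, rev.alt_aa, rev.hgvs_c, rev.hgvs_p)


@pytest.mark.parametrize(
    "category,expected",
    [
        (Consequence.MISSENSE, True),
        (Consequence.NONSENSE, True),
        (Consequence.SPLICE_ACCEPTOR, True),
        (Consequence.SPLICE_DONOR, True),
        (Consequence.FRAMESHIFT, True),
        (Consequence.INFRAME_INDEL, True),
        (Consequence.STOP_LOSS, True),
        (Consequence.SYNONYMOUS, False),
        (Consequence.INTRONIC, False),
        (Consequence.UTR, False),
        (Consequence.INTERGENIC, False),
    ],
)
def test_is_amino_acid_altering(category, expected):
    assert is_amino_acid_altering(ConsequenceCall(category)) is expected


def test_annotate_variant_dispatch(tiny_assembly, plus_gene):
    index = GeneIndex([plus_gene])
    seq = tiny_assembly.sequence("chrT")
    inside = annotate_variant(
        tiny_assembly, index,
        Variant("chrT", 498, seq[497], "A" if seq[497] != "A" else "C"))
    assert inside.gene_id == "geneP"
    outside = annotate_variant(
        tiny_assembly, index,
        Variant("chrT", 900, seq[899], "A" if seq[899] != "A" else "C"))
    assert outside.category is Consequence.INTERGENIC


def test_normalize_left_shifts_deletion():
    assembly = ReferenceAssembly({"c": "GATTTTC"})
    v = normalize_variant(assembly, "c", 5, "TT", "T")
    assert (v.pos, v.ref, v.alt) == (2, "AT", "A")


def test_generated_cds_translates_to_recorded_protein(small_scenario):
    """Independent splice-and-translate of every generated gene matches the
    protein the generator recorded."""
    from Bio.Seq import Seq
    b = small_scenario
    for gene in b.genes:
        seq = b.assembly.sequence(gene.contig)
        cds = "".join(seq[s:e] for s, e in gene.cds_intervals)
        if gene.strand == "-":
            cds = str(Seq(cds).reverse_complement())
        assert str(Seq(cds).translate()) == b.proteins[gene.gene_id]
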