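"""The three-criteria candidate filter, trajectory and intersection."""

import numpy as np
import pytest
from helpers import naive_filter, random_mini_study

from pxdscout.annotate import Consequence, ConsequenceCall
from pxdscout.filtering import (CandidateSet, ControlVariantStore,
                                GenomeObservation, Zygosity,
                                candidate_trajectory, count_candidate_table,
                                filter_candidates, intersect_cases,
                                summarize_candidates)
from pxdscout.genome import InputError, Variant


def _v(pos):
    return Variant("c1", pos, "A", "G")


def _missense(gene="g1"):
    return ConsequenceCall(Consequence.MISSENSE, gene_id=gene)


def _store(*observations):
    store = ControlVariantStore()
    for obs in observations:
        store.add_genome(obs)
    return store


def test_three_criteria_enumeration():
    """het missense, hom missense unseen, hom missense seen in a control and
    hom synonymous: only the unseen hom missense survives."""
    v1, v2, v3, v4 = _v(10), _v(20), _v(30), _v(40)
    case = GenomeObservation("case1", "case", {
        v1: Zygosity.HET, v2: Zygosity.HOM_ALT, v3: Zygosity.HOM_ALT,
        v4: Zygosity.HOM_ALT,
    })
    annotations = {v1: _missense(), v2: _missense(), v3: _missense(),
                   v4: ConsequenceCall(Consequence.SYNONYMOUS, gene_id="g2")}
    store = _store(GenomeObservation("ctl1", "control", {v3: Zygosity.HET}))
    cand = filter_candidates(case, store, annotations)
    assert set(cand.variants) == {v2}


def test_empty_store_keeps_all_hom_altering():
    variants = [_v(p) for p in range(1, 6)]
    case = GenomeObservation("case1", "case",
                             {v: Zygosity.HOM_ALT for v in variants})
    cand = filter_candidates(case, ControlVariantStore(),
                             {v: _missense() for v in variants})
    assert len(cand) == 5


def test_no_hom_calls_gives_empty_set():
    variants = [_v(p) for p in range(1, 6)]
    case = GenomeObservation("case1", "case",
                             {v: Zygosity.HET for v in variants})
    cand = filter_candidates(case, ControlVariantStore(),
                             {v: _missense() for v in variants})
    assert len(cand) == 0


def test_unannotated_variant_raises():
    case = GenomeObservation("case1", "case", {_v(10): Zygosity.HOM_ALT})
    with pytest.raises(InputError, match="lack annotations"):
        filter_candidates(case, ControlVariantStore(), {})


def test_duplicate_control_is_idempotent():
    v = _v(10)
    ctl = GenomeObservation("ctl1", "control", {v: Zygosity.HET})
    store = _store(ctl)
    before = {k: set(s) for k, s in store._index.items()}
    store.add_genome(ctl)
    assert len(store) == 1
    assert {k: set(s) for k, s in store._index.items()} == before


def test_trajectory_monotone_and_order_invariant():
    rng = np.random.default_rng(7)
    for _ in range(30):
        case, controls, annotations = random_mini_study(rng)
        traj = candidate_trajectory(case, controls, annotations)
        assert len(traj) == len(controls)
        assert all(a >= b for a, b in zip(traj, traj[1:]))
        # final candidate set independent of control order
        final_fwd = filter_candidates(case, _store(*controls), annotations)
        final_rev = filter_candidates(case, _store(*reversed(controls)), annotations)
        assert set(final_fwd.variants) == set(final_rev.variants)


def test_trajectory_with_zero_controls_is_empty():
    case = GenomeObservation("case1", "case", {_v(1): Zygosity.HOM_ALT})
    assert candidate_trajectory(case, [], {_v(1): _missense()}) == []


def test_filter_matches_naive_oracle():
    """Indexed filter agrees with a literal triple-loop reimplementation."""
    rng = np.random.default_rng(21)
    for _ in range(20):
        case, controls, annotations = random_mini_study(rng, n_pool=120, n_controls=8)
        got = set(filter_candidates(case, _store(*controls), annotations).variants)
        assert got == naive_filter(case, controls, annotations)


def test_intersection_basics():
    v2, v5, v6 = _v(2), _v(5), _v(6)
    a = CandidateSet("case1", {v2: _missense(), v5: _missense("g3")}, 1)
    b = CandidateSet("case2", {v2: _missense(), v6: _missense("g4")}, 1)
    inter = intersect_cases([a, b])
    assert set(inter.variants) == {v2}
    assert inter.variants.keys() <= a.variants.keys()
    assert inter.variants.keys() <= b.variants.keys()
    disjoint = intersect_cases(
        [CandidateSet("x", {v5: _missense()}, 1), CandidateSet("y", {v6: _missense()}, 1)]
    )
    assert len(disjoint) == 0
    with pytest.raises(InputError):
        intersect_cases([a])


def test_summarize_counts_variants_and_genes():
    variants = {_v(p): _missense(f"g{p % 3}") for p in range(1, 8)}
    s = CandidateSet("case1", variants, 0)
    assert summarize_candidates(s) == (7, 3)
    assert summarize_candidates(CandidateSet("c", {}, 0)) == (0, 0)


def test_store_save_load_round_trip(tmp_path):
    rng = np.random.default_rng(5)
    _, controls, _ = random_mini_study(rng)
    store = _store(*controls)
    path = tmp_path / "store.json"
    store.save(path)
    loaded = ControlVariantStore.load(path)
    assert len(loaded) == len(store)
    for v in [_v(p + 1) for p in range(100)]:
        assert loaded.observers(v) == store.observers(v)


def test_candidate_table_count(tmp_path):
    lines = ["contig\tpos\tref\talt\tgene"]
    for i in range(10):
        lines.append(f"c1\t{100 + i}\tA\tG\tg{i % 4}")
    path = tmp_path / "candidates.tsv"
    path.write_text("\n".join(lines) + "\n")
    assert count_candidate_table(path) == (10, 4)
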