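"""Fluorescence genotype calling, segregation and the Fisher exact test."""

import numpy as np
import pandas as pd
import pytest
from helpers import fisher_two_sided_oracle
from scipy.stats import fisher_exact as scipy_fisher

from pxdscout.genome import InputError
from pxdscout.genotyping import (CallerParams, FluorescenceRecord,
                                 call_genotypes, fisher_exact_2x2,
                                 fisher_exact_recessive, genotype_concordance,
                                 segregation_check)
from pxdscout.simulate import fluorescence_from_genotypes


def _records(array):
    return [FluorescenceRecord(f"s{i}", float(r), float(a))
            for i, (r, a) in enumerate(array)]


def test_pure_signals_and_no_call():
    calls = call_genotypes(_records([(1000, 0), (0, 1000), (700, 700), (0, 0)]))
    assert calls == ["hom_ref", "hom_alt", "het", "no_call"]


def test_all_zero_intensities_all_no_call():
    assert call_genotypes(_records([(0, 0)] * 4)) == ["no_call"] * 4


def test_caller_scale_invariance():
    rng = np.random.default_rng(3)
    truth = list(rng.choice(["hom_ref", "het", "hom_alt"], size=120))
    fluo = fluorescence_from_genotypes(truth, rng, 0.08)
    base = call_genotypes(_records(fluo))
    for scale in (0.05, 3.0, 250.0):
        assert call_genotypes(_records(fluo * scale)) == base


def test_caller_recovers_planted_clusters_at_low_noise():
    rng = np.random.default_rng(11)
    truth = ["hom_ref"] * 40 + ["het"] * 30 + ["hom_alt"] * 30
    fluo = fluorescence_from_genotypes(truth, rng, 0.05)
    assert call_genotypes(_records(fluo)) == truth


def test_caller_exact_at_zero_noise():
    rng = np.random.default_rng(0)
    truth = ["hom_ref", "het", "hom_alt"] * 10
    fluo = fluorescence_from_genotypes(truth, rng, 0.0)
    assert call_genotypes(_records(fluo)) == truth


def test_caller_accuracy_under_noise():
    rng = np.random.default_rng(77)
    hits = total = 0
    for _ in range(50):
        truth = list(rng.choice(["hom_ref", "het", "hom_alt"], size=200,
                                p=[0.5, 0.3, 0.2]))
        fluo = fluorescence_from_genotypes(truth, rng, 0.10)
        acc = genotype_concordance(truth, call_genotypes(_records(fluo)))
        hits += acc * 200
        total += 200
    assert hits / total >= 0.99


def test_segregation_paper_cohort(paper_cohort):
    """All 25 affected homozygous alternate, 15/682 SCWT controls het, the
    rest reference homozygous: consistent with recessive inheritance and a
    SCWT control allele frequency of 15/1364."""
    report = segregation_check(paper_cohort)
    assert report.consistent_recessive is True
    scwt = report.strata["SCWT"]
    assert (scwt.n_affected_hom_alt, scwt.n_control_het, scwt.n_control_hom_ref) == (22, 15, 667)
    assert scwt.allele_freq_controls == pytest.approx(15 / 1364, abs=0)
    assert report.strata["Poodle"].n_control_hom_ref == 388
    assert report.n_affected_called == 25
    assert report.n_controls_called == 682 + 388 + 132
    assert report.fisher_p < 1e-10
    # counts are conserved: strata sum back to the cohort size
    total = sum(
        s.n_affected_hom_alt + s.n_affected_other + s.n_controls_called
        for s in report.strata.values()
    )
    assert total == len(paper_cohort)


def test_one_affected_het_breaks_consistency(paper_cohort):
    df = paper_cohort.copy()
    idx = df.index[df["phenotype"] == "affected"][0]
    df.loc[idx, "genotype"] = "het"
    assert segregation_check(df).consistent_recessive is False


def test_no_call_excluded_from_counts(paper_cohort):
    df = paper_cohort.copy()
    idx = df.index[df["genotype"] == "hom_ref"][:10]
    df.loc[idx, "genotype"] = "no_call"
    report = segregation_check(df)
    assert report.n_controls_called == 682 + 388 + 132 - 10


def test_fisher_known_table_matches_oracle():
    assert fisher_exact_2x2(8, 2, 1, 5) == pytest.approx(
        fisher_two_sided_oracle(8, 2, 1, 5), abs=1e-15)


def test_fisher_degenerate_margin_is_one():
    assert fisher_exact_2x2(0, 10, 0, 10) == 1.0
    assert fisher_exact_2x2(0, 0, 0, 0) == 1.0


def test_fisher_matches_scipy_on_random_tables():
    rng = np.random.default_rng(13)
    for _ in range(300):
        a, b, c, d = (int(x) for x in rng.integers(0, 25, size=4))
        ours = fisher_exact_2x2(a, b, c, d)
        ref = scipy_fisher([[a, b], [c, d]], alternative="two-sided").pvalue
        assert ours == pytest.approx(ref, abs=1e-9)


def test_fisher_recessive_from_table(paper_cohort):
    p = fisher_exact_recessive(paper_cohort)
    assert p == pytest.approx(fisher_two_sided_oracle(25, 0, 0, 1202), rel=1e-12)


def test_fisher_recessive_requires_both_groups(paper_cohort):
    df = paper_cohort[paper_cohort["phenotype"] == "unaffected"]
    with pytest.raises(InputError):
        fisher_exact_recessive(df)


def test_invalid_intensities_rejected():
    with pytest.raises(InputError):
        FluorescenceRecord("s", -1.0, 5.0)
    with pytest.raises(InputError):
        FluorescenceRecord("s", float("nan"), 5.0)
    with pytest.raises(InputError):
        call_genotypes([])
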