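"""Endpoint-fluorescence genotype calling and recessive segregation analysis.

An allelic-discrimination (TaqMan-style) assay reads two competing
allele-specific probes: a VIC-labelled probe for the reference allele and a
FAM-labelled probe for the variant allele.  Homozygous-reference samples
light up the reference channel only, homozygous-variant samples the variant
channel only, and heterozygotes both, so genotype clusters separate by the
angle of the (reference, variant) intensity vector.  The caller here is a
small angle-space k-means with clusters seeded at the canonical angles
0 deg / 45 deg / 90 deg; low-signal or outlying samples are left uncalled.

Downstream, :func:`segregation_check` tabulates genotype against phenotype
per breed stratum and tests the recessive association (homozygous-variant
vs. everything else) with a Fisher exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .genome import InputError

log = logging.getLogger(__name__)

GENOTYPES = ("hom_ref", "het", "hom_alt", "no_call")
PHENOTYPES = ("affected", "unaffected", "unknown")
CANONICAL_ANGLES = (0.0, 45.0, 90.0)  # degrees: hom_ref, het, hom_alt


@dataclass(frozen=True)
class FluorescenceRecord:
    """One sample's endpoint intensities (reference channel, variant channel)."""

    sample_id: str
    channel_ref: float
    channel_alt: float

    def __post_init__(self) -> None:
        for v in (self.channel_ref, self.channel_alt):
            if not np.isfinite(v) or v < 0:
                raise InputError(
                    f"sample {self.sample_id}: intensities must be finite and >= 0"
                )


@dataclass(frozen=True)
class CallerParams:
    """Tunables for the angle-space caller.

    ``max_angle_dev`` — maximal angular distance (degrees) from the nearest
    cluster centre before a sample is left uncalled.  ``min_total_frac`` —
    minimal total intensity, as a fraction of the cohort median total, below
    which a sample is treated as failed amplification.  ``n_iter`` — k-means
    refinement sweeps from the canonical seeds.
    """

    max_angle_dev: float = 20.0
    min_total_frac: float = 0.1
    n_iter: int = 10


def call_genotypes(records: Sequence[FluorescenceRecord],
                   params: CallerParams = CallerParams()) -> List[str]:
    """Assign hom_ref / het / hom_alt / no_call to each fluorescence record.

    Invariant to uniform rescaling of both channels: cluster geometry lives
    in angle space and the signal floor is relative to the cohort median.
    """
    if not records:
        raise InputError("no fluorescence records supplied")
    ref = np.array([r.channel_ref for r in records], dtype=float)
    alt = np.array([r.channel_alt for r in records], dtype=float)
    total = ref + alt
    med = np.median(total[total > 0]) if (total > 0).any() else 0.0
    if med == 0.0:
        log.warning("all fluorescence intensities are zero; calling everything no_call")
        return ["no_call"] * len(records)
    ok = total >= params.min_total_frac * med

    angle = np.degrees(np.arctan2(alt, ref))  # 0 = pure ref .. 90 = pure alt
    centers = np.array(CANONICAL_ANGLES, dtype=float)
    labels = np.zeros(len(records), dtype=int)
    for _ in range(params.n_iter):
        d = np.abs(angle[:, None] - centers[None, :])
        new_labels = np.argmin(d, axis=1)
        for k in range(3):
            sel = ok & (new_labels == k)
            if sel.any():
                centers[k] = angle[sel].mean()
        if (new_labels == labels).all():
            labels = new_labels
            break
        labels = new_labels

    dev = np.abs(angle - centers[labels])
    calls = []
    for i in range(len(records)):
        if not ok[i] or dev[i] > params.max_angle_dev:
            calls.append("no_call")
        else:
            calls.append(GENOTYPES[labels[i]])
    return calls


@dataclass
class BreedStratum:
    breed: str
    n_affected_hom_alt: int
    n_affected_other: int
    n_control_hom_alt: int
    n_control_het: int
    n_control_hom_ref: int

    @property
    def n_controls_called(self) -> int:
        return self.n_control_hom_alt + self.n_control_het + self.n_control_hom_ref

    @property
    def allele_freq_controls(self) -> float:
        """Variant-allele frequency among called control genotypes."""
        n = self.n_controls_called
        return (2 * self.n_control_hom_alt + self.n_control_het) / (2 * n) if n else float("nan")


@dataclass
class SegregationReport:
    """Genotype-by-phenotype tabulation with recessive-model diagnostics."""

    strata: Dict[str, BreedStratum]
    consistent_recessive: bool
    fisher_p: float
    allele_freq_controls: float  # across all control samples pooled
    n_affected_called: int
    n_controls_called: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "breed": s.breed,
                "affected_hom_alt": s.n_affected_hom_alt,
                "affected_other": s.n_affected_other,
                "control_hom_alt": s.n_control_hom_alt,
                "control_het": s.n_control_het,
                "control_hom_ref": s.n_control_hom_ref,
                "control_allele_freq": s.allele_freq_controls,
            }
            for s in self.strata.values()
        ]
        return pd.DataFrame(rows)


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "breed", "phenotype", "genotype"}
    missing = required - set(table.columns)
    if missing:
        raise InputError(f"cohort table missing columns {sorted(missing)}")
    if table.empty:
        raise InputError("cohort table is empty")
    if table["sample_id"].duplicated().any():
        raise InputError("duplicate sample_ids in cohort table")
    bad = set(table["genotype"]) - set(GENOTYPES)
    if bad:
        raise InputError(f"unknown genotype labels {sorted(bad)}")
    bad = set(table["phenotype"]) - set(PHENOTYPES)
    if bad:
        raise InputError(f"unknown phenotype labels {sorted(bad)}")
    return table


def segregation_check(table: pd.DataFrame) -> SegregationReport:
    """Tabulate genotypes per breed and check recessive-model consistency.

    Consistency means every called affected sample is homozygous for the
    variant allele and no unaffected sample is.  Samples with phenotype
    'unknown' or genotype 'no_call' are excluded from counts and the test.
    """
    table = _validate_table(table)
    called = table[table["genotype"] != "no_call"]
    strata: Dict[str, BreedStratum] = {}
    for breed, grp in called.groupby("breed", sort=True):
        aff = grp[grp["phenotype"] == "affected"]
        ctl = grp[grp["phenotype"] == "unaffected"]
        strata[breed] = BreedStratum(
            breed=breed,
            n_affected_hom_alt=int((aff["genotype"] == "hom_alt").sum()),
            n_affected_other=int((aff["genotype"] != "hom_alt").sum()),
            n_control_hom_alt=int((ctl["genotype"] == "hom_alt").sum()),
            n_control_het=int((ctl["genotype"] == "het").sum()),
            n_control_hom_ref=int((ctl["genotype"] == "hom_ref").sum()),
        )
    n_aff_other = sum(s.n_affected_other for s in strata.values())
    n_ctl_hom = sum(s.n_control_hom_alt for s in strata.values())
    n_ctl_het = sum(s.n_control_het for s in strata.values())
    n_aff = sum(s.n_affected_hom_alt + s.n_affected_other for s in strata.values())
    n_ctl = sum(s.n_controls_called for s in strata.values())
    freq = (2 * n_ctl_hom + n_ctl_het) / (2 * n_ctl) if n_ctl else float("nan")
    return SegregationReport(
        strata=strata,
        consistent_recessive=(n_aff_other == 0 and n_ctl_hom == 0),
        fisher_p=fisher_exact_recessive(table),
        allele_freq_controls=freq,
        n_affected_called=n_aff,
        n_controls_called=n_ctl,
    )


def fisher_exact_recessive(table: pd.DataFrame) -> float:
    """Two-sided Fisher exact p for hom_alt-vs-rest by affected-vs-unaffected.

    Computed by exact hypergeometric summation over the conditional
    distribution with the observed margins fixed (integer arithmetic, so the
    two-sided tail is exact up to the final float conversion).
    """
    table = _validate_table(table)
    called = table[table["genotype"] != "no_call"]
    aff = called[called["phenotype"] == "affected"]
    ctl = called[called["phenotype"] == "unaffected"]
    if aff.empty or ctl.empty:
        raise InputError("need at least one called affected and one called control sample")
    a = int((aff["genotype"] == "hom_alt").sum())
    b = len(aff) - a
    c = int((ctl["genotype"] == "hom_alt").sum())
    d = len(ctl) - c
    return fisher_exact_2x2(a, b, c, d)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p for the table [[a, b], [c, d]].

    Sums the hypergeometric probabilities of every table with the same
    margins whose probability does not exceed that of the observed table.
    """
    if min(a, b, c, d) < 0:
        raise InputError("table cells must be non-negative")
    n = a + b + c + d
    if n == 0:
        return 1.0
    r, k = a + b, a + c
    lo, hi = max(0, r + k - n), min(r, k)
    weights = [comb(r, x) * comb(n - r, k - x) for x in range(lo, hi + 1)]
    obs = weights[a - lo]
    tail = sum(w for w in weights if w <= obs)
    return min(1.0, tail / comb(n, k))


def genotype_concordance(truth: Sequence[str], called: Sequence[str]) -> float:
    """Fraction of samples whose call matches the true genotype (no_call counts as a miss)."""
    if len(truth) != len(called):
        raise InputError("truth and call vectors differ in length")
    if not truth:
        return float("nan")
    return sum(t == c for t, c in zip(truth, called)) / len(truth)
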