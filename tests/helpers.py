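"""Shared test utilities: independent oracles and random mini-studies.

Everything here is deliberately naive — plain loops and exact arithmetic —
so the implementations under test are checked against independent logic.
"""

from fractions import Fraction
from math import factorial
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np

from pxdscout.annotate import Consequence, ConsequenceCall
from pxdscout.filtering import GenomeObservation, Zygosity
from pxdscout.genome import Variant

# spelled out independently of pxdscout.annotate.AMINO_ACID_ALTERING
ALTERING_CATEGORIES = {
    "missense", "nonsense", "stop_loss", "frameshift", "inframe_indel",
    "splice_donor", "splice_acceptor",
}


def naive_filter(case: GenomeObservation,
                 controls: Sequence[GenomeObservation],
                 annotations: Dict[Variant, ConsequenceCall]) -> Set[Variant]:
    """Triple-loop restatement of the three candidate criteria."""
    kept = set()
    for v, zyg in case.calls.items():
        if zyg.value != "hom_alt":
            continue
        if annotations[v].category.value not in ALTERING_CATEGORIES:
            continue
        seen = False
        for ctl in controls:
            for vc in ctl.calls:
                if (vc.contig, vc.pos, vc.ref, vc.alt) == (v.contig, v.pos, v.ref, v.alt):
                    seen = True
        if not seen:
            kept.add(v)
    return kept


_CATEGORIES = list(Consequence)


def random_mini_study(rng: np.random.Generator,
                      n_pool: int = 60, n_controls: int = 6
                      ) -> Tuple[GenomeObservation, List[GenomeObservation],
                                 Dict[Variant, ConsequenceCall]]:
    """A small random case/control layout over a shared variant pool."""
    pool = [Variant("c1", int(p) + 1, "A", "G")
            for p in rng.choice(10_000, size=n_pool, replace=False)]
    annotations = {
        v: ConsequenceCall(_CATEGORIES[int(rng.integers(len(_CATEGORIES)))],
                           gene_id=f"g{int(rng.integers(10))}")
        for v in pool
    }
    def random_obs(gid, role):
        take = rng.random(n_pool) < 0.4
        calls = {
            v: (Zygosity.HOM_ALT if rng.random() < 0.5 else Zygosity.HET)
            for v, t in zip(pool, take) if t
        }
        return GenomeObservation(gid, role, calls)

    case = random_obs("case1", "case")
    controls = [random_obs(f"ctl{i}", "control") for i in range(n_controls)]
    return case, controls, annotations


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exhaustive fixed-margins Fisher oracle with exact rational arithmetic.

    Enumerates every table compatible with the observed margins, computes
    each table's conditional probability from factorials, and sums those not
    exceeding the observed table's probability.
    """
    n = a + b + c + d
    if n == 0:
        return 1.0
    r, k = a + b, a + c
    fact = [factorial(i) for i in range(n + 1)]
    lo, hi = max(0, r + k - n), min(r, k)
    probs = []
    for x in range(lo, hi + 1):
        cells = (x, r - x, k - x, n - r - k + x)
        probs.append(
            Fraction(fact[r] * fact[n - r] * fact[k] * fact[n - k],
                     fact[n] * fact[cells[0]] * fact[cells[1]]
                     * fact[cells[2]] * fact[cells[3]])
        )
    obs = probs[a - lo]
    return float(min(Fraction(1), sum(p for p in probs if p <= obs)))
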