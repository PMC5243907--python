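"""Multi-genome variant store and the three-criteria candidate filter.

The discovery strategy for a strictly recessive trait: a candidate causal
variant must (1) be predicted to alter the amino-acid sequence of a gene
product (splice-signal variants included), (2) be homozygous for the
alternate allele in the affected genome, and (3) be absent — at any zygosity
— from every control genome in the store.  Candidates from independent
affected genomes are then intersected; with enough controls the intersection
collapses to the causal variant.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import pandas as pd

from .annotate import ConsequenceCall, is_amino_acid_altering
from .genome import InputError, Variant

log = logging.getLogger(__name__)

VariantKey = Tuple[str, int, str, str]


class Zygosity(str, Enum):
    HET = "het"
    HOM_ALT = "hom_alt"


@dataclass
class GenomeObservation:
    """All non-reference calls from one whole-genome sequence."""

    genome_id: str
    role: str  # "case" or "control"
    calls: Dict[Variant, Zygosity] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in ("case", "control"):
            raise InputError(f"role must be 'case' or 'control', got {self.role!r}")

    def hom_alt_variants(self) -> List[Variant]:
        return [v for v, z in self.calls.items() if z is Zygosity.HOM_ALT]


class ControlVariantStore:
    """Embedded index of control-genome variant observations.

    Supports the single query the filter needs: has *any* control genome
    observed this variant, at any zygosity?  Persistable to a JSON file so a
    store can be grown across runs without a database server.
    """

    def __init__(self) -> None:
        self._genomes: Dict[str, GenomeObservation] = {}
        self._index: Dict[VariantKey, Set[str]] = {}

    def __len__(self) -> int:
        return len(self._genomes)

    @property
    def genome_ids(self) -> List[str]:
        return list(self._genomes)

    def add_genome(self, obs: GenomeObservation) -> None:
        if obs.role != "control":
            raise InputError(f"genome {obs.genome_id!r} has role {obs.role!r}, not control")
        if obs.genome_id in self._genomes:
            log.debug("control genome %s already in store; ignoring duplicate", obs.genome_id)
            return
        self._genomes[obs.genome_id] = obs
        for v in obs.calls:
            self._index.setdefault(v.key, set()).add(obs.genome_id)

    def observers(self, v: Variant) -> Set[str]:
        return set(self._index.get(v.key, ()))

    def contains(self, v: Variant) -> bool:
        return v.key in self._index

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        payload = {
            gid: [[*v.key, z.value] for v, z in sorted(obs.calls.items())]
            for gid, obs in sorted(self._genomes.items())
        }
        Path(path).write_text(json.dumps(payload, indent=0, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "ControlVariantStore":
        store = cls()
        payload = json.loads(Path(path).read_text())
        for gid, rows in payload.items():
            calls = {
                Variant(c, int(p), r, a): Zygosity(z) for c, p, r, a, z in rows
            }
            store.add_genome(GenomeObservation(gid, "control", calls))
        return store


@dataclass
class CandidateSet:
    """Variants of one case surviving all three filter criteria."""

    case_id: str
    variants: Dict[Variant, ConsequenceCall]
    n_controls_used: int

    @property
    def genes(self) -> Set[str]:
        return {c.gene_id for c in self.variants.values() if c.gene_id is not None}

    def __len__(self) -> int:
        return len(self.variants)


def filter_candidates(case: GenomeObservation, store: ControlVariantStore,
                      annotations: Mapping[Variant, ConsequenceCall]) -> CandidateSet:
    """Apply the three candidate-causality criteria to one affected genome.

    Retains a variant iff it is amino-acid-altering, called homozygous
    alternate in the case, and never observed in any control genome.
    """
    if case.role != "case":
        raise InputError(f"genome {case.genome_id!r} has role {case.role!r}, not case")
    missing = [v for v in case.calls if v not in annotations]
    if missing:
        shown = ", ".join(f"{v.contig}:{v.pos}{v.ref}>{v.alt}" for v in missing[:5])
        raise InputError(
            f"{len(missing)} case variant(s) lack annotations (e.g. {shown})"
        )
    kept: Dict[Variant, ConsequenceCall] = {}
    for v, zyg in case.calls.items():
        if zyg is not Zygosity.HOM_ALT:
            continue
        call = annotations[v]
        if not is_amino_acid_altering(call):
            continue
        if store.contains(v):
            continue
        kept[v] = call
    return CandidateSet(case.genome_id, kept, n_controls_used=len(store))


def candidate_trajectory(case: GenomeObservation,
                         controls: Sequence[GenomeObservation],
                         annotations: Mapping[Variant, ConsequenceCall]) -> List[int]:
    """Candidate count after each successive control genome is added.

    Reproduces the discovery-time observation that the number of homozygous
    coding variants unique to the affected genome shrinks as the control
    store grows; the sequence is non-increasing by construction.
    """
    store = ControlVariantStore()
    counts: List[int] = []
    for ctl in controls:
        store.add_genome(ctl)
        counts.append(len(filter_candidates(case, store, annotations)))
    return counts


def intersect_cases(sets: Sequence[CandidateSet]) -> CandidateSet:
    """Variants common to every case's candidate set, keyed by (contig, pos, ref, alt)."""
    if len(sets) < 2:
        raise InputError("intersection requires at least two candidate sets")
    common = set(sets[0].variants)
    for s in sets[1:]:
        common &= set(s.variants)
    if not common:
        log.warning("candidate intersection across %d cases is empty", len(sets))
    case_id = "+".join(s.case_id for s in sets)
    variants = {v: sets[0].variants[v] for v in sorted(common)}
    return CandidateSet(case_id, variants,
                        n_controls_used=max(s.n_controls_used for s in sets))


def summarize_candidates(s: CandidateSet) -> Tuple[int, int]:
    """(number of distinct variants, number of distinct genes harbouring them)."""
    return len(s.variants), len(s.genes)


def parse_candidate_table(path: str | Path) -> pd.DataFrame:
    """Read a candidate-variant list (TSV with at least variant + gene columns).

    Accepts the layout this package writes (contig, pos, ref, alt, gene, ...)
    or any table exposing a ``gene`` column plus either explicit variant
    coordinate columns or a ``variant`` identifier column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "gene" not in cols:
        raise InputError(f"candidate table {path} has no 'gene' column")
    if {"contig", "pos", "ref", "alt"} <= set(cols):
        df["_variant_key"] = (
            df[cols["contig"]] + ":" + df[cols["pos"]] + ":"
            + df[cols["ref"]] + ">" + df[cols["alt"]]
        )
    elif "variant" in cols:
        df["_variant_key"] = df[cols["variant"]]
    else:
        raise InputError(f"candidate table {path} has no variant identifier columns")
    df["_gene"] = df[cols["gene"]]
    return df


def count_candidate_table(path: str | Path) -> Tuple[int, int]:
    """(distinct variants, distinct genes) in a candidate-list table."""
    df = parse_candidate_table(path)
    return df["_variant_key"].nunique(), df["_gene"].nunique()
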