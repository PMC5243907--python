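"""Ortholog alignment column analysis at a focal codon.

Given a multiple alignment of orthologous protein segments across species and
the alignment column corresponding to a codon of interest, report the residue
composition of that column and the set of residues observed often enough to
be considered evolutionarily tolerated.  A variant amino acid outside that
set has never been sampled by evolution at the position — circumstantial
evidence of functional constraint.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Set, Tuple

from .genome import InputError

GAP_CHARS = frozenset("-.")


@dataclass(frozen=True)
class OrthologAlignment:
    """Aligned residue strings per species with a 1-based focal column."""

    rows: Tuple[Tuple[str, str], ...]  # (species_name, aligned residues)
    focal_column: int

    def __post_init__(self) -> None:
        rows = tuple((name, seq.upper()) for name, seq in self.rows)
        object.__setattr__(self, "rows", rows)
        lengths = {len(seq) for _, seq in rows}
        if len(lengths) > 1:
            raise InputError(f"ragged alignment: row lengths {sorted(lengths)}")
        if rows:
            width = lengths.pop()
            if not 1 <= self.focal_column <= width:
                raise InputError(
                    f"focal column {self.focal_column} outside alignment width {width}"
                )
        elif self.focal_column < 1:
            raise InputError("focal column must be 1-based positive")

    def __len__(self) -> int:
        return len(self.rows)

    def focal_residues(self) -> List[str]:
        c = self.focal_column - 1
        return [seq[c] for _, seq in self.rows]


@dataclass(frozen=True)
class ColumnComposition:
    counts: Dict[str, int]  # residue -> count, gaps excluded
    n_gaps: int
    n_rows: int


def column_composition(alignment: OrthologAlignment) -> ColumnComposition:
    """Residue counts at the focal column; gap characters tallied separately."""
    residues = alignment.focal_residues()
    counts = Counter(r for r in residues if r not in GAP_CHARS)
    n_gaps = sum(1 for r in residues if r in GAP_CHARS)
    return ColumnComposition(dict(counts), n_gaps, len(residues))


def tolerated_states(alignment: OrthologAlignment, min_count: int = 1) -> Set[str]:
    """Residues seen at least ``min_count`` times at the focal column."""
    if min_count < 1:
        raise InputError("min_count must be >= 1")
    comp = column_composition(alignment)
    return {res for res, n in comp.counts.items() if n >= min_count}


def is_observed_state(alignment: OrthologAlignment, residue: str,
                      min_count: int = 1) -> bool:
    """Whether ``residue`` belongs to the tolerated set at the focal column."""
    return residue.upper() in tolerated_states(alignment, min_count)
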