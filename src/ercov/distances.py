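"""Per-block pairwise evolutionary distances under p, JC69 and K80 models.

A site contributes to a species pair only when both rows carry an unambiguous
base (pairwise deletion of gaps and ``N``).  Transitions are the purine and
pyrimidine exchanges A<->G and C<->T; every other mismatch is a transversion.

Saturated estimates — raw mismatch proportions at or beyond a model's
invertibility bound (p >= 3/4 for JC69, non-positive log arguments for K80)
— are reported as missing rather than clamped, so they cannot inject an
artificial shared signal across blocks.  Entries with fewer than ``min_sites``
comparable sites are likewise missing: distance variance explodes on tiny
site counts and short blocks make that a live concern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .alignment_io import GeneAlignment

__all__ = [
    "SpeciesPair",
    "SiteCounts",
    "PairDistanceTable",
    "comparable_sites",
    "p_distance",
    "jc69_distance",
    "k80_distance",
    "block_distance_table",
    "distance_tables_to_tsv",
    "distance_tables_from_tsv",
    "MODELS",
]

MODELS = ("p", "jc69", "k80")

# code semantics from alignment_io.encode_row: A=0 C=1 G=2 T=3 N=4 -=5
_BASE_MAX = 3


@dataclass(frozen=True, order=True)
class SpeciesPair:
    """Unordered species pair with canonical (lexicographic) member order."""

    a: str
    b: str

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError(f"species pair needs two distinct taxa, got {self.a!r} twice")
        if self.a > self.b:
            a, b = self.a, self.b
            object.__setattr__(self, "a", b)
            object.__setattr__(self, "b", a)

    @classmethod
    def of(cls, x: str, y: str) -> "SpeciesPair":
        return cls(*sorted((x, y)))


@dataclass(frozen=True)
class SiteCounts:
    """Comparable-site tallies for one pair of rows."""

    n_sites: int
    n_mismatch: int
    n_transition: int
    n_transversion: int


def comparable_sites(row_a, row_b) -> SiteCounts:
    """Count comparable sites, mismatches, transitions and transversions.

    Accepts either strings over {A,C,G,T,N,-} or pre-encoded uint8 code
    vectors; rows must have equal length.
    """
    from .alignment_io import encode_row

    a = row_a if isinstance(row_a, np.ndarray) else encode_row(row_a)
    b = row_b if isinstance(row_b, np.ndarray) else encode_row(row_b)
    if a.shape != b.shape:
        raise ValueError(f"row lengths differ: {a.size} vs {b.size}")
    ok = (a <= _BASE_MAX) & (b <= _BASE_MAX)
    diff = ok & (a != b)
    # A(0)<->G(2) and C(1)<->T(3): same parity, absolute code difference 2
    transition = diff & (np.abs(a.astype(np.int8) - b.astype(np.int8)) == 2)
    n_sites = int(ok.sum())
    n_ts = int(transition.sum())
    n_mm = int(diff.sum())
    return SiteCounts(n_sites, n_mm, n_ts, n_mm - n_ts)


def p_distance(counts: SiteCounts) -> float | None:
    """Raw mismatch proportion; ``None`` when no sites are comparable."""
    if counts.n_sites == 0:
        return None
    return counts.n_mismatch / counts.n_sites


def jc69_distance(counts: SiteCounts) -> float | None:
    """Jukes-Cantor 1969 distance, d = -(3/4) ln(1 - 4p/3).

    Returns ``None`` for zero comparable sites or saturation (p >= 3/4).
    """
    if counts.n_sites == 0:
        return None
    p = counts.n_mismatch / counts.n_sites
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def k80_distance(counts: SiteCounts) -> float | None:
    """Kimura 1980 two-parameter distance.

    With transition proportion P and transversion proportion Q,
    d = -(1/2) ln(1 - 2P - Q) - (1/4) ln(1 - 2Q); ``None`` when either log
    argument is non-positive (saturation) or no sites are comparable.
    """
    if counts.n_sites == 0:
        return None
    P = counts.n_transition / counts.n_sites
    Q = counts.n_transversion / counts.n_sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return None
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


_ESTIMATORS = {"p": p_distance, "jc69": jc69_distance, "k80": k80_distance}


@dataclass
class PairDistanceTable:
    """Distances for one block of one gene, keyed by unordered species pair.

    ``entries`` maps each pair to ``(distance, n_sites)``; a missing estimate
    (saturation, or fewer than ``min_sites`` comparable sites) has distance
    ``None`` but keeps its site count for auditability.
    """

    gene_id: str
    block_index: int
    model: str
    entries: dict[SpeciesPair, tuple[float | None, int]]

    def distance(self, pair: SpeciesPair) -> float | None:
        entry = self.entries.get(pair)
        return None if entry is None else entry[0]

    def present_pairs(self) -> list[SpeciesPair]:
        return [p for p, (d, _) in self.entries.items() if d is not None]

    def n_missing(self) -> int:
        return sum(1 for d, _ in self.entries.values() if d is None)


def block_distance_table(
    block_alignment: GeneAlignment,
    model: str = "k80",
    min_sites: int = 30,
    block_index: int = 0,
) -> PairDistanceTable:
    """Compute all unordered pairwise distances for one block alignment.

    For N taxa the table holds N(N-1)/2 entries; entries below ``min_sites``
    comparable sites or with saturated estimates carry a missing distance.
    """
    if model not in _ESTIMATORS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    if block_alignment.n_taxa < 2:
        raise ValueError("need at least 2 taxa to compute pairwise distances")
    est = _ESTIMATORS[model]
    mat = block_alignment.matrix()
    idx = {t: i for i, t in enumerate(block_alignment.taxa)}
    entries: dict[SpeciesPair, tuple[float | None, int]] = {}
    for x, y in combinations(sorted(block_alignment.taxa), 2):
        counts = comparable_sites(mat[idx[x]], mat[idx[y]])
        d = est(counts) if counts.n_sites >= min_sites else None
        entries[SpeciesPair(x, y)] = (d, counts.n_sites)
    return PairDistanceTable(
        gene_id=block_alignment.gene_id,
        block_index=block_index,
        model=model,
        entries=entries,
    )


def distance_tables_to_tsv(tables: Iterable[PairDistanceTable], path: str | Path) -> None:
    """Write distance tables as TSV with columns
    gene, block, species_a, species_b, n_sites, distance, model; missing
    distances are written as empty fields."""
    rows = []
    for tab in tables:
        for pair, (d, n_sites) in sorted(tab.entries.items()):
            rows.append(
                {
                    "gene": tab.gene_id,
                    "block": tab.block_index,
                    "species_a": pair.a,
                    "species_b": pair.b,
                    "n_sites": n_sites,
                    "distance": "" if d is None else format(d, ".10g"),
                    "model": tab.model,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def distance_tables_from_tsv(path: str | Path) -> list[PairDistanceTable]:
    """Inverse of :func:`distance_tables_to_tsv` (missing -> None)."""
    df = pd.read_csv(path, sep="\t", dtype={"distance": str})
    tables: list[PairDistanceTable] = []
    for (gene, block, model), grp in df.groupby(["gene", "block", "model"], sort=True):
        entries: dict[SpeciesPair, tuple[float | None, int]] = {}
        for row in grp.itertuples():
            d = None if pd.isna(row.distance) or row.distance == "" else float(row.distance)
            entries[SpeciesPair(row.species_a, row.species_b)] = (d, int(row.n_sites))
        tables.append(
            PairDistanceTable(gene_id=str(gene), block_index=int(block), model=str(model), entries=entries)
        )
    tables.sort(key=lambda t: (t.gene_id, t.block_index))
    return tables
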