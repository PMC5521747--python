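"""Pearson covariation between all block combinations of two genes.

Each block of each gene carries a vector of relative rates indexed by
unordered species pairs.  The covariation score of block i of gene A with
block j of gene B is the Pearson product-moment correlation of those two
vectors over the species pairs present in both; scores near +1 indicate the
two blocks sped up and slowed down together across the phylogeny — the
signature used to propose physical contact between the encoded regions.

Scores are missing (NaN) when fewer than ``min_pairs`` species pairs are
jointly present, or when either vector is constant over the intersection
(a correlation is undefined there, and reporting 0 would masquerade as
evidence of independence).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .distances import SpeciesPair
from .relative_rates import RelativeRateTable

__all__ = [
    "CovariationMatrix",
    "PeakRegion",
    "pearson",
    "covariation_matrix",
    "find_peak",
    "matrix_to_tsv",
    "matrix_from_tsv",
    "peak_to_json",
    "plot_heatmap",
]


def pearson(
    x_vector: Mapping[SpeciesPair, float | None],
    y_vector: Mapping[SpeciesPair, float | None],
    min_pairs: int = 8,
) -> float | None:
    """Pearson r over pairwise-complete species-pair keys.

    Returns ``None`` below ``min_pairs`` jointly-present entries or when
    either vector is constant over the intersection.
    """
    keys = [
        k
        for k in x_vector
        if x_vector[k] is not None and y_vector.get(k) is not None
    ]
    if len(keys) < max(min_pairs, 2):
        return None
    x = np.array([x_vector[k] for k in keys], dtype=float)
    y = np.array([y_vector[k] for k in keys], dtype=float)
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return None
    r = stats.pearsonr(x, y).statistic
    if math.isnan(r):
        return None
    return float(min(1.0, max(-1.0, r)))


@dataclass
class CovariationMatrix:
    """Blocks-of-A x blocks-of-B Pearson score matrix with missingness.

    ``scores`` holds NaN for missing cells; ``n_pairs_used`` records how many
    species pairs entered each correlation (0 where never computed).
    """

    gene_a: str
    gene_b: str
    scores: np.ndarray
    n_pairs_used: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.scores.shape

    def present_mask(self) -> np.ndarray:
        return ~np.isnan(self.scores)


@dataclass(frozen=True)
class PeakRegion:
    """Argmax cell of the score matrix plus all cells at or above a threshold."""

    cell: tuple[int, int]
    score: float
    members: frozenset[tuple[int, int]]
    threshold: float


def covariation_matrix(
    relrates_a: Sequence[RelativeRateTable],
    relrates_b: Sequence[RelativeRateTable],
    min_pairs: int = 8,
) -> CovariationMatrix:
    """Correlate every block of gene A with every block of gene B.

    Both inputs must have been normalized in the same mode against the same
    reference signature; mixing normalizations silently changes what the
    correlation measures, so it is a hard configuration error.
    """
    if not relrates_a or not relrates_b:
        raise ValueError("need at least one block per gene")
    meta = {(t.mode, t.reference_source) for t in list(relrates_a) + list(relrates_b)}
    if len(meta) > 1:
        raise ValueError(
            f"relative-rate tables disagree on mode/reference: {sorted(meta)}"
        )
    na, nb = len(relrates_a), len(relrates_b)
    scores = np.full((na, nb), np.nan)
    n_used = np.zeros((na, nb), dtype=int)
    for i, ta in enumerate(relrates_a):
        xa = ta.entries
        for j, tb in enumerate(relrates_b):
            xb = tb.entries
            keys = [k for k in xa if xa[k] is not None and xb.get(k) is not None]
            n_used[i, j] = len(keys)
            r = pearson(xa, xb, min_pairs=min_pairs)
            if r is not None:
                scores[i, j] = r
    gene_a = relrates_a[0].gene_id
    gene_b = relrates_b[0].gene_id
    return CovariationMatrix(gene_a=gene_a, gene_b=gene_b, scores=scores, n_pairs_used=n_used)


def find_peak(matrix: CovariationMatrix, peak_threshold: float = 0.8) -> PeakRegion:
    """Locate the maximum-score cell and all cells at or above the threshold.

    Ties at the maximum break to the lexicographically smallest (i, j) so
    repeated runs report the same peak.
    """
    scores = matrix.scores
    present = ~np.isnan(scores)
    if not present.any():
        raise ValueError("all covariation scores are missing; no peak exists")
    best = np.nanmax(scores)
    # argmax with lexicographic tie-break: first True in row-major order
    flat_idx = int(np.flatnonzero(present & (scores == best))[0])
    cell = np.unravel_index(flat_idx, scores.shape)
    members = frozenset(
        (int(i), int(j))
        for i, j in zip(*np.nonzero(present & (scores >= peak_threshold)))
    )
    return PeakRegion(
        cell=(int(cell[0]), int(cell[1])),
        score=float(best),
        members=members,
        threshold=peak_threshold,
    )


def matrix_to_tsv(matrix: CovariationMatrix, path: str | Path) -> None:
    """Write the score matrix as TSV: row index = A blocks, columns = B blocks."""
    na, nb = matrix.shape
    df = pd.DataFrame(
        [
            ["" if np.isnan(v) else format(v, ".10g") for v in row]
            for row in matrix.scores
        ],
        index=[f"{matrix.gene_a}:{i}" for i in range(na)],
        columns=[f"{matrix.gene_b}:{j}" for j in range(nb)],
    )
    df.to_csv(path, sep="\t", index_label="block")


def matrix_from_tsv(path: str | Path) -> CovariationMatrix:
    """Inverse of :func:`matrix_to_tsv` (n_pairs_used is not round-tripped)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    scores = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    gene_a = str(df.index[0]).rsplit(":", 1)[0]
    gene_b = str(df.columns[0]).rsplit(":", 1)[0]
    return CovariationMatrix(
        gene_a=gene_a,
        gene_b=gene_b,
        scores=scores,
        n_pairs_used=np.zeros(scores.shape, dtype=int),
    )


def peak_to_json(peak: PeakRegion, path: str | Path) -> None:
    """Serialize a peak report (cell, score, threshold, member cells)."""
    payload = {
        "cell": list(peak.cell),
        "score": round(peak.score, 10),
        "threshold": peak.threshold,
        "members": sorted(list(c) for c in peak.members),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def plot_heatmap(matrix: CovariationMatrix, path: str | Path) -> None:
    """Render the score matrix with a diverging scale spanning [-1, 1].

    Positive scores plot dark blue, matching the convention that values close
    to +1 flag positively coevolving block pairs.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, matrix.shape[1] / 8), max(3, matrix.shape[0] / 2)))
    im = ax.imshow(matrix.scores, cmap="RdBu", vmin=-1, vmax=1, aspect="auto")
    ax.set_xlabel(f"{matrix.gene_b} blocks")
    ax.set_ylabel(f"{matrix.gene_a} blocks")
    fig.colorbar(im, ax=ax, label="covariation score (Pearson r)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
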