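"""Evaluation statistics for sorted binary matrices.

Four families of scores:

* :func:`overall_me_coverage` — the row-order quality score used to compare
  sorting methods: iterate genes top to bottom, accrue each gene's exclusive
  coverage over the not-yet-deleted submatrix, then delete the gene and its
  mutated samples.
* :func:`joint_entropy` / :func:`topk_pair_entropy` — an independent
  entropy-based pair score: the empirical joint Shannon entropy (in nats) of
  two binary rows.  Mutually exclusive pairs spread probability mass over
  more outcomes than co-occurring pairs of the same marginal, hence score
  higher.
* :func:`run_stats` — run/overlap diagnostics (a run is a maximal block of
  consecutive 1s within a row).
* :func:`rank_pairs` — where known gene pairs land in a row ordering.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .binmat import BinaryMatrix, SortResult

__all__ = [
    "RunStats",
    "overall_me_coverage",
    "joint_entropy",
    "topk_pair_entropy",
    "run_stats",
    "rank_pairs",
    "PairRank",
]


def overall_me_coverage(bm: BinaryMatrix, variant: str = "printed") -> int:
    """Overall mutual-exclusivity coverage of a matrix in its current row order.

    For each gene in row order: with remaining genes ``G_r`` (not yet
    deleted, including the current one) and remaining samples ``S_r``, the
    gene score is ``sum_{s in S_r}(B[g,s] - sum_{g' in G_r, g' != g}
    B[g',s])``; the gene and every remaining sample in which it is mutated
    are then deleted.  The result is the sum of gene scores and may be
    negative.  Column order never enters, so the score is invariant under
    column permutations.
    """
    A = bm.values.astype(np.int64)
    n, m = A.shape
    rows_left = np.ones(n, dtype=bool)
    cols_left = np.ones(m, dtype=bool)
    total_score = 0
    for g in range(n):
        rows_left[g] = False
        if not cols_left.any():
            continue
        own = A[g, cols_left]
        cov = int(own.sum())
        if variant == "printed":
            rest = int(A[np.ix_(rows_left, cols_left)].sum())
            total_score += cov - rest
        elif variant == "restricted":
            competitors = A[np.ix_(rows_left, cols_left)].sum(axis=0)
            total_score += int((own * (1 - competitors)).sum())
        else:
            raise ValueError(f"unknown variant {variant!r}")
        cols_left[cols_left] = own == 0
    return total_score


def joint_entropy(x: Sequence[int] | np.ndarray, y: Sequence[int] | np.ndarray) -> float:
    """Empirical joint Shannon entropy (nats) of two paired binary vectors.

    Plug-in estimator over the four outcomes (0,0), (0,1), (1,0), (1,1) with
    the convention ``0*ln(0) = 0``.  Symmetric in its arguments and bounded
    by ``ln(4)``.
    """
    x = np.asarray(x, dtype=np.int64).ravel()
    y = np.asarray(y, dtype=np.int64).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size == 0:
        raise ValueError("vectors must have length >= 1")
    counts = np.bincount(2 * x + y, minlength=4)
    p = counts[counts > 0] / x.size
    return float(-(p * np.log(p)).sum())


def topk_pair_entropy(
    bm: BinaryMatrix, sortres: SortResult, k: int
) -> tuple[float, dict[tuple[str, str], float]]:
    """Mean joint entropy over all pairs among the first ``k`` sorted rows.

    Returns ``(mean, per_pair)`` where ``per_pair`` maps each of the
    ``C(k, 2)`` unordered pairs (in top-down order) to its joint entropy.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > bm.n_rows:
        raise ValueError(f"k={k} exceeds the number of rows ({bm.n_rows})")
    ridx = {r: i for i, r in enumerate(bm.row_ids)}
    top = list(sortres.row_order[:k])
    per_pair: dict[tuple[str, str], float] = {}
    for ga, gb in combinations(top, 2):
        per_pair[(ga, gb)] = joint_entropy(bm.values[ridx[ga]], bm.values[ridx[gb]])
    mean = float(np.mean(list(per_pair.values())))
    return mean, per_pair


@dataclass(frozen=True)
class RunStats:
    """Run/overlap diagnostics of a matrix in its current orientation."""

    run_counts: Mapping[str, int]
    mean_run_lengths: Mapping[str, float]  # 0.0 for all-zero rows
    consecutive_overlap: int  # columns shared as 1s by vertically adjacent rows


def run_stats(bm: BinaryMatrix) -> RunStats:
    """Count runs per row, their mean length, and vertical overlap.

    A run is a maximal block of consecutive 1s within a row; the overlap is
    ``sum_{i<n} #{j : B[i,j] = B[i+1,j] = 1}``.  Zero overlap means no two
    vertically adjacent rows share a non-zero column.
    """
    A = bm.values
    run_counts: dict[str, int] = {}
    mean_lengths: dict[str, float] = {}
    for i, rid in enumerate(bm.row_ids):
        row = A[i]
        starts = int(((row[1:] == 1) & (row[:-1] == 0)).sum()) + int(row[0] == 1)
        run_counts[rid] = starts
        mean_lengths[rid] = float(row.sum() / starts) if starts else 0.0
    overlap = int(((A[:-1] == 1) & (A[1:] == 1)).sum()) if bm.n_rows > 1 else 0
    return RunStats(run_counts, mean_lengths, overlap)


@dataclass(frozen=True)
class PairRank:
    """Placement of one gene pair in a row ordering."""

    pair: tuple[str, str]
    best_rank: int | None  # max of the two 1-based positions; None if missing
    in_top_k: bool
    missing: tuple[str, ...] = ()


def rank_pairs(
    sortres: SortResult, pairs: Sequence[tuple[str, str]], k: int
) -> list[PairRank]:
    """Rank gene pairs by their worse member's position in a row order.

    A pair only becomes visible in the top ``k`` rows when *both* members are
    there, so ``best_rank`` is the max of the two 1-based positions.  Pairs
    with members absent from the ordering are flagged, not fatal.
    """
    if k < 1:
        raise ValueError("k must be positive")
    pos = {g: i + 1 for i, g in enumerate(sortres.row_order)}
    out: list[PairRank] = []
    for ga, gb in pairs:
        missing = tuple(g for g in (ga, gb) if g not in pos)
        if missing:
            out.append(PairRank((ga, gb), None, False, missing))
        else:
            best = max(pos[ga], pos[gb])
            out.append(PairRank((ga, gb), best, best <= k))
    return out
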