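"""Two-phase greedy heuristic for mutual-exclusivity sorting of a binary matrix.

The exact problem — reordering rows and columns so that runs of consecutive
non-zero entries are long and do not overlap vertically — is NP-hard, so the
sorter is a deterministic greedy heuristic in two phases:

Phase 1 (row ordering).  All genes and samples start *uncovered*.  While
uncovered genes and uncovered samples both remain, the *best-in-class* gene
``g*`` is the uncovered gene maximizing its exclusive coverage

    score(g) = sum over uncovered samples s of
               ( B[g, s] - sum over other uncovered genes g' of B[g', s] )

``g*`` is appended to the covered-gene vector G* and every uncovered sample
in which it is mutated becomes covered.  If samples run out before genes,
the remaining genes are appended in their original order.

Phase 2 (column ordering).  Samples are reset to uncovered.  Genes are
visited in G* order; for each gene its uncovered mutated samples are sorted
by decreasing per-sample exclusive coverage

    L_s = B[g, s] * (1 - sum over other genes g' of B[g', s])

and appended to the column vector L.  Columns never claimed (e.g. all-zero
columns) are appended last in original order.

Both phases are deterministic: ties are broken by original row/column
position.  The printed phase-1 score equals ``2*cov(g) - T`` where ``cov(g)``
is the number of uncovered samples with a 1 in row ``g`` and ``T`` the total
number of 1s in the uncovered submatrix; the subtraction term is constant in
``g``, so the argmax coincides with the most-covering gene.  A *restricted*
variant, where the penalty only counts samples in which ``g`` itself is
mutated (mirroring the phase-2 formula), is available via ``bic_variant``.
"""

from __future__ import annotations

from typing import Iterable, Literal, Sequence

import numpy as np

from .binmat import BinaryMatrix, SortResult

__all__ = [
    "best_in_class_score",
    "select_rows",
    "sample_exclusive_coverage",
    "order_columns",
    "mutex_sort",
]

BicVariant = Literal["printed", "restricted"]


def _ids_to_indices(ids: Iterable[str], index: dict[str, int], what: str) -> np.ndarray:
    out = []
    for i in ids:
        if i not in index:
            raise KeyError(f"unknown {what} id: {i!r}")
        out.append(index[i])
    return np.asarray(out, dtype=np.intp)


def best_in_class_score(
    bm: BinaryMatrix,
    g: str,
    uncovered_genes: Iterable[str],
    uncovered_samples: Iterable[str],
    variant: BicVariant = "printed",
) -> int:
    """Exclusive-coverage score of uncovered gene ``g`` (phase-1 objective).

    With ``variant='printed'`` the score is the sum over all uncovered
    samples of ``B[g,s]`` minus the entries of every other uncovered gene;
    with ``variant='restricted'`` the penalty is only accrued in samples
    where ``g`` itself is mutated.  May be negative.
    """
    ridx = {r: i for i, r in enumerate(bm.row_ids)}
    cidx = {c: j for j, c in enumerate(bm.col_ids)}
    gi = ridx.get(g)
    if gi is None:
        raise KeyError(f"unknown row id: {g!r}")
    rows = _ids_to_indices(uncovered_genes, ridx, "row")
    cols = _ids_to_indices(uncovered_samples, cidx, "column")
    if gi not in rows:
        raise ValueError(f"gene {g!r} is not in the uncovered set")
    sub = bm.values[np.ix_(rows, cols)].astype(np.int64)
    own = bm.values[gi, cols].astype(np.int64)
    if variant == "printed":
        competitors = sub.sum(axis=0) - own
        return int((own - competitors).sum())
    if variant == "restricted":
        competitors = sub.sum(axis=0) - own
        return int((own * (1 - competitors)).sum())
    raise ValueError(f"unknown variant {variant!r}")


def select_rows(bm: BinaryMatrix, variant: BicVariant = "printed") -> list[str]:
    """Phase 1: greedy best-in-class row ordering (the covered-gene vector G*).

    Ties on the score are broken by smallest original row index; when the
    uncovered samples are exhausted first, the remaining genes are appended
    in original row order.
    """
    A = bm.values.astype(np.int64)
    n, m = A.shape
    uncovered_rows = np.ones(n, dtype=bool)
    uncovered_cols = np.ones(m, dtype=bool)
    order: list[int] = []
    while uncovered_rows.any() and uncovered_cols.any():
        cov = A[:, uncovered_cols].sum(axis=1)
        if variant == "printed":
            total = int(cov[uncovered_rows].sum())
            scores = 2 * cov - total
        else:
            colsum = A[uncovered_rows][:, uncovered_cols].sum(axis=0)
            penalty = A[:, uncovered_cols] @ colsum - cov  # competitors in g's own samples
            scores = cov - penalty
        cand = np.flatnonzero(uncovered_rows)
        g = int(cand[np.argmax(scores[cand])])  # argmax is stable: first max wins
        order.append(g)
        uncovered_rows[g] = False
        uncovered_cols &= A[g] == 0
    order.extend(int(i) for i in np.flatnonzero(uncovered_rows))
    return [bm.row_ids[i] for i in order]


def sample_exclusive_coverage(
    bm: BinaryMatrix, g: str, s: str, gene_queue: Sequence[str]
) -> int:
    """Phase-2 per-sample score ``L_s = B[g,s] * (1 - sum_{g' != g} B[g',s])``.

    Zero whenever ``g`` is not mutated in ``s``; equal to 1 when ``g`` is the
    only gene of the queue mutated in ``s``; negative when several
    competitors share the sample.
    """
    ridx = {r: i for i, r in enumerate(bm.row_ids)}
    gi = ridx.get(g)
    if gi is None:
        raise KeyError(f"unknown row id: {g!r}")
    if g not in gene_queue:
        raise ValueError(f"gene {g!r} is not in the gene queue")
    sj = bm.col_index(s)
    rows = _ids_to_indices(gene_queue, ridx, "row")
    colsum = int(bm.values[rows, sj].sum())
    own = int(bm.values[gi, sj])
    return own * (1 - (colsum - own))


def order_columns(bm: BinaryMatrix, gstar: Sequence[str]) -> list[str]:
    """Phase 2: assemble the column order L by visiting genes in G* order.

    For each gene, its still-uncovered mutated samples are appended sorted by
    decreasing exclusive coverage (ties in original column order); leftover
    columns (never claimed, e.g. all-zero ones) are appended last in
    original order.
    """
    if sorted(gstar) != sorted(bm.row_ids):
        raise ValueError("gstar is not a permutation of the matrix row ids")
    A = bm.values.astype(np.int64)
    m = A.shape[1]
    # competitor sum runs over the whole queue, so the per-sample score for a
    # mutated sample reduces to 2 - (full column marginal)
    colsum = A.sum(axis=0)
    uncovered = np.ones(m, dtype=bool)
    ridx = {r: i for i, r in enumerate(bm.row_ids)}
    L: list[int] = []
    for g in gstar:
        if not uncovered.any():
            break
        gi = ridx[g]
        cand = np.flatnonzero(uncovered & (A[gi] == 1))
        if cand.size == 0:
            continue
        keys = 2 - colsum[cand]
        take = cand[np.argsort(-keys, kind="stable")]
        L.extend(int(j) for j in take)
        uncovered[cand] = False
    L.extend(int(j) for j in np.flatnonzero(uncovered))
    return [bm.col_ids[j] for j in L]


def mutex_sort(bm: BinaryMatrix, variant: BicVariant = "printed") -> SortResult:
    """Run both phases and return the resulting row/column orders.

    Deterministic: repeated runs on the same matrix give identical results.
    Overall complexity is O(n^2 m + n m log m) for an n x m matrix.
    """
    rows = select_rows(bm, variant=variant)
    cols = order_columns(bm, rows)
    return SortResult("mutex", tuple(rows), tuple(cols), source=bm.fingerprint())
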