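"""MEMo-style matrix sorting, used as a comparator method.

Rows are sorted by decreasing marginal (number of non-zero entries).  Columns
are then sorted by decreasing value of their 0/1 pattern read top-to-bottom
under the new row order as a number in binary notation — the top row is the
most significant bit, so a 1 near the top of the matrix outweighs any number
of 1s below it.  Comparison is done lexicographically on the bit sequences,
which is equivalent to comparing the (up to 2^n-scale) integers without ever
materializing them.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .binmat import BinaryMatrix, SortResult

__all__ = ["memo_row_order", "memo_col_key", "memo_sort"]


def memo_row_order(bm: BinaryMatrix) -> list[str]:
    """Rows by decreasing marginal; ties keep original order (stable sort)."""
    marg = bm.values.sum(axis=1)
    order = np.argsort(-marg, kind="stable")
    return [bm.row_ids[i] for i in order]


def memo_col_key(bm: BinaryMatrix, row_order: Sequence[str], s: str) -> tuple[int, ...]:
    """Column pattern under ``row_order`` as a lexicographically comparable key.

    Comparing two keys with tuple comparison is equivalent to comparing the
    big integers ``sum_i B[i, s] * 2**(n - i)`` (first row of ``row_order``
    most significant), for any number of rows.
    """
    if sorted(row_order) != sorted(bm.row_ids):
        raise ValueError("row_order is not a permutation of the matrix row ids")
    ridx = {r: i for i, r in enumerate(bm.row_ids)}
    sj = bm.col_index(s)
    return tuple(int(bm.values[ridx[g], sj]) for g in row_order)


def memo_sort(bm: BinaryMatrix) -> SortResult:
    """Full MEMo sort: marginal-ordered rows, binary-notation-ordered columns.

    Column ties (identical patterns) keep their original relative order.
    Deterministic.
    """
    rows = memo_row_order(bm)
    ridx = {r: i for i, r in enumerate(bm.row_ids)}
    perm = np.asarray([ridx[g] for g in rows], dtype=np.intp)
    patterns = bm.values[perm]  # n x m, row 0 = most significant bit
    # stable sort on reversed-significance rows: np.lexsort keys are last-first
    order = np.lexsort(np.vstack([np.arange(bm.n_cols), -patterns[::-1]]))
    cols = [bm.col_ids[j] for j in order]
    return SortResult("memo", tuple(rows), tuple(cols), source=bm.fingerprint())
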