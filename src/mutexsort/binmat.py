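"""Binary-matrix data model, validation, delimited-file I/O and permutation utilities.

A :class:`BinaryMatrix` is a dense 0/1 matrix whose rows are genes (or any
binary features) and whose columns are samples.  Every sorting algorithm in
this package consumes and produces this object.  Identifiers are opaque
strings; row/column orders are always expressed as sequences of ids, never
as integer coordinates.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BinaryMatrix",
    "SortResult",
    "MatrixFormatError",
    "read_matrix",
    "write_matrix",
    "permute_matrix",
    "marginals",
]


class MatrixFormatError(ValueError):
    """Raised when a delimited file does not encode a valid binary matrix."""


_TOKEN_MAP = {"0": 0, "1": 1, "true": 1, "false": 0}


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise MatrixFormatError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass(frozen=True)
class BinaryMatrix:
    """A named 0/1 matrix with unique row (gene) and column (sample) ids.

    Parameters
    ----------
    row_ids, col_ids
        Ordered, pairwise-distinct identifiers.
    values
        Array of shape ``(len(row_ids), len(col_ids))`` containing only 0/1.
        The array is copied and frozen at construction; marginals are always
        derived from it, never cached.
    """

    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __init__(self, row_ids: Iterable[str], col_ids: Iterable[str], values) -> None:
        object.__setattr__(self, "row_ids", tuple(str(r) for r in row_ids))
        object.__setattr__(self, "col_ids", tuple(str(c) for c in col_ids))
        arr = np.asarray(values)
        if arr.ndim != 2:
            raise MatrixFormatError(f"expected a 2-D array, got ndim={arr.ndim}")
        if arr.shape[0] == 0 or arr.shape[1] == 0:
            raise MatrixFormatError("empty matrices (n=0 or m=0) are not supported")
        if arr.shape != (len(self.row_ids), len(self.col_ids)):
            raise MatrixFormatError(
                f"shape {arr.shape} does not match {len(self.row_ids)} row ids "
                f"x {len(self.col_ids)} col ids"
            )
        _check_unique(self.row_ids, "row")
        _check_unique(self.col_ids, "column")
        if not np.isin(arr, (0, 1)).all():
            bad = np.argwhere(~np.isin(arr, (0, 1)))[0]
            raise MatrixFormatError(
                f"non-binary entry {arr[bad[0], bad[1]]!r} at row "
                f"{self.row_ids[bad[0]]!r}, column {self.col_ids[bad[1]]!r}"
            )
        arr = arr.astype(np.int8, copy=True)
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)

    # -- basic geometry -------------------------------------------------
    @property
    def n_rows(self) -> int:
        return len(self.row_ids)

    @property
    def n_cols(self) -> int:
        return len(self.col_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def density(self) -> float:
        """Fraction of non-zero entries."""
        return float(self.values.sum()) / (self.n_rows * self.n_cols)

    def row_index(self, row_id: str) -> int:
        try:
            return self.row_ids.index(row_id)
        except ValueError:
            raise KeyError(f"unknown row id: {row_id!r}") from None

    def col_index(self, col_id: str) -> int:
        try:
            return self.col_ids.index(col_id)
        except ValueError:
            raise KeyError(f"unknown column id: {col_id!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.asarray(self.values), index=list(self.row_ids), columns=list(self.col_ids)
        )

    def fingerprint(self) -> str:
        """Stable hex digest of ids and entries, used for SortResult provenance."""
        h = hashlib.sha256()
        h.update("\x1f".join(self.row_ids).encode())
        h.update(b"\x1e")
        h.update("\x1f".join(self.col_ids).encode())
        h.update(b"\x1e")
        h.update(np.ascontiguousarray(self.values).tobytes())
        return h.hexdigest()[:16]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryMatrix):
            return NotImplemented
        return (
            self.row_ids == other.row_ids
            and self.col_ids == other.col_ids
            and np.array_equal(self.values, other.values)
        )


SortMethod = Literal["mutex", "memo", "random", "identity"]
_METHODS = ("mutex", "memo", "random", "identity")


@dataclass(frozen=True)
class SortResult:
    """A row and column permutation of a matrix, tagged with its origin.

    ``row_order`` and ``col_order`` are sequences of ids (not indices); each
    must be a bijection on the source matrix's ids.  ``source`` holds the
    fingerprint of the matrix the orders were derived from.
    """

    method: str
    row_order: tuple[str, ...]
    col_order: tuple[str, ...]
    source: str = ""

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {_METHODS}")
        object.__setattr__(self, "row_order", tuple(self.row_order))
        object.__setattr__(self, "col_order", tuple(self.col_order))
        _check_unique(self.row_order, "row-order")
        _check_unique(self.col_order, "column-order")

    def to_json(self) -> str:
        return json.dumps(
            {
                "method": self.method,
                "row_order": list(self.row_order),
                "col_order": list(self.col_order),
                "source": self.source,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SortResult":
        d = json.loads(text)
        return cls(d["method"], d["row_order"], d["col_order"], d.get("source", ""))

    def to_text(self) -> str:
        """Two-section plain-text serialization: ordered row ids, blank line, col ids."""
        return "\n".join(self.row_order) + "\n\n" + "\n".join(self.col_order) + "\n"

    @classmethod
    def from_text(cls, text: str, method: str = "identity") -> "SortResult":
        head, _, tail = text.strip("\n").partition("\n\n")
        rows = [r for r in head.splitlines() if r]
        cols = [c for c in tail.splitlines() if c]
        return cls(method, rows, cols)


# -- I/O ----------------------------------------------------------------

def _parse_token(tok: str, row: str, col: str):
    v = _TOKEN_MAP.get(str(tok).strip().lower())
    if v is None:
        raise MatrixFormatError(
            f"non-binary token {tok!r} at row {row!r}, column {col!r}"
        )
    return v


def read_matrix(
    path: str | Path,
    delimiter: str = "\t",
    named: bool = True,
) -> BinaryMatrix:
    """Read a binary matrix from a delimited UTF-8 text file.

    The expected layout is a header row of sample (column) ids and a first
    field per subsequent line holding the gene (row) id.  Cell tokens may be
    ``0``, ``1``, ``TRUE`` or ``FALSE`` (case-insensitive).  With
    ``named=False`` the file is a bare table of cells and ids default to
    positional labels ``R1..Rn`` / ``C1..Cm``.
    """
    path = Path(path)
    rows: list[list[str]] = []
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n").rstrip("\r")
            if line == "":
                continue
            rows.append(line.split(delimiter))
    if not rows:
        raise MatrixFormatError(f"{path}: empty file")

    if named:
        header = rows[0]
        body = rows[1:]
        if not body:
            raise MatrixFormatError(f"{path}: no data rows below the header")
        # tolerate a leading corner label when header has m+1 fields
        width = len(body[0])
        if len(header) == width:
            col_ids = header[1:]
        elif len(header) == width - 1:
            col_ids = header
        else:
            raise MatrixFormatError(
                f"{path}: header has {len(header)} fields but data rows have {width}"
            )
        row_ids = [r[0] for r in body]
        cells = [r[1:] for r in body]
    else:
        cells = rows
        row_ids = [f"R{i + 1}" for i in range(len(cells))]
        col_ids = [f"C{j + 1}" for j in range(len(cells[0]))]

    width = len(cells[0])
    for i, r in enumerate(cells):
        if len(r) != width:
            raise MatrixFormatError(
                f"{path}: ragged row {row_ids[i]!r} ({len(r)} fields, expected {width})"
            )
    if width != len(col_ids):
        raise MatrixFormatError(
            f"{path}: {len(col_ids)} column ids but {width} data fields per row"
        )
    data = np.array(
        [
            [_parse_token(tok, row_ids[i], col_ids[j]) for j, tok in enumerate(r)]
            for i, r in enumerate(cells)
        ],
        dtype=np.int8,
    )
    return BinaryMatrix(row_ids, col_ids, data)


def write_matrix(
    bm: BinaryMatrix,
    path: str | Path,
    delimiter: str = "\t",
    named: bool = True,
) -> None:
    """Write a matrix as delimited UTF-8 text (inverse of :func:`read_matrix`)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if named:
            fh.write(delimiter.join(("", *bm.col_ids)) + "\n")
        for i, rid in enumerate(bm.row_ids):
            cells = (str(int(v)) for v in bm.values[i])
            if named:
                fh.write(delimiter.join((rid, *cells)) + "\n")
            else:
                fh.write(delimiter.join(cells) + "\n")


# -- permutation & marginals -------------------------------------------

def permute_matrix(bm: BinaryMatrix, r: SortResult) -> BinaryMatrix:
    """Apply a :class:`SortResult` to a matrix, reordering rows and columns.

    ``r.row_order`` / ``r.col_order`` must be permutations of the matrix's
    ids; the output entry at ``[i, j]`` is the input entry at
    ``(row_order[i], col_order[j])``.
    """
    if set(r.row_order) != set(bm.row_ids) or len(r.row_order) != bm.n_rows:
        raise MatrixFormatError("row_order is not a permutation of the matrix row ids")
    if set(r.col_order) != set(bm.col_ids) or len(r.col_order) != bm.n_cols:
        raise MatrixFormatError("col_order is not a permutation of the matrix column ids")
    ridx = {g: i for i, g in enumerate(bm.row_ids)}
    cidx = {s: j for j, s in enumerate(bm.col_ids)}
    ri = np.fromiter((ridx[g] for g in r.row_order), dtype=np.intp, count=bm.n_rows)
    ci = np.fromiter((cidx[s] for s in r.col_order), dtype=np.intp, count=bm.n_cols)
    return BinaryMatrix(r.row_order, r.col_order, bm.values[np.ix_(ri, ci)])


def marginals(bm: BinaryMatrix, axis: Literal["rows", "cols"]) -> Mapping[str, int]:
    """Counts of 1s per row (``axis='rows'``) or per column (``axis='cols'``)."""
    if axis == "rows":
        sums = bm.values.sum(axis=1)
        return {g: int(s) for g, s in zip(bm.row_ids, sums)}
    if axis == "cols":
        sums = bm.values.sum(axis=0)
        return {c: int(s) for c, s in zip(bm.col_ids, sums)}
    raise ValueError(f"axis must be 'rows' or 'cols', got {axis!r}")
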