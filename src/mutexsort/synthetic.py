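"""Seeded generators for the matrix classes used in benchmarking.

Three input classes:

* :func:`random_bm` — iid Bernoulli background matrices of prescribed
  density (optionally with an exact count of 1s placed uniformly at random);
* :func:`shuffled_diagonal` — a row/column-shuffled identity (permutation)
  matrix, the heuristic sorter's worst case: one 1 per row and column, so
  each greedy iteration covers a single row and a single column;
* :func:`inject_patterns` — a background matrix injected with a set of rows
  with pairwise column-disjoint supports (mutual exclusivity) and a set of
  rows sharing a common support core (co-occurrence), with ground-truth row
  labels, emulating driver-gene patterns buried in passenger noise.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .binmat import BinaryMatrix

__all__ = ["SyntheticSpec", "random_bm", "shuffled_diagonal", "inject_patterns"]


def _row_ids(n: int) -> list[str]:
    return [f"g{i + 1}" for i in range(n)]


def _col_ids(m: int) -> list[str]:
    return [f"s{j + 1}" for j in range(m)]


def random_bm(
    n: int,
    m: int,
    density: float,
    seed: int,
    exact_count: bool = False,
) -> BinaryMatrix:
    """Random binary matrix of the given density.

    By default each entry is independently 1 with probability ``density``.
    With ``exact_count=True``, exactly ``floor(n*m*density)`` ones are placed
    uniformly at random instead (useful for variance-sensitive tests).
    """
    if not 0.0 <= density <= 1.0:
        raise ValueError(f"density must be in [0, 1], got {density}")
    if n < 1 or m < 1:
        raise ValueError("matrix dimensions must be positive")
    rng = np.random.default_rng(seed)
    if exact_count:
        ones = int(math.floor(n * m * density))
        flat = np.zeros(n * m, dtype=np.int8)
        flat[rng.choice(n * m, size=ones, replace=False)] = 1
        vals = flat.reshape(n, m)
    else:
        vals = (rng.random((n, m)) < density).astype(np.int8)
    return BinaryMatrix(_row_ids(n), _col_ids(m), vals)


def shuffled_diagonal(n: int, seed: int) -> BinaryMatrix:
    """Shuffled n x n permutation matrix: exactly one 1 per row and column."""
    if n < 1:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    vals = np.zeros((n, n), dtype=np.int8)
    vals[np.arange(n), perm] = 1
    return BinaryMatrix(_row_ids(n), _col_ids(n), vals)


def _default_me_ones(m: int, n_me: int) -> int:
    # disjoint supports partition the full sample set
    return m // n_me if n_me else 0


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of an injected-pattern matrix.

    Defaults follow the benchmark design: a 1000 x 1000 background with 10
    mutually exclusive and 10 co-occurrent injected rows.  Counts left at
    ``None`` are derived from the matrix geometry: ``me_ones = m // n_me``,
    so the disjoint ME supports partition the whole sample set (the
    strongest form of exclusivity, and the densest 10 disjoint rows can
    be); co-occurrent rows carry the *same* marginal as ME rows with ~90%
    of it in the shared core (``cooc_noise = max(1, me_ones // 10)``,
    ``cooc_core = me_ones - cooc_noise``), so that comparing ME and cooc
    pairs isolates exclusivity versus overlap rather than density.
    """

    n: int = 1000
    m: int = 1000
    density: float = 0.01
    n_me: int = 10
    me_ones: int | None = None
    n_cooc: int = 10
    cooc_core: int | None = None
    cooc_noise: int | None = None
    seed: int = 0

    def resolved(self) -> "SyntheticSpec":
        """Fill derived defaults and validate feasibility."""
        me_ones = self.me_ones if self.me_ones is not None else _default_me_ones(self.m, self.n_me)
        if self.cooc_noise is not None:
            noise = self.cooc_noise
        elif self.cooc_core is not None:
            noise = math.ceil(self.cooc_core / 10)
        else:
            noise = max(1, me_ones // 10)
        core = self.cooc_core if self.cooc_core is not None else max(me_ones - noise, 1)
        spec = SyntheticSpec(
            self.n, self.m, self.density, self.n_me, me_ones, self.n_cooc, core, noise, self.seed
        )
        if not 0.0 <= spec.density <= 1.0:
            raise ValueError(f"density must be in [0, 1], got {spec.density}")
        if spec.n_me + spec.n_cooc > spec.n:
            raise ValueError(
                f"injected rows ({spec.n_me} + {spec.n_cooc}) exceed n = {spec.n}"
            )
        if spec.n_me and spec.n_me * spec.me_ones > spec.m:
            raise ValueError(
                f"disjoint supports do not fit: n_me * me_ones = "
                f"{spec.n_me * spec.me_ones} > m = {spec.m}"
            )
        if spec.n_cooc and spec.cooc_core + spec.cooc_noise > spec.m:
            raise ValueError(
                f"cooc_core + cooc_noise = {spec.cooc_core + spec.cooc_noise} "
                f"> m = {spec.m}"
            )
        return spec


RowLabel = Literal["me", "cooc", "background"]


def inject_patterns(spec: SyntheticSpec) -> tuple[BinaryMatrix, dict[str, RowLabel]]:
    """Generate a background matrix with injected ME and co-occurrent rows.

    ME rows receive ``me_ones`` 1s each in pairwise-disjoint random sample
    subsets; co-occurrent rows share a common random core of ``cooc_core``
    samples plus ``cooc_noise`` private random extra 1s each; all other rows
    are iid Bernoulli(density).  Row placement within the matrix is
    randomized.  Returns the matrix and a ground-truth map row id -> label.
    """
    spec = spec.resolved()
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n, spec.m
    vals = np.zeros((n, m), dtype=np.int8)

    patterns = np.zeros((spec.n_me + spec.n_cooc, m), dtype=np.int8)
    if spec.n_me:
        chosen = rng.choice(m, size=spec.n_me * spec.me_ones, replace=False)
        for i in range(spec.n_me):
            patterns[i, chosen[i * spec.me_ones : (i + 1) * spec.me_ones]] = 1
    if spec.n_cooc:
        core = rng.choice(m, size=spec.cooc_core, replace=False)
        rest = np.setdiff1d(np.arange(m), core)
        for i in range(spec.n_cooc):
            row = patterns[spec.n_me + i]
            row[core] = 1
            if spec.cooc_noise:
                row[rng.choice(rest, size=spec.cooc_noise, replace=False)] = 1

    slots = rng.choice(n, size=spec.n_me + spec.n_cooc, replace=False)
    labels_arr = np.array(["background"] * n, dtype=object)
    for k, slot in enumerate(slots):
        vals[slot] = patterns[k]
        labels_arr[slot] = "me" if k < spec.n_me else "cooc"
    background = labels_arr == "background"
    vals[background] = (rng.random((int(background.sum()), m)) < spec.density).astype(np.int8)

    row_ids = _row_ids(n)
    labels: dict[str, RowLabel] = {row_ids[i]: labels_arr[i] for i in range(n)}
    return BinaryMatrix(row_ids, _col_ids(m), vals), labels
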