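"""Benchmark harness: sweep sizes and densities, compare sorting methods.

Runs the competing sorters ({mutex, memo, random, identity}) over seeded
replicate matrices, scores each output (overall mutual-exclusivity coverage,
or mean top-k pairwise joint entropy), and tests paired per-replicate score
differences with a one-sided Wilcoxon signed-rank test.  The random baseline
shuffles rows only, leaving columns fixed.  Everything is reproducible from
the master seed.
"""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .binmat import BinaryMatrix, SortResult, permute_matrix
from .memo_sort import memo_sort
from .mutex_sort import mutex_sort
from .scoring import overall_me_coverage, topk_pair_entropy
from .synthetic import SyntheticSpec, inject_patterns, random_bm

__all__ = [
    "PairedTest",
    "paired_onesided_p",
    "SweepConfig",
    "ComparisonReport",
    "compare_methods",
    "timing_sweep",
    "random_sort",
    "identity_sort",
    "me_recovery_rate",
]


# -- baseline sorters ---------------------------------------------------

def identity_sort(bm: BinaryMatrix) -> SortResult:
    """No-op sorter: original row and column orders."""
    return SortResult("identity", bm.row_ids, bm.col_ids, source=bm.fingerprint())


def random_sort(bm: BinaryMatrix, seed: int) -> SortResult:
    """Random baseline: shuffle rows uniformly, keep columns fixed."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(bm.n_rows)
    rows = tuple(bm.row_ids[i] for i in perm)
    return SortResult("random", rows, bm.col_ids, source=bm.fingerprint())


# -- paired test --------------------------------------------------------

@dataclass(frozen=True)
class PairedTest:
    """One-sided paired test result for H1: left scores > right scores."""

    p: float
    n_nonzero: int
    degenerate: bool  # all paired differences were zero


def paired_onesided_p(
    left: Sequence[float],
    right: Sequence[float],
    method: Literal["wilcoxon", "signflip"] = "wilcoxon",
    exact_threshold: int = 25,
    seed: int = 0,
) -> PairedTest:
    """One-sided paired p-value for H1: ``left > right``.

    Default is the Wilcoxon signed-rank test with zero differences dropped:
    exact null distribution for up to ``exact_threshold`` non-zero
    differences, normal approximation with continuity correction above.
    ``method='signflip'`` uses an exact/Monte-Carlo permutation sign-flip
    test on the mean difference instead.  When every difference is zero the
    result is degenerate with p = 1.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape:
        raise ValueError("score vectors must have equal length")
    if left.size < 5:
        raise ValueError("need at least 5 paired scores")
    diffs = left - right
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        return PairedTest(1.0, 0, True)
    if method == "wilcoxon":
        mode = "exact" if nonzero.size <= exact_threshold else "approx"
        res = stats.wilcoxon(
            nonzero, alternative="greater", method=mode, correction=(mode == "approx")
        )
        return PairedTest(float(res.pvalue), int(nonzero.size), False)
    if method == "signflip":
        res = stats.permutation_test(
            (nonzero,),
            np.mean,
            permutation_type="samples",
            alternative="greater",
            n_resamples=100_000,
            rng=np.random.default_rng(seed),
        )
        return PairedTest(float(res.pvalue), int(nonzero.size), False)
    raise ValueError(f"unknown method {method!r}")


# -- sweep configuration ------------------------------------------------

@dataclass(frozen=True)
class SweepConfig:
    """Configuration of a method-comparison sweep.

    ``methods`` are compared pairwise in the given order (each method
    against the next), so list them from the expected best to the baseline.
    ``mode='random'`` scores iid background matrices; ``mode='inject'``
    scores matrices with injected ME/co-occurrence patterns.
    """

    sizes: tuple[int, ...] = (100,)
    densities: tuple[float, ...] = (0.05, 0.1, 0.25, 0.5)
    reps: int = 50
    methods: tuple[str, ...] = ("mutex", "memo", "identity")
    metric: Literal["coverage", "entropy"] = "coverage"
    top_k: int = 10
    seed: int = 0
    mode: Literal["random", "inject"] = "random"
    n_me: int = 10
    n_cooc: int = 10
    test_method: Literal["wilcoxon", "signflip"] = "wilcoxon"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sizes", tuple(self.sizes))
        object.__setattr__(self, "densities", tuple(self.densities))
        object.__setattr__(self, "methods", tuple(self.methods))
        if self.reps < 5:
            raise ValueError("reps must be at least 5")
        if len(self.methods) < 2:
            raise ValueError("need at least two methods to compare")


@dataclass(frozen=True)
class ComparisonReport:
    """Per-replicate scores, paired p-values and win fractions of a sweep."""

    config: SweepConfig
    scores: pd.DataFrame  # columns: size, density, replicate, method, score
    pvalues: pd.DataFrame  # columns: size, density, left, right, p, win_fraction, ...
    timings: pd.DataFrame  # columns: size, density, method, mean_s, total_s

    def to_json_dict(self) -> dict:
        return {
            "config": asdict(self.config),
            "scores": self.scores.to_dict(orient="records"),
            "pvalues": self.pvalues.to_dict(orient="records"),
            "timings": self.timings.to_dict(orient="records"),
        }


def _derive_seed(master: int, *key: int) -> int:
    ss = np.random.SeedSequence([int(master), *[int(k) for k in key]])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _make_matrix(cfg: SweepConfig, size: int, density: float, seed: int):
    if cfg.mode == "random":
        return random_bm(size, size, density, seed), None
    spec = SyntheticSpec(
        n=size, m=size, density=density, n_me=cfg.n_me, n_cooc=cfg.n_cooc, seed=seed
    )
    return inject_patterns(spec)


def _apply_method(bm: BinaryMatrix, method: str, seed: int) -> SortResult:
    if method == "mutex":
        return mutex_sort(bm)
    if method == "memo":
        return memo_sort(bm)
    if method == "identity":
        return identity_sort(bm)
    if method == "random":
        return random_sort(bm, seed)
    raise ValueError(f"unknown method {method!r}")


def _score(bm: BinaryMatrix, res: SortResult, cfg: SweepConfig) -> float:
    if cfg.metric == "coverage":
        return float(overall_me_coverage(permute_matrix(bm, res)))
    if cfg.metric == "entropy":
        mean, _ = topk_pair_entropy(bm, res, cfg.top_k)
        return mean
    raise ValueError(f"unknown metric {cfg.metric!r}")


def compare_methods(
    cfg: SweepConfig,
    progress: Callable[[str], None] | None = None,
) -> ComparisonReport:
    """Run the full sweep and assemble a :class:`ComparisonReport`.

    For every (size, density, replicate) a fresh matrix is generated from a
    seed derived from the master seed; each method sorts it and the sorted
    matrix is scored.  Consecutive method pairs get a one-sided paired
    p-value (left > right) and a win fraction.
    """
    score_rows: list[dict] = []
    timing_acc: dict[tuple[int, float, str], list[float]] = {}
    for si, size in enumerate(cfg.sizes):
        for di, density in enumerate(cfg.densities):
            if progress:
                progress(f"size={size} density={density}")
            for rep in range(cfg.reps):
                mseed = _derive_seed(cfg.seed, 1, si, di, rep)
                bm, _labels = _make_matrix(cfg, size, density, mseed)
                for mi, method in enumerate(cfg.methods):
                    rseed = _derive_seed(cfg.seed, 2, si, di, rep, mi)
                    t0 = time.perf_counter()
                    res = _apply_method(bm, method, rseed)
                    elapsed = time.perf_counter() - t0
                    timing_acc.setdefault((size, density, method), []).append(elapsed)
                    score_rows.append(
                        {
                            "size": size,
                            "density": density,
                            "replicate": rep,
                            "method": method,
                            "score": _score(bm, res, cfg),
                        }
                    )
    scores = pd.DataFrame(score_rows)

    pv_rows: list[dict] = []
    for size in cfg.sizes:
        for density in cfg.densities:
            cond = scores[(scores["size"] == size) & (scores["density"] == density)]
            by_method = {
                meth: cond[cond["method"] == meth].sort_values("replicate")["score"].to_numpy()
                for meth in cfg.methods
            }
            for left, right in zip(cfg.methods[:-1], cfg.methods[1:]):
                test = paired_onesided_p(
                    by_method[left], by_method[right], method=cfg.test_method, seed=cfg.seed
                )
                wins = float(np.mean(by_method[left] > by_method[right]))
                pv_rows.append(
                    {
                        "size": size,
                        "density": density,
                        "left": left,
                        "right": right,
                        "p": test.p,
                        "n_nonzero": test.n_nonzero,
                        "degenerate": test.degenerate,
                        "win_fraction": wins,
                    }
                )
    pvalues = pd.DataFrame(pv_rows)

    timings = pd.DataFrame(
        [
            {
                "size": size,
                "density": density,
                "method": method,
                "mean_s": float(np.mean(v)),
                "total_s": float(np.sum(v)),
            }
            for (size, density, method), v in timing_acc.items()
        ]
    )
    return ComparisonReport(cfg, scores, pvalues, timings)


def me_recovery_rate(
    labels: dict[str, str], res: SortResult, k: int | None = None
) -> float:
    """Fraction of ground-truth mutually exclusive rows placed in the top rows.

    ``k`` defaults to the number of ME rows in the truth labels.
    """
    me_rows = {g for g, lab in labels.items() if lab == "me"}
    if not me_rows:
        raise ValueError("no ME rows in the ground truth")
    if k is None:
        k = len(me_rows)
    top = set(res.row_order[:k])
    return len(me_rows & top) / len(me_rows)


def timing_sweep(
    sizes: Sequence[int],
    densities: Sequence[float],
    reps: int = 3,
    seed: int = 0,
    fine_grid: bool = False,
) -> pd.DataFrame:
    """Wall-clock summary of the heuristic sorter per (size, density) condition.

    Informational only — timings are hardware-dependent and never asserted.
    With ``fine_grid=True`` the density grid 0.001..0.1 (step 0.001) is
    appended, which covers the sparse worst-case region around one non-zero
    entry per row.
    """
    densities = list(densities)
    if fine_grid:
        densities = sorted(set(densities) | {round(d, 3) for d in np.arange(0.001, 0.1, 0.001)})
    rows = []
    for size in sizes:
        for density in densities:
            times = []
            for rep in range(reps):
                bm = random_bm(size, size, density, _derive_seed(seed, 3, size, rep))
                t0 = time.perf_counter()
                mutex_sort(bm)
                times.append(time.perf_counter() - t0)
            times_arr = np.asarray(times)
            mean = float(times_arr.mean())
            half = float(1.96 * times_arr.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0
            rows.append(
                {
                    "size": size,
                    "density": density,
                    "reps": reps,
                    "mean_s": mean,
                    "ci95_lo": mean - half,
                    "ci95_hi": mean + half,
                }
            )
    return pd.DataFrame(rows)
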