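"""The two-phase greedy mutual-exclusivity sorter, against brute-force oracles."""

import itertools

import numpy as np
import pytest

from mutexsort import (
    BinaryMatrix,
    best_in_class_score,
    marginals,
    mutex_sort,
    order_columns,
    permute_matrix,
    run_stats,
    sample_exclusive_coverage,
    select_rows,
)


def brute_best_in_class(values, g, uncovered_rows, uncovered_cols):
    """Straight-from-the-formula evaluation with explicit loops."""
    total = 0
    for s in uncovered_cols:
        competitors = sum(values[gp][s] for gp in uncovered_rows if gp != g)
        total += values[g][s] - competitors
    return total


class TestBestInClass:
    def test_single_gene_score_is_row_marginal(self):
        bm = BinaryMatrix(["g1"], ["s1", "s2", "s3"], [[1, 0, 1]])
        assert best_in_class_score(bm, "g1", ["g1"], bm.col_ids) == 2

    def test_fixture_everything_uncovered(self, bm3x4):
        # cov(g1)=2, six 1s in total: 2*2 - 6 = -2
        assert best_in_class_score(bm3x4, "g1", bm3x4.row_ids, bm3x4.col_ids) == -2

    def test_fixture_after_first_cover_step(self, bm3x4):
        # g1 and {s1,s2} covered: g2 over {s3,s4} vs competitor g3 = (1-1)+(1-0)
        assert best_in_class_score(bm3x4, "g2", ["g2", "g3"], ["s3", "s4"]) == 1

    def test_gene_must_be_uncovered(self, bm3x4):
        with pytest.raises(ValueError):
            best_in_class_score(bm3x4, "g1", ["g2", "g3"], bm3x4.col_ids)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_on_all_small_configs(self, seed):
        """Exhaustive uncovered-set configurations on random 4x4 matrices."""
        rng = np.random.default_rng(seed)
        vals = rng.integers(0, 2, size=(4, 4))
        bm = BinaryMatrix(list("abcd"), list("wxyz"), vals)
        for rows in itertools.chain.from_iterable(
            itertools.combinations(range(4), k) for k in range(1, 5)
        ):
            for cols in itertools.chain.from_iterable(
                itertools.combinations(range(4), k) for k in range(1, 5)
            ):
                rids = [bm.row_ids[i] for i in rows]
                cids = [bm.col_ids[j] for j in cols]
                for g in rids:
                    gi = bm.row_index(g)
                    expected = brute_best_in_class(vals, gi, list(rows), list(cols))
                    assert best_in_class_score(bm, g, rids, cids) == expected

    @pytest.mark.parametrize("seed", range(3))
    def test_argmax_equals_coverage_argmax(self, seed):
        """The printed score is 2*cov - T with T constant in g, so the argmax
        (with first-index tie-breaking) coincides with the most-covering gene."""
        rng = np.random.default_rng(100 + seed)
        vals = rng.integers(0, 2, size=(8, 8))
        bm = BinaryMatrix([f"g{i}" for i in range(8)], [f"s{j}" for j in range(8)], vals)
        for _ in range(200):
            rows = sorted(rng.choice(8, size=rng.integers(1, 9), replace=False))
            cols = sorted(rng.choice(8, size=rng.integers(1, 9), replace=False))
            rids = [bm.row_ids[i] for i in rows]
            cids = [bm.col_ids[j] for j in cols]
            scores = [best_in_class_score(bm, g, rids, cids) for g in rids]
            covs = [int(vals[i][cols].sum()) for i in rows]
            assert int(np.argmax(scores)) == int(np.argmax(covs))


class TestSelectRows:
    def test_identity_matrix_keeps_original_order(self, make_identity):
        bm = make_identity(5)
        assert select_rows(bm) == list(bm.row_ids)

    def test_fixture_hand_trace(self, bm3x4):
        # g1 wins the 3-way tie at -2, covers {s1,s2}; g2 beats g3 (1 vs -1);
        # g3 appended as leftover once samples run out
        assert select_rows(bm3x4) == ["g1", "g2", "g3"]

    def test_all_zero_row_lands_in_leftover_block(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n, m = int(rng.integers(2, 6)), int(rng.integers(1, 6))
            vals = rng.integers(0, 2, size=(n, m))
            zero_row = int(rng.integers(0, n))
            vals[zero_row] = 0
            if vals.sum() == 0:
                continue
            bm = BinaryMatrix([f"g{i}" for i in range(n)], [f"s{j}" for j in range(m)], vals)
            order = select_rows(bm)
            # the zero row is never best-in-class while a non-zero uncovered row
            # and uncovered samples remain
            nonzero_first = next(
                i for i, g in enumerate(order) if vals[bm.row_index(g)].sum() > 0
            )
            assert order.index(f"g{zero_row}") > nonzero_first or n == 1

    def test_phase1_iteration_bound(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n, m = int(rng.integers(1, 10)), int(rng.integers(1, 10))
            bm = BinaryMatrix(
                [f"g{i}" for i in range(n)],
                [f"s{j}" for j in range(m)],
                rng.integers(0, 2, size=(n, m)),
            )
            order = select_rows(bm)
            assert sorted(order) == sorted(bm.row_ids)


class TestSampleExclusiveCoverage:
    def test_zero_when_gene_not_mutated(self, bm3x4):
        assert sample_exclusive_coverage(bm3x4, "g1", "s3", list(bm3x4.row_ids)) == 0

    def test_uniquely_mutated_sample_scores_one(self, bm3x4):
        assert sample_exclusive_coverage(bm3x4, "g1", "s2", list(bm3x4.row_ids)) == 1

    def test_shared_sample_scores_zero(self, bm3x4):
        # s1 also mutated in g3: 1 * (1 - 1) = 0
        assert sample_exclusive_coverage(bm3x4, "g1", "s1", list(bm3x4.row_ids)) == 0

    def test_negative_with_multiple_competitors(self):
        bm = BinaryMatrix(["a", "b", "c"], ["s"], [[1], [1], [1]])
        assert sample_exclusive_coverage(bm, "a", "s", ["a", "b", "c"]) == -1


class TestOrderColumns:
    def test_fixture_hand_trace(self, bm3x4):
        assert order_columns(bm3x4, ["g1", "g2", "g3"]) == ["s2", "s1", "s4", "s3"]

    def test_all_zero_column_appended_last(self):
        bm = BinaryMatrix(["a", "b"], ["s1", "s2", "s3"], [[1, 0, 0], [0, 0, 1]])
        assert order_columns(bm, ["a", "b"])[-1] == "s2"

    def test_identity_matrix_keeps_columns(self, make_identity):
        bm = make_identity(6)
        assert order_columns(bm, list(bm.row_ids)) == list(bm.col_ids)

    def test_requires_row_permutation(self, bm3x4):
        with pytest.raises(ValueError):
            order_columns(bm3x4, ["g1", "g2"])


class TestMutexSort:
    def test_fixture_full_trace(self, bm3x4):
        res = mutex_sort(bm3x4)
        assert res.row_order == ("g1", "g2", "g3")
        assert res.col_order == ("s2", "s1", "s4", "s3")
        out = permute_matrix(bm3x4, res)
        assert out.values.tolist() == [[1, 1, 0, 0], [0, 0, 1, 1], [0, 1, 0, 1]]

    def test_identity_matrix_is_fixed_point(self, make_identity):
        for n in range(1, 7):
            bm = make_identity(n)
            res = mutex_sort(bm)
            assert permute_matrix(bm, res) == bm

    def test_deterministic(self, bm3x4):
        assert mutex_sort(bm3x4) == mutex_sort(bm3x4)

    def test_conserves_marginals(self):
        rng = np.random.default_rng(3)
        bm = BinaryMatrix(
            [f"g{i}" for i in range(12)],
            [f"s{j}" for j in range(9)],
            rng.integers(0, 2, size=(12, 9)),
        )
        out = permute_matrix(bm, mutex_sort(bm))
        assert out.values.sum() == bm.values.sum()
        orig = marginals(bm, "rows")
        assert all(cnt == orig[g] for g, cnt in marginals(out, "rows").items())

    def test_disjoint_support_rows_get_one_run_each_no_overlap(self):
        """Brute force over all 2- and 3-row matrices with pairwise disjoint
        non-empty supports, m <= 6: after sorting, zero vertical overlap and
        one run per row."""
        checked = 0
        for m in range(2, 7):
            for n_rows in (2, 3):
                for assignment in itertools.product(range(n_rows + 1), repeat=m):
                    vals = np.zeros((n_rows, m), dtype=int)
                    for j, a in enumerate(assignment):
                        if a > 0:
                            vals[a - 1, j] = 1
                    if (vals.sum(axis=1) == 0).any():
                        continue
                    checked += 1
                    if checked % 7:  # thin the enumeration to keep it quick
                        continue
                    bm = BinaryMatrix(
                        [f"g{i}" for i in range(n_rows)],
                        [f"s{j}" for j in range(m)],
                        vals,
                    )
                    out = permute_matrix(bm, mutex_sort(bm))
                    stats = run_stats(out)
                    assert stats.consecutive_overlap == 0
                    assert all(c == 1 for c in stats.run_counts.values())
        assert checked > 500

    def test_restricted_variant_is_valid_permutation(self, bm3x4):
        res = mutex_sort(bm3x4, variant="restricted")
        assert sorted(res.row_order) == sorted(bm3x4.row_ids)
        assert sorted(res.col_order) == sorted(bm3x4.col_ids)
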