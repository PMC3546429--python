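"""Selection strategies: random, exact-count, and the deterministic variants."""

import numpy as np
import pytest
from scipy import stats

from curlev import (DataMatrix, SelectionConfig, leverage_for, select,
                    select_exact_num_random, select_highest_ranks,
                    select_ortho_top_scores, select_random, select_top_scores)
from conftest import random_matrix


class TestSelectRandom:
    def test_degenerate_probabilities_force_outcome(self):
        res = select_random(np.array([1.0, 1.0, 0.0]), seed=7)
        assert res.indices.tolist() == [0, 1]

    def test_count_matches_bernoulli_expectation(self):
        p = np.full(1000, 0.5)
        res = select_random(p, seed=11)
        assert abs(res.indices.size - 500) <= 3 * np.sqrt(1000 * 0.25)
        counts = [select_random(p, seed=s).indices.size for s in range(200)]
        assert abs(np.mean(counts) - 500) < 0.02 * 500

    def test_seeded_determinism(self):
        p = np.array([0.3, 0.8, 0.5, 0.1])
        a, b = select_random(p, seed=5), select_random(p, seed=5)
        np.testing.assert_array_equal(a.indices, b.indices)

    def test_all_zero_probabilities_rejected(self):
        with pytest.raises(ValueError, match="all probabilities are zero"):
            select_random(np.zeros(4), seed=0)

    def test_redraw_on_empty_selection(self):
        # one tiny probability: most draws are empty, redraw must recover
        res = select_random(np.array([0.02]), seed=3)
        assert res.indices.tolist() == [0]

    def test_per_index_frequencies_chi_square(self):
        """Selected-count distribution matches independent Bernoulli draws."""
        rng_p = np.random.default_rng(42)
        p = rng_p.uniform(0.1, 0.9, size=10)
        n_seeds = 2000
        hits = np.zeros(10)
        for s in range(n_seeds):
            hits[select_random(p, seed=s).indices] += 1
        chi2 = np.sum((hits - n_seeds * p) ** 2 / (n_seeds * p * (1 - p)))
        assert stats.chi2.sf(chi2, df=10) > 0.01


class TestSelectExactNumRandom:
    def test_exact_count(self):
        scores = np.array([0.4, 0.3, 0.2, 0.05, 0.05])
        for s in range(50):
            res = select_exact_num_random(scores, 3, seed=s)
            assert res.indices.size == 3
            assert np.unique(res.indices).size == 3

    def test_single_positive_weight_always_chosen(self):
        res = select_exact_num_random(np.array([1.0, 0, 0, 0]), 1, seed=9)
        assert res.indices.tolist() == [0]

    def test_marginal_frequencies_match_weights(self):
        scores = np.array([0.5, 0.3, 0.2])
        p = np.minimum(1, 1 * scores)
        p = p / p.sum()
        n = 10_000
        counts = np.zeros(3)
        for s in range(n):
            counts[select_exact_num_random(scores, 1, seed=s).indices[0]] += 1
        se = np.sqrt(n * p * (1 - p))
        assert np.all(np.abs(counts - n * p) <= 3 * se)

    def test_count_exceeding_positive_weights_rejected(self):
        with pytest.raises(ValueError, match="positive weight"):
            select_exact_num_random(np.array([1.0, 0.0, 0.0]), 2, seed=0)


class TestSelectTopScores:
    def test_descending_order(self):
        res = select_top_scores(np.array([0.1, 0.4, 0.2, 0.3]), 2)
        assert res.indices.tolist() == [1, 3]

    def test_tie_broken_by_lower_index(self):
        res = select_top_scores(np.array([0.3, 0.3, 0.4]), 2)
        assert res.indices.tolist() == [2, 0]

    def test_full_count_returns_all_in_score_order(self):
        res = select_top_scores(np.array([0.1, 0.4, 0.2, 0.3]), 4)
        assert res.indices.tolist() == [1, 3, 2, 0]


class TestSelectOrthoTopScores:
    def test_duplicate_column_not_picked_twice(self):
        # two identical high-leverage columns: the duplicate has zero
        # orthogonal component once its twin is selected
        rng = np.random.default_rng(0)
        base = rng.normal(size=(8, 3))
        big = rng.normal(size=8) * 10
        A = np.column_stack([big, big, base])
        lev = leverage_for(DataMatrix(A), 1)
        assert lev.column_scores[0] == pytest.approx(lev.column_scores[1])
        assert lev.column_scores[0] > lev.column_scores[2:].max()
        res = select_ortho_top_scores(A, lev.column_scores, 2)
        assert res.indices[0] == 0  # tie with its twin broken by lower index
        assert res.indices[1] != 1  # the twin has zero orthogonal component

    def test_orthogonal_columns_reduce_to_top_scores(self):
        A = np.diag([5.0, 4.0, 3.0, 2.0])
        lev = leverage_for(DataMatrix(A), 3)
        res_o = select_ortho_top_scores(A, lev.column_scores, 3)
        res_t = select_top_scores(lev.column_scores, 3)
        assert res_o.indices.tolist() == res_t.indices.tolist()

    def test_count_one_equals_top_scores(self):
        A = random_matrix(7, 6, 5).values
        lev = leverage_for(DataMatrix(A), 2)
        assert (select_ortho_top_scores(A, lev.column_scores, 1).indices.tolist()
                == select_top_scores(lev.column_scores, 1).indices.tolist())

    def test_fill_flag_when_span_exhausted(self):
        # rank-1 matrix: after the first pick everything lies in the span
        A = np.outer(np.arange(1.0, 5.0), np.array([3.0, 2.0, 1.0]))
        lev = leverage_for(DataMatrix(A), 1)
        res = select_ortho_top_scores(A, lev.column_scores, 3)
        assert res.filled_from_scores
        assert res.indices.size == 3


class TestSelectHighestRanks:
    def test_k_one_equals_top_scores_at_rank_one(self):
        A = random_matrix(8, 7, 6).values
        lev1 = leverage_for(DataMatrix(A), 1)
        res_h = select_highest_ranks(A, 1, 3)
        res_t = select_top_scores(lev1.column_scores, 3)
        assert res_h.indices.tolist() == res_t.indices.tolist()

    def test_diagonal_enumeration(self, diag321):
        res = select_highest_ranks(diag321.values, 2, 2)
        assert set(res.indices.tolist()) == {0, 1}

    def test_selected_within_union_of_per_rank_tops(self):
        A = random_matrix(9, 10, 8).values
        k, count = 4, 3
        res = select_highest_ranks(A, k, count)
        union = set()
        for kp in range(1, k + 1):
            lev = leverage_for(DataMatrix(A), kp)
            union |= set(np.argsort(-lev.column_scores, kind="stable")[:count].tolist())
        assert set(res.indices.tolist()) <= union


class TestDispatcher:
    def test_top_scores_both_axes(self, diag321):
        lev = leverage_for(diag321, 2)
        cols, rows = select(diag321, SelectionConfig("top.scores", c=2, r=2), lev)
        assert cols.indices.tolist() == [0, 1]
        assert rows.indices.tolist() == [0, 1]

    def test_all_sentinel_skips_rows(self, diag321):
        lev = leverage_for(diag321, 2)
        cols, rows = select(diag321, SelectionConfig("top.scores", c=2, r="all"), lev)
        assert rows is None

    def test_random_seeded_repeatable(self):
        A = random_matrix(10, 9, 7)
        lev = leverage_for(A, 3)
        cfg = SelectionConfig("random", c=4, r=4, seed=123)
        (c1, r1), (c2, r2) = select(A, cfg, lev), select(A, cfg, lev)
        np.testing.assert_array_equal(c1.indices, c2.indices)
        np.testing.assert_array_equal(r1.indices, r2.indices)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown method"):
            SelectionConfig("fancy", c=1, r=1)

    @pytest.mark.parametrize("method", ["top.scores", "ortho.top.scores",
                                        "highest.ranks"])
    def test_deterministic_methods_pure(self, method):
        A = random_matrix(11, 8, 6)
        lev = leverage_for(A, 3)
        cfg = SelectionConfig(method, c=3, r=3)
        (c1, r1), (c2, r2) = select(A, cfg, lev), select(A, cfg, lev)
        np.testing.assert_array_equal(c1.indices, c2.indices)
        np.testing.assert_array_equal(r1.indices, r2.indices)

    def test_planted_orthogonal_column_reaches_top(self):
        """A column orthogonal to a rank-k signal attains a top-(k+1)
        leverage score at rank k+1 and is picked by top.scores."""
        rng = np.random.default_rng(12)
        k = 3
        G1, G2 = rng.normal(size=(20, k)), rng.normal(size=(k, 10))
        signal = G1 @ G2
        v = rng.normal(size=20)
        Q, _ = np.linalg.qr(G1)
        v -= Q @ (Q.T @ v)
        v *= np.mean(np.linalg.norm(signal, axis=0)) / np.linalg.norm(v)
        A = DataMatrix(np.column_stack([signal, v]))
        lev = leverage_for(A, k + 1)
        top = select_top_scores(lev.column_scores, k + 1)
        assert 10 in top.indices.tolist()
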