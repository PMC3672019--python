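import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ppialign.matching import (adaptive_auction_match, auction_match,
                               brute_force_optimal, complete_matching,
                               greedy_match)
from ppialign.model import Matching


def _valid(m, shape):
    rows = [i for i, _ in m.pairs]
    cols = [j for _, j in m.pairs]
    assert len(set(rows)) == len(rows) and len(set(cols)) == len(cols)
    assert all(0 <= i < shape[0] and 0 <= j < shape[1] for i, j in m.pairs)
    assert m.weight == pytest.approx(sum(m.scores))


class TestGreedy:
    def test_single_entry(self):
        m = greedy_match(np.array([[5.0]]))
        assert m.pairs == [(0, 0)] and m.weight == 5.0

    def test_half_approximation_worked_example(self):
        X = np.array([[1.0, 0.9], [0.9, 0.0]])
        g = greedy_match(X)
        opt = brute_force_optimal(X)
        assert g.pairs == [(0, 0)] and g.weight == pytest.approx(1.0)
        assert opt.weight == pytest.approx(1.8)
        assert g.weight > 0.5 * opt.weight

    def test_tie_breaks_to_smallest_row_then_column(self):
        m = greedy_match(np.array([[2.0, 1.0], [1.0, 2.0]]))
        assert m.pairs == [(0, 0), (1, 1)] and m.weight == 4.0

    def test_zero_entries_produce_no_pairs(self):
        m = greedy_match(np.array([[0.0, 0.0], [0.0, 3.0]]))
        assert m.pairs == [(1, 1)]

    def test_half_bound_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            X = rng.random((int(rng.integers(1, 7)), int(rng.integers(1, 7))))
            g, opt = greedy_match(X), brute_force_optimal(X)
            assert g.weight >= 0.5 * opt.weight - 1e-12


class TestAuction:
    def test_single_entry(self):
        m = auction_match(np.array([[5.0]]), epsilon=0.5)
        assert m.pairs == [(0, 0)] and m.weight == 5.0

    def test_integer_example_matches_optimum(self):
        X = np.array([[4.0, 1, 0], [2, 3, 0], [0, 1, 2]])
        m = auction_match(X, epsilon=0.2, scale=1)
        assert m.weight == pytest.approx(brute_force_optimal(X).weight) == 9

    def test_all_zero_row_left_unassigned(self):
        X = np.array([[0.0, 0.0], [1.0, 2.0]])
        m = auction_match(X, epsilon=0.3, scale=1)
        assert all(i != 0 for i, _ in m.pairs) and len(m) == 1

    def test_rows_exceeding_columns_handled_by_transpose(self):
        X = np.array([[3.0], [5.0]])
        m = auction_match(X, epsilon=0.4, scale=1)
        assert m.pairs == [(1, 0)]

    def test_exactness_regime_random_integers(self):
        rng = np.random.default_rng(13)
        for _ in range(60):
            nr = int(rng.integers(2, 7))
            nc = int(rng.integers(nr, nr + 3))
            X = rng.integers(0, 9, size=(nr, nc)).astype(float)
            m = auction_match(X, epsilon=0.9 / nr, scale=1)
            assert m.weight == pytest.approx(brute_force_optimal(X).weight)

    def test_prices_monotone_nondecreasing(self):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 20, size=(6, 8)).astype(float)
        _, state = auction_match(X, epsilon=0.1, scale=1, return_state=True)
        hist = state.price_history
        for prev, cur in zip(hist, hist[1:]):
            assert (cur >= prev - 1e-12).all()

    def test_non_finite_entries_error(self):
        with pytest.raises(ValueError):
            auction_match(np.array([[1.0, np.inf]]), epsilon=0.1)


class TestAdaptiveAuction:
    def test_dense_positive_reaches_maximum_cardinality(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0.1, 1.0, size=(5, 6))
        m = adaptive_auction_match(X)
        assert len(m) == 5
        _valid(m, X.shape)

    def test_validity_and_half_bound_random(self):
        rng = np.random.default_rng(21)
        for _ in range(60):
            nr, nc = int(rng.integers(2, 7)), int(rng.integers(2, 7))
            X = rng.uniform(0.01, 1.0, size=(nr, nc))
            m = adaptive_auction_match(X)
            _valid(m, X.shape)
            assert len(m) == min(nr, nc)
            assert m.weight >= 0.5 * brute_force_optimal(X).weight - 1e-12

    def test_large_delta_still_returns_valid_matching(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0.0, 1.0, size=(6, 6))
        m = adaptive_auction_match(X, epsilon0=0.1, growth=2.0, delta=6)
        _valid(m, X.shape)
        assert len(m) == 6

    def test_parameter_validation(self):
        X = np.ones((2, 2))
        with pytest.raises(ValueError):
            adaptive_auction_match(X, growth=1.0)
        with pytest.raises(ValueError):
            adaptive_auction_match(X, delta=0)

    def test_prices_monotone_across_epsilon_phases(self):
        rng = np.random.default_rng(8)
        X = rng.uniform(0.0, 1.0, size=(8, 8))
        _, state = adaptive_auction_match(X, return_state=True)
        hist = state.price_history
        for prev, cur in zip(hist, hist[1:]):
            assert (cur >= prev - 1e-12).all()


class TestCompleteMatching:
    def test_empty_partial_pairs_in_order(self):
        X = np.zeros((2, 2))
        m = complete_matching(Matching(pairs=[], scores=[]), X)
        assert m.pairs == [(0, 0), (1, 1)]

    def test_fills_around_existing_pair(self):
        X = np.arange(4.0).reshape(2, 2)
        m = complete_matching(Matching(pairs=[(0, 1)], scores=[1.0]), X)
        assert set(m.pairs) == {(0, 1), (1, 0)}

    def test_idempotent_and_weight_never_decreases(self):
        rng = np.random.default_rng(4)
        X = rng.random((4, 5))
        partial = greedy_match(X)
        full = complete_matching(partial, X)
        again = complete_matching(full, X)
        assert full.pairs == again.pairs
        assert full.weight >= partial.weight - 1e-12
        assert len(full) == 4


class TestBruteForce:
    def test_counterexample_optimum(self):
        m = brute_force_optimal(np.array([[1.0, 0.9], [0.9, 0.0]]))
        assert set(m.pairs) == {(0, 1), (1, 0)} and m.weight == pytest.approx(1.8)

    def test_single_row_picks_best_column(self):
        m = brute_force_optimal(np.array([[1.0, 7.0, 3.0]]))
        assert m.pairs == [(0, 1)]

    def test_all_equal_ties_deterministic(self):
        m = brute_force_optimal(np.full((3, 3), 2.0))
        assert m.pairs == [(0, 0), (1, 1), (2, 2)]
        assert m.weight == pytest.approx(6.0)

    def test_size_guard(self):
        with pytest.raises(ValueError, match="guard"):
            brute_force_optimal(np.ones((10, 10)))

    def test_agrees_with_linear_sum_assignment(self):
        # independent cross-check of the enumeration oracle itself
        from scipy.optimize import linear_sum_assignment

        rng = np.random.default_rng(17)
        for _ in range(30):
            X = rng.random((int(rng.integers(1, 7)), int(rng.integers(1, 8))))
            m = brute_force_optimal(X)
            if X.shape[0] <= X.shape[1]:
                r, c = linear_sum_assignment(-X)
            else:
                c, r = linear_sum_assignment(-X.T)
            assert m.weight == pytest.approx(float(X[r, c].sum()))


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(1, 6), st.integers(1, 6), st.integers(0, 10_000))
def test_every_matcher_returns_injective_pairs(nr, nc, seed):
    rng = np.random.default_rng(seed)
    X = rng.random((nr, nc))
    eps = 0.5 / min(nr, nc)
    for m in (greedy_match(X), auction_match(X, epsilon=eps, scale=1000),
              adaptive_auction_match(X)):
        _valid(m, X.shape)
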