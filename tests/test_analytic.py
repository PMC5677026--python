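"""Closed-form costs, baselines, bounds, and optimality scans."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from halflie import (
    GameConfig,
    conventional_raster_queries,
    epsilon_grid_near_powers,
    mean_queries,
    mean_zero_lie,
    nearness_metric,
    optimality_map,
    rastering_verification_mean,
    rivest_lower_bound,
)


class TestMeanZeroLie:
    @pytest.mark.parametrize(
        "q, eps_inv, expected",
        [
            (2, 10**10, 51.0),
            (3, 10**10, 42.0),
            (4, 10**10, 42.5),
            (2, 8, 4.5),
            (3, 3, 2.0),
        ],
    )
    def test_known_costs(self, q, eps_inv, expected):
        assert mean_zero_lie(q, eps_inv) == expected

    def test_rejects_bad_order(self):
        with pytest.raises(ValueError):
            mean_zero_lie(1, 100)


class TestMeanQueries:
    # analytic rows of the high-loss cost table (alpha0 = 0.99)
    @pytest.mark.parametrize(
        "q, eps_inv, expected",
        [
            (2, 10**3, 1995.0),
            (3, 10**3, 2093.0),
            (4, 10**3, 1992.5),
            (5, 10**3, 2490.0),
            (3, 3 * 10**3, 2392.0),
            (4, 3 * 10**3, 2391.0),
            (2, 10**6, 3990.0),
            (3, 10**6, 3887.0),
            (4, 10**6, 3985.0),
            (5, 10**6, 4482.0),
            (3, 10**10, 6279.0),
        ],
    )
    def test_high_loss_costs_are_exact(self, q, eps_inv, expected):
        assert mean_queries(q, eps_inv, 0.99) == expected

    @settings(derandomize=True, max_examples=100)
    @given(q=st.integers(2, 8), eps_inv=st.integers(2, 10**9))
    def test_reduces_to_zero_lie_at_zero_loss(self, q, eps_inv):
        assert mean_queries(q, eps_inv, 0.0) == mean_zero_lie(q, eps_inv)

    @pytest.mark.parametrize("q", [2, 3, 5])
    def test_step_structure_between_powers(self, q):
        # the cost is constant on [q^(i-1)+1, q^i] and jumps just past q^i
        for i in [2, 5, 9]:
            assert mean_queries(q, q ** (i - 1) + 1, 0.99) == mean_queries(q, q**i, 0.99)
            assert mean_queries(q, q**i + 1, 0.99) > mean_queries(q, q**i, 0.99)

    def test_finite_and_correct_at_extreme_resolution(self):
        # double precision fails near 2^49 with naive logs; the robust
        # ceiling keeps level counts exact up to 2^48
        val = mean_queries(2, 2**48, 0.99)
        assert math.isfinite(val)
        assert val == (2 * 99 + 1.5) * 48

    def test_rejects_total_loss(self):
        with pytest.raises(ValueError):
            mean_queries(3, 100, 1.0)


class TestNearnessMetric:
    @pytest.mark.parametrize(
        "q, eps_inv, expected",
        [(4, 10**6, 0.034), (2, 10**6, 0.068), (3, 10**6, 0.425), (5, 10**6, 0.416)],
    )
    def test_printed_values(self, q, eps_inv, expected):
        assert round(nearness_metric(q, eps_inv), 3) == expected

    @pytest.mark.parametrize("q, power", [(3, 7), (2, 10), (5, 4)])
    def test_exact_powers_score_zero(self, q, power):
        assert nearness_metric(q, q**power) == 0.0

    @settings(derandomize=True, max_examples=100)
    @given(q=st.integers(2, 9), eps_inv=st.integers(2, 10**9))
    def test_bounded(self, q, eps_inv):
        assert 0.0 <= nearness_metric(q, eps_inv) <= 0.5


class TestRasteringBaselines:
    def test_verification_rastering(self):
        assert rastering_verification_mean(3) == 2.0 == mean_zero_lie(3, 3)
        assert rastering_verification_mean(2) == 1.5 == mean_zero_lie(2, 2)
        assert rastering_verification_mean(10**6) == 500000.5

    def test_conventional_raster(self):
        assert conventional_raster_queries(10, 1) == 10.0
        assert conventional_raster_queries(10, 1, adaptive=True) == 5.0
        assert conventional_raster_queries(10**6, 3, adaptive=True) == 1.5e6
        with pytest.raises(ValueError):
            conventional_raster_queries(10, 0)


class TestRivestBound:
    def test_printed_values(self):
        assert rivest_lower_bound(10**10, 1) == 39
        assert rivest_lower_bound(10**10, 0) == 34

    @pytest.mark.parametrize("m", [1, 5, 20, 40])
    def test_error_free_bound_is_plain_bisection(self, m):
        assert rivest_lower_bound(2**m, 0) == m

    def test_validation(self):
        with pytest.raises(ValueError):
            rivest_lower_bound(1, 0)
        with pytest.raises(ValueError):
            rivest_lower_bound(100, -1)


class TestOptimalityMap:
    def test_smallest_resolution_prefers_bisection(self):
        result = optimality_map([2], [0.0], (2, 3, 4, 5, 6, 7, 8), return_cells=True)
        (cell,) = result.cells
        assert cell.optimal_q_set == frozenset({2})
        assert cell.unique

    def test_ties_are_counted_for_every_winner(self):
        # at eps^-1 = 6 and zero loss, q=5 (cost 3) and q=6 (cost 3.5)...
        # check against brute-force means
        eps = np.arange(2, 50)
        qs = (2, 3, 4, 5)
        result = optimality_map(eps, [0.0], qs, return_cells=True)
        for cell in result.cells:
            means = {q: mean_zero_lie(q, cell.epsilon_inverse) for q in qs}
            best = min(means.values())
            expected = frozenset(q for q, m in means.items() if m == best)
            assert cell.optimal_q_set == expected
            assert cell.unique == (len(expected) == 1)

    def test_counts_consistent_with_cells(self):
        eps = np.arange(2, 200)
        result = optimality_map(eps, [0.0, 0.5], (2, 3, 4), return_cells=True)
        for alpha in (0.0, 0.5):
            sub = result.counts[result.counts["loss_rate"] == alpha]
            cells = [c for c in result.cells if c.loss_rate == alpha]
            for _, row in sub.iterrows():
                q = row["q"]
                assert row["n_optimal"] == sum(q in c.optimal_q_set for c in cells)
                assert row["n_unique"] == sum(
                    c.unique and q in c.optimal_q_set for c in cells
                )

    def test_high_loss_unique_sum_covers_all_cells(self):
        # at alpha0 = 0.99 the rational prefactors break every tie: each
        # resolution has exactly one winner
        eps = np.arange(2, 20_000)
        result = optimality_map(eps, [0.99], (2, 3, 4, 5))
        counts = result.counts
        assert counts["n_optimal"].sum() == eps.size
        assert (counts["n_optimal"] == counts["n_unique"]).all()

    def test_trisection_uniquely_optimal_beyond_2_24(self):
        # sampled resolutions in (2^24, 2^48]: q = 3 is always the sole winner
        rng = np.random.default_rng(42)
        eps = rng.integers(2**24 + 1, 2**48, size=300)
        result = optimality_map(eps, [0.99], (2, 3, 4, 5), return_cells=True)
        for cell in result.cells:
            assert cell.optimal_q_set == frozenset({3})
            assert cell.unique

    def test_rejects_total_loss_and_tiny_resolutions(self):
        with pytest.raises(ValueError):
            optimality_map([10], [1.0], (2, 3))
        with pytest.raises(ValueError):
            optimality_map([1], [0.0], (2, 3))


class TestEpsilonGridNearPowers:
    def test_matches_brute_force(self):
        qs = (2, 3)
        expected = set()
        for q in qs:
            p = q
            while p - 1 <= 100:
                expected.update({p - 1, p, p + 1})
                p *= q
        expected = sorted(e for e in expected if 2 <= e <= 100)
        assert epsilon_grid_near_powers(100, qs).tolist() == expected

    def test_grid_is_sorted_unique(self):
        grid = epsilon_grid_near_powers(10**10, (2, 3, 4, 5))
        assert np.all(np.diff(grid) > 0)
        assert grid[0] >= 2 and grid[-1] <= 10**10
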