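"""Aggregation, dominance/ICER frontier, NMB, CEAC and ellipses."""

import math

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st
from scipy import stats

from irct_cea.cea_stats import (ABSOLUTE_DOMINATED, EXTENDED_DOMINATED,
                                UNDOMINATED, CEACCurve, IterationResult,
                                aggregate_psa, build_cea_table, ceac,
                                confidence_ellipse, crossover_wtp,
                                dominance_and_icers, incremental_pairs, nmb,
                                optimal_shares)

PRINTED_MEANS = {
    "SABS": (16412.0, 5.59),
    "LTTT": (25819.0, 5.33),
    "RSA": (26896.0, 3.78),
    "SCR": (30540.0, 6.17),
}


def _iteration(i, values):
    return IterationResult(
        iteration=i,
        costs={k: v[0] for k, v in values.items()},
        qalys={k: v[1] for k, v in values.items()})


def _results_with_noise(rng, n=400):
    results = []
    for i in range(n):
        values = {name: (abs(c + rng.normal(0, 2000)),
                         abs(q + rng.normal(0, 0.3)))
                  for name, (c, q) in PRINTED_MEANS.items()}
        results.append(_iteration(i, values))
    return results


class TestAggregate:
    def test_identical_iterations_have_zero_sd(self):
        results = [_iteration(i, PRINTED_MEANS) for i in range(5)]
        agg = aggregate_psa(results)
        assert (agg["sd_cost"] == 0).all()
        assert agg.loc["SCR", "mean_qaly"] == 6.17

    def test_two_iteration_hand_arithmetic(self):
        results = [_iteration(0, {"A": (10.0, 1.0), "B": (1.0, 1.0)}),
                   _iteration(1, {"A": (20.0, 1.0), "B": (1.0, 1.0)})]
        agg = aggregate_psa(results)
        assert agg.loc["A", "mean_cost"] == 15.0
        assert agg.loc["A", "sd_cost"] == pytest.approx(math.sqrt(50), abs=1e-9)

    def test_fewer_than_two_iterations_rejected(self):
        with pytest.raises(ValueError):
            aggregate_psa([_iteration(0, PRINTED_MEANS)])

    def test_nonfinite_iteration_rejected(self):
        with pytest.raises(ValueError):
            _iteration(0, {"A": (float("nan"), 1.0), "B": (1.0, 1.0)})


class TestNMB:
    def test_published_sabs_value(self):
        assert nmb(16412, 5.59, 50_000) == pytest.approx(263_088)

    def test_zero_inputs(self):
        assert nmb(0, 0, 50_000) == 0

    def test_wtp_zero_is_negative_cost(self):
        assert nmb(30540, 6.17, 0) == -30540


class TestDominance:
    def test_published_means_classification(self):
        table = dominance_and_icers(PRINTED_MEANS, wtp=50_000)
        assert table.row("LTTT").dominance_label == ABSOLUTE_DOMINATED
        assert table.row("RSA").dominance_label == ABSOLUTE_DOMINATED
        assert table.row("SABS").dominance_label == UNDOMINATED
        assert table.row("SCR").dominance_label == UNDOMINATED
        scr = table.row("SCR")
        assert scr.incremental_cost == pytest.approx(14128.0)
        assert scr.incremental_effect == pytest.approx(0.58)
        assert scr.icer == pytest.approx(24358.6, abs=0.1)
        # frontier chain is SABS -> SCR
        assert table.frontier_icers == ((("SABS", "SCR",
                                          pytest.approx(24358.6, abs=0.1))),)

    def test_equal_qaly_costlier_is_dominated(self):
        table = dominance_and_icers({"A": (5.0, 1.0), "B": (10.0, 1.0)},
                                    wtp=0.0)
        assert table.row("B").dominance_label == ABSOLUTE_DOMINATED
        assert table.row("A").dominance_label == UNDOMINATED

    def test_extended_dominance_middle_point(self):
        means = {"A": (0.001, 0.0), "B": (1.0, 0.1), "C": (2.0, 1.0)}
        table = dominance_and_icers(means, wtp=0.0)
        assert table.row("B").dominance_label == EXTENDED_DOMINATED
        assert table.row("A").dominance_label == UNDOMINATED
        assert table.row("C").dominance_label == UNDOMINATED

    @given(st.lists(
        st.tuples(st.floats(1, 1000), st.floats(0.01, 10)),
        min_size=2, max_size=6, unique_by=(lambda t: t[0], lambda t: t[1])))
    @hyp_settings(deadline=None, max_examples=200, derandomize=True)
    def test_frontier_agrees_with_nmb_argmax_oracle(self, points):
        means = {f"S{i}": (c, q) for i, (c, q) in enumerate(points)}
        table = dominance_and_icers(means, wtp=0.0)
        undominated = {r.strategy for r in table.rows
                       if r.dominance_label == UNDOMINATED}
        # oracle: a strategy is on the frontier iff it attains maximal NMB
        # at some WTP >= 0 (ties to lower cost)
        breakpoints = sorted({0.0} | {
            (means[b][0] - means[a][0]) / (means[b][1] - means[a][1])
            for a in means for b in means
            if means[b][1] != means[a][1]
            and (means[b][0] - means[a][0]) / (means[b][1] - means[a][1]) > 0})
        probes = list(breakpoints)
        probes += [(a + b) / 2 for a, b in zip(breakpoints, breakpoints[1:])]
        probes.append((breakpoints[-1] + 1) * 10)
        winners = set()
        for w in probes:
            winners.add(min(means, key=lambda n: (-nmb(*means[n], w),
                                                  means[n][0], n)))
        assert winners == undominated

    def test_dominated_strategy_never_optimal_at_any_wtp(self):
        table = dominance_and_icers(PRINTED_MEANS, wtp=50_000)
        dominated = [r.strategy for r in table.rows
                     if r.dominance_label != UNDOMINATED]
        for w in np.linspace(0, 500_000, 101):
            best = min(PRINTED_MEANS,
                       key=lambda n: (-nmb(*PRINTED_MEANS[n], w),
                                      PRINTED_MEANS[n][0], n))
            assert best not in dominated


class TestCEAC:
    def test_single_strategy_probability_one_everywhere(self):
        results = [_iteration(i, {"A": (10.0 + i, 1.0)}) for i in range(3)]
        curve = ceac(results, [0, 10_000, 50_000])
        assert (curve.probability("A") == 1.0).all()

    def test_degenerate_dominant_strategy_is_step_at_one(self):
        results = [_iteration(i, {"A": (10.0, 2.0), "B": (20.0, 1.0)})
                   for i in range(3)]
        curve = ceac(results, [0, 25_000, 50_000])
        assert (curve.probability("A") == 1.0).all()
        assert (curve.probability("B") == 0.0).all()

    def test_shares_sum_to_one_at_every_wtp(self):
        results = _results_with_noise(np.random.default_rng(0))
        curve = ceac(results, np.linspace(0, 100_000, 21))
        sums = curve.probabilities.sum(axis=1).to_numpy()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_optimal_shares_sum_to_100(self):
        results = _results_with_noise(np.random.default_rng(1))
        shares = optimal_shares(results, 50_000)
        assert sum(shares.values()) == pytest.approx(100.0, abs=0.01)

    def test_tie_goes_to_lower_cost(self):
        # equal NMB: B costs less and gains less, at wtp = dC/dQ both tie
        results = [_iteration(0, {"A": (10_000.0, 1.0), "B": (5000.0, 0.9)})]
        shares = optimal_shares(results, 50_000.0)
        assert shares == {"A": 0.0, "B": 100.0}


class TestCrossover:
    @staticmethod
    def _synthetic_two_strategy(dc, dq, sd_c, sd_q, n=2000, seed=0):
        rng = np.random.default_rng(seed)
        results = []
        for i in range(n):
            d_cost = dc + rng.normal(0, sd_c)
            d_qaly = dq + rng.normal(0, sd_q)
            results.append(_iteration(i, {
                "REF": (20_000.0, 5.0),
                "NEW": (20_000.0 + d_cost, 5.0 + d_qaly)}))
        return results

    def test_crossover_near_analytic_indifference(self):
        # NEW becomes preferred once WTP exceeds dC/dQ = 25,000
        results = self._synthetic_two_strategy(10_000, 0.4, 3000, 0.12)
        curve = ceac(results, range(0, 100_001, 1000))
        cross = crossover_wtp(curve, "NEW", "REF")
        assert cross == pytest.approx(25_000, abs=2000)

    def test_parallel_curves_have_no_crossover(self):
        # NEW is strictly dominated in every iteration: never optimal
        results = [_iteration(i, {"REF": (10.0, 2.0), "NEW": (20.0, 1.0)})
                   for i in range(5)]
        curve = ceac(results, range(0, 50_001, 1000))
        assert crossover_wtp(curve, "NEW", "REF") is None


class TestEllipse:
    def test_identity_covariance_radius(self):
        rng = np.random.default_rng(0)
        pairs = rng.standard_normal((200_000, 2))
        ell = confidence_ellipse(pairs, level=0.95)
        assert not ell.degenerate
        assert ell.semi_axes[0] == pytest.approx(2.4477, abs=0.03)
        assert ell.semi_axes[1] == pytest.approx(2.4477, abs=0.03)

    def test_identical_points_flagged_degenerate(self):
        pairs = np.ones((10, 2))
        assert confidence_ellipse(pairs).degenerate

    def test_coverage_of_known_bivariate_normal(self):
        rng = np.random.default_rng(12)
        cov = np.array([[4.0, 1.2], [1.2, 1.0]])
        pairs = rng.multivariate_normal([3.0, -1.0], cov, size=100_000)
        ell = confidence_ellipse(pairs, level=0.95)
        coverage = ell.contains(pairs).mean()
        assert coverage == pytest.approx(0.95, abs=0.01)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            confidence_ellipse(np.ones((2, 2)))


class TestBuildTable:
    def test_full_table_invariants(self):
        results = _results_with_noise(np.random.default_rng(4))
        table = build_cea_table(results, 50_000)
        pct = [r.pct_iterations_optimal for r in table.rows]
        assert sum(pct) == pytest.approx(100.0, abs=0.01)
        for r in table.rows:
            assert r.nmb == pytest.approx(
                r.mean_qaly * 50_000 - r.mean_cost, rel=1e-9)
        # rows sorted by mean cost
        costs = [r.mean_cost for r in table.rows]
        assert costs == sorted(costs)

    def test_incremental_pairs_shape(self):
        results = [_iteration(i, PRINTED_MEANS) for i in range(4)]
        pairs = incremental_pairs(results, "SCR", "SABS")
        assert pairs.shape == (4, 2)
        assert np.allclose(pairs[:, 0], 30540 - 16412)
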