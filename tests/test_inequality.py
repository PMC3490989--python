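"""Quantile midpoint ranks, SII/RII estimators, heterogeneity tests."""

import numpy as np
import pytest
from scipy.special import logit

from growthineq.inequality import (
    assign_quantiles,
    heterogeneity_test,
    meta_trend_test,
    rii_logistic,
    sii_grouped,
    sii_individual,
)

NOMINAL = np.array([0.1, 0.3, 0.5, 0.7, 0.9])


class TestAssignQuantiles:
    def test_hundred_distinct_incomes(self, rng):
        values = rng.permutation(np.arange(100.0))
        groups = assign_quantiles(values, 5)
        sizes = np.bincount(groups.group_index)[1:]
        assert list(sizes) == [20] * 5
        assert np.allclose(groups.midpoint_ranks, NOMINAL, atol=1e-12)
        # the 20 smallest values are exactly group 1
        assert set(np.where(groups.group_index == 1)[0]) == set(
            np.argsort(values)[:20]
        )

    def test_ties_forced_thirty_seventy(self):
        values = np.concatenate([np.arange(30.0), np.full(70, 99.0)])
        groups = assign_quantiles(values, 2)
        sizes = np.bincount(groups.group_index)[1:]
        assert list(sizes) == [30, 70]
        assert np.allclose(groups.midpoint_ranks, [0.15, 0.65], atol=1e-12)

    def test_tied_block_never_split(self, rng):
        values = rng.choice([1.0, 2.0, 3.0], size=200)
        groups = assign_quantiles(values, 5)
        for v in (1.0, 2.0, 3.0):
            assert len(np.unique(groups.group_index[values == v])) == 1

    def test_single_group(self):
        groups = assign_quantiles(np.arange(10.0), 1)
        assert groups.n_groups == 1
        assert groups.midpoint_ranks[0] == pytest.approx(0.5)

    def test_weighted_boundaries(self):
        # subject 2 holds 60% of the weight; its inclusive cumulative share
        # (0.7) passes the 0.5 boundary, so it lands in the upper group
        values = np.array([1.0, 2.0, 3.0, 4.0])
        groups = assign_quantiles(values, 2, weights=np.array([1.0, 6.0, 2.0, 1.0]))
        assert list(groups.group_index) == [1, 2, 2, 2]
        assert np.allclose(groups.shares, [0.1, 0.9])
        assert np.allclose(groups.midpoint_ranks, [0.05, 0.55])

    def test_nominal_ranks_flag(self):
        values = np.concatenate([np.arange(30.0), np.full(70, 99.0)])
        groups = assign_quantiles(values, 2, nominal=True)
        assert np.allclose(groups.midpoint_ranks, [0.25, 0.75])

    def test_errors(self):
        with pytest.raises(ValueError):
            assign_quantiles(np.arange(10.0), 0)
        with pytest.raises(ValueError):
            assign_quantiles(np.array([1.0, np.nan]), 2)
        with pytest.raises(ValueError):
            assign_quantiles(np.array([1.0]), 2)


class TestSIIGrouped:
    def test_published_style_worked_example(self):
        prev = np.array([6.7, 5.3, 3.1, 2.0, 1.1]) / 100.0
        res = sii_grouped(prev, NOMINAL)
        assert res.estimate == pytest.approx(-7.25, abs=1e-9)

    def test_constant_prevalence_zero_slope(self):
        res = sii_grouped(np.full(5, 0.05), NOMINAL)
        assert res.estimate == pytest.approx(0.0, abs=1e-12)

    def test_two_groups_line_through_points(self):
        res = sii_grouped([0.10, 0.30], [0.25, 0.75])
        assert res.estimate == pytest.approx(40.0, abs=1e-9)
        assert np.isnan(res.ci_low) and np.isnan(res.std_error)  # CI unavailable

    def test_errors(self):
        with pytest.raises(ValueError):
            sii_grouped([0.1], [0.5])
        with pytest.raises(ValueError):
            sii_grouped([0.1, 1.5], [0.3, 0.7])


class TestSIIIndividual:
    def test_all_zero_outcomes(self):
        res = sii_individual(np.zeros(50), np.tile(NOMINAL, 10))
        assert res.estimate == pytest.approx(0.0, abs=1e-12)

    def test_matches_grouped_on_collapsed_data(self, rng):
        ranks = np.repeat(NOMINAL, [30, 25, 20, 15, 10])
        y = (rng.random(ranks.size) < 0.1 + 0.3 * ranks).astype(float)
        individual = sii_individual(y, ranks)
        prev = [y[ranks == r].mean() for r in NOMINAL]
        sizes = [np.sum(ranks == r) for r in NOMINAL]
        grouped = sii_grouped(prev, NOMINAL, group_sizes=sizes)
        assert individual.estimate == pytest.approx(grouped.estimate, abs=1e-10)

    def test_zero_total_weight_rejected(self):
        with pytest.raises(ValueError):
            sii_individual([0, 1], [0.25, 0.75], weights=[0.0, 0.0])


class TestRIILogistic:
    def test_no_gradient_gives_unity(self):
        res = rii_logistic(np.full(5, 50.0), NOMINAL, trials=np.full(5, 500.0))
        assert res.estimate == pytest.approx(1.0, abs=1e-9)

    def test_two_point_closed_form(self):
        res = rii_logistic(
            np.array([100.0, 300.0]), np.array([0.25, 0.75]),
            trials=np.array([1000.0, 1000.0]),
        )
        expected = np.exp((logit(0.3) - logit(0.1)) / 0.5)
        assert res.estimate == pytest.approx(expected, rel=1e-9)
        assert res.estimate == pytest.approx(14.88, abs=0.01)

    def test_published_style_stunting_row(self):
        prev = np.array([26.0, 16.0, 6.3, 5.3, 2.7]) / 100.0
        res = rii_logistic(prev * 948, NOMINAL, trials=np.full(5, 948.0))
        assert round(res.estimate, 2) == 0.04

    def test_grouped_equals_expanded_individual(self):
        successes = np.array([30.0, 20.0, 12.0, 8.0, 5.0])
        trials = np.full(5, 100.0)
        grouped = rii_logistic(successes, NOMINAL, trials=trials)
        y = np.concatenate(
            [np.r_[np.ones(int(s)), np.zeros(int(t - s))]
             for s, t in zip(successes, trials)]
        )
        ranks = np.repeat(NOMINAL, 100)
        individual = rii_logistic(y, ranks)
        assert individual.estimate == pytest.approx(grouped.estimate, rel=1e-8)
        assert individual.std_error == pytest.approx(grouped.std_error, rel=1e-8)

    def test_no_variation_rejected(self):
        with pytest.raises(ValueError):
            rii_logistic(np.zeros(10), np.tile(NOMINAL, 2))

    def test_ci_brackets_estimate(self):
        res = rii_logistic(np.array([40.0, 10.0]), np.array([0.25, 0.75]),
                           trials=np.array([200.0, 200.0]))
        assert res.ci_low <= res.estimate <= res.ci_high
        assert res.estimate > 0


class TestOrderReversal:
    """Reversing the socioeconomic ordering negates the SII and inverts the RII."""

    def test_sii_sign_flip(self):
        prev = np.array([0.26, 0.16, 0.063, 0.053, 0.027])
        fwd = sii_grouped(prev, NOMINAL)
        rev = sii_grouped(prev[::-1], NOMINAL)
        assert rev.estimate == pytest.approx(-fwd.estimate, abs=1e-10)

    def test_rii_inversion(self):
        succ = np.array([26.0, 16.0, 6.3, 5.3, 2.7]) * 9.48
        trials = np.full(5, 948.0)
        fwd = rii_logistic(succ, NOMINAL, trials=trials)
        rev = rii_logistic(succ[::-1], NOMINAL, trials=trials)
        assert rev.estimate == pytest.approx(1.0 / fwd.estimate, rel=1e-8)

    def test_scaling_group_sizes_invariant(self):
        prev = np.array([0.26, 0.16, 0.063, 0.053, 0.027])
        sizes = np.array([120.0, 100.0, 90.0, 80.0, 60.0])
        a = sii_grouped(prev, NOMINAL, group_sizes=sizes)
        b = sii_grouped(prev, NOMINAL, group_sizes=10 * sizes)
        assert a.estimate == pytest.approx(b.estimate, abs=1e-12)
        ra = rii_logistic(prev * sizes, NOMINAL, trials=sizes)
        rb = rii_logistic(prev * sizes * 7, NOMINAL, trials=sizes * 7)
        assert ra.estimate == pytest.approx(rb.estimate, rel=1e-9)


class TestHeterogeneity:
    def test_identical_estimates(self):
        res = heterogeneity_test([2.0, 2.0, 2.0], [0.5, 0.4, 0.3])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_published_style_sii_slopes(self):
        # SEs reconstructed from printed 95% CI widths / 3.92
        slopes = [-16.80, -18.52, -7.60]
        ci_widths = (9.98, 12.65, 5.25)
        ses = [w / 3.92 for w in ci_widths]
        res = heterogeneity_test(slopes, ses)
        # independent arithmetic oracle
        w = 1.0 / np.asarray(ses) ** 2
        b = np.asarray(slopes)
        b_bar = np.sum(w * b) / np.sum(w)
        q_oracle = float(np.sum(w * (b - b_bar) ** 2))
        assert res.statistic == pytest.approx(q_oracle, abs=1e-10)
        assert res.statistic == pytest.approx(17.0, abs=0.1)
        assert res.df == 2 and res.p_value < 0.001

    def test_two_estimates_at_significance_boundary(self):
        se = (0.7, 1.1)
        gap = 1.959963984540054 * np.hypot(*se)
        res = heterogeneity_test([0.0, gap], se)
        assert res.p_value == pytest.approx(0.05, abs=1e-6)

    def test_errors(self):
        with pytest.raises(ValueError):
            heterogeneity_test([1.0], [0.5])
        with pytest.raises(ValueError):
            heterogeneity_test([1.0, 2.0], [0.5, 0.0])


class TestMetaTrend:
    def test_exact_trend_detected(self):
        res = meta_trend_test([-30.0, -20.0, -10.0], [2.0, 2.0, 2.0],
                              [1982, 1993, 2004])
        assert res.df == 1 and res.p_value < 0.01

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError):
            meta_trend_test([1.0, 2.0], [0.5, 0.5], [3.0, 3.0])
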