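"""t-tests, trend regression and the blocked ANCOVA with AIC selection."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from bryoflux import stats
from bryoflux.errors import DegenerateDesignError, InvalidInputError


class TestTTestFromSummary:
    def test_chlorophyll_contrast_reproduces_printed_statistic(self):
        res = stats.ttest_from_summary(stats.SummaryStats(1300, 190, 5),
                                       stats.SummaryStats(740, 120, 5))
        assert res.t == pytest.approx(2.49, abs=0.005)
        assert res.df == 8
        assert res.p == pytest.approx(0.037, abs=0.002)

    def test_light_compensation_contrast_reproduces_printed_statistic(self):
        res = stats.ttest_from_summary(stats.SummaryStats(94.67, 5.21, 3),
                                       stats.SummaryStats(28.00, 2.89, 3))
        assert res.t == pytest.approx(11.20, rel=0.005)
        assert res.df == 4

    def test_equal_means_give_null_statistic(self):
        res = stats.ttest_from_summary(stats.SummaryStats(5, 1, 4),
                                       stats.SummaryStats(5, 2, 4))
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_matches_replicate_level_pooled_t(self):
        # three replicates realizing each summary exactly: (m−s, m, m+s)
        def realize(m, s):
            return np.array([m - s, m, m + s])

        a = realize(10.0, 2.0)   # mean 10, sd 2, se 2/√3
        b = realize(7.0, 1.5)
        res = stats.ttest_from_summary(
            stats.SummaryStats(10.0, 2.0 / math.sqrt(3), 3),
            stats.SummaryStats(7.0, 1.5 / math.sqrt(3), 3))
        ref = sps.ttest_ind(a, b)
        assert res.t == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_welch_variant(self):
        res = stats.ttest_from_summary(stats.SummaryStats(10, 1.0, 5),
                                       stats.SummaryStats(7, 2.0, 3),
                                       var_equal=False)
        assert res.df < 6  # Welch df below the pooled 6
        assert res.t == pytest.approx(3 / math.sqrt(5), rel=1e-12)

    def test_tiny_groups_rejected(self):
        with pytest.raises(InvalidInputError):
            stats.SummaryStats(1.0, 0.5, 1)


class TestTTestPaired:
    def test_identical_samples_give_zero(self):
        res = stats.ttest_paired([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.t == 0.0
        assert res.p == 1.0

    def test_constant_shift_is_capped_and_flagged(self):
        res = stats.ttest_paired([1, 2, 3], [0, 1, 2])
        assert res.capped is True
        assert res.t == stats.T_CAP
        assert res.p == 0.0

    def test_matches_hand_computed_difference_oracle(self):
        x = [4.1, 5.3, 3.8, 6.2, 5.5, 4.9, 5.1, 6.0, 4.4, 5.8, 5.0, 4.6]
        y = [3.9, 4.8, 4.1, 5.6, 5.2, 4.1, 5.3, 5.1, 4.0, 5.2, 4.4, 4.5]
        d = [a - b for a, b in zip(x, y)]
        n = len(d)
        mean = sum(d) / n
        sd = math.sqrt(sum((v - mean) ** 2 for v in d) / (n - 1))
        expected_t = mean / (sd / math.sqrt(n))
        res = stats.ttest_paired(x, y)
        assert res.t == pytest.approx(expected_t, rel=1e-12)
        assert res.df == n - 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            stats.ttest_paired([1, 2, 3], [1, 2])


class TestLinearTrend:
    def test_perfect_line(self):
        x = np.arange(10.0)
        fit = stats.linear_trend(x, 2.5 * x - 1.0)
        assert fit.slope == pytest.approx(2.5)
        assert fit.adj_r2 == pytest.approx(1.0)
        assert fit.p < 1e-10

    def test_constant_response_has_zero_slope(self):
        fit = stats.linear_trend(np.arange(6.0), np.full(6, 3.3))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equation_arithmetic(self):
        x = [0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0]
        y = [1.2, 1.9, 3.1, 3.6, 5.2, 5.4, 6.9, 7.3, 8.8, 9.1]
        n = len(x)
        sxx = sum(v ** 2 for v in x) - sum(x) ** 2 / n
        sxy = sum(a * b for a, b in zip(x, y)) - sum(x) * sum(y) / n
        slope = sxy / sxx
        intercept = (sum(y) - slope * sum(x)) / n
        rss = sum((b - intercept - slope * a) ** 2 for a, b in zip(x, y))
        tss = sum((b - sum(y) / n) ** 2 for b in y)
        f = (tss - rss) / (rss / (n - 2))
        fit = stats.linear_trend(x, y)
        assert fit.slope == pytest.approx(slope, rel=1e-12)
        assert fit.intercept == pytest.approx(intercept, rel=1e-12)
        assert fit.f == pytest.approx(f, rel=1e-9)

    def test_affine_rescaling_of_covariate(self):
        x = np.arange(12.0)
        y = 0.7 * x + np.sin(x)
        base = stats.linear_trend(x, y)
        scaled = stats.linear_trend(10 * x + 3, y)
        assert scaled.slope == pytest.approx(base.slope / 10, rel=1e-9)
        assert scaled.f == pytest.approx(base.f, rel=1e-9)
        assert scaled.adj_r2 == pytest.approx(base.adj_r2, rel=1e-9)

    def test_degenerate_designs_rejected(self):
        with pytest.raises(DegenerateDesignError):
            stats.linear_trend([1, 1, 1], [1, 2, 3])
        with pytest.raises(DegenerateDesignError):
            stats.linear_trend([1, 2], [1, 2])


class TestAICSelection:
    def test_within_two_aic_prefers_fewer_parameters(self):
        assert stats.select_by_aic([("simple", 100.0, 3), ("rich", 101.5, 5)]) == "simple"
        assert stats.select_by_aic([("simple", 101.5, 3), ("rich", 100.0, 5)]) == "simple"

    def test_clear_winner_selected(self):
        assert stats.select_by_aic([("simple", 105.0, 3), ("rich", 100.0, 5)]) == "rich"


def _ancova_frame(seed, offset=0.0):
    from bryoflux import core, synthetic

    ctl = synthetic.CONTROL_TRUTH
    trt = dataclasses.replace(ctl, dr_ref=ctl.dr_ref * (1 + offset))
    spec = synthetic.default_scenario(
        seed=seed, groups={"control": ctl, "treatment": trt},
        dr_noise_sigma_log=0.0, dr_noise_sd=0.2, temp_noise_sd=0.2)
    table = core.temperature_table(synthetic.gen_temperature_response(spec))
    return table.rename(columns={"temperature_C": "temperature"})


class TestANCOVA:
    def test_identical_groups_exclude_the_group_term(self):
        cmp_ = stats.ancova_group_by_temperature(_ancova_frame(seed=3), "dr")
        assert cmp_.selected == "covariate"
        assert not cmp_.group_selected

    def test_programmed_group_offset_is_detected(self):
        cmp_ = stats.ancova_group_by_temperature(_ancova_frame(seed=3, offset=0.3), "dr")
        assert cmp_.group_selected
        assert cmp_.group_min_p < 0.05

    def test_aic_ordering_invariant_to_response_rescaling(self):
        df = _ancova_frame(seed=5, offset=0.3)
        base = stats.ancova_group_by_temperature(df, "dr")
        df2 = df.copy()
        df2["dr"] = df2["dr"] * 7.5
        scaled = stats.ancova_group_by_temperature(df2, "dr")
        d0 = np.diff([a for _, a, _ in base.table])
        d1 = np.diff([a for _, a, _ in scaled.table])
        assert np.allclose(d0, d1, atol=1e-6)
        assert scaled.selected == base.selected

    def test_degenerate_designs_rejected(self):
        df = _ancova_frame(seed=1)
        with pytest.raises(DegenerateDesignError):
            stats.ancova_group_by_temperature(df[df["group"] == "control"], "dr")
        single = df[df["sample_id"].isin(["C1", "T1", "T2"])]
        with pytest.raises(DegenerateDesignError):
            stats.ancova_group_by_temperature(single, "dr")


def test_holm_correction_monotone_and_bounded():
    p = [0.01, 0.04, 0.03, 0.5]
    adj = stats.holm_correction(p)
    assert np.all(adj >= p)
    assert np.all(adj <= 1.0)
    assert adj[np.argsort(p)[0]] == pytest.approx(0.04)
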