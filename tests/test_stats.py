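"""Agreement, comparison, regression and power routines."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eatq.stats import (
    StatsValidationError,
    bland_altman,
    limits_from_summary,
    multivariable_regression,
    simple_regression,
    t_test_sample_size,
    two_group_compare,
)


class TestBlandAltman:
    def test_hand_computed_example(self):
        res = bland_altman([(10, 8), (12, 12), (9, 11)], relative=False)
        assert res.mean_difference_d == pytest.approx(0.0)
        assert res.sd_differences == pytest.approx(2.0)
        assert res.lower_limit == pytest.approx(-3.92)
        assert res.upper_limit == pytest.approx(3.92)

    def test_identical_series(self):
        res = bland_altman([(5, 5), (7, 7), (9, 9)], relative=True)
        assert res.mean_difference_d == 0.0
        assert res.sd_differences == 0.0
        assert (res.lower_limit, res.upper_limit) == (0.0, 0.0)

    def test_interobserver_limits_from_printed_summary(self):
        lower, upper = limits_from_summary(3.18, 3.13)
        assert round(upper, 1) == 9.3
        assert round(lower, 1) == -3.0

    @given(
        d=st.floats(-50, 50), sd=st.floats(0, 20), factor=st.floats(1.0, 3.0)
    )
    @settings(deadline=None, max_examples=100)
    def test_limits_identity(self, d, sd, factor):
        lower, upper = limits_from_summary(d, sd, factor)
        assert lower == d - factor * sd
        assert upper == d + factor * sd
        assert lower <= upper

    def test_limits_reconstruct_from_own_summary(self):
        rng = np.random.default_rng(3)
        pairs = np.column_stack([rng.uniform(40, 90, 30), rng.uniform(40, 90, 30)])
        res = bland_altman(pairs, relative=True)
        lo, hi = limits_from_summary(res.mean_difference_d, res.sd_differences, res.limit_factor)
        assert (lo, hi) == (res.lower_limit, res.upper_limit)

    def test_too_few_pairs(self):
        with pytest.raises(StatsValidationError):
            bland_altman([(1, 2)])

    def test_zero_pair_mean_in_relative_mode(self):
        with pytest.raises(StatsValidationError):
            bland_altman([(1, -1), (2, 3)], relative=True)


class TestTwoGroupCompare:
    def test_identical_groups(self):
        a = [1.0, 2.0, 3.0, 4.0]
        res_t = two_group_compare(a, a, "students_t")
        assert res_t.statistic == pytest.approx(0.0)
        assert res_t.p_value == pytest.approx(1.0)
        res_u = two_group_compare(a, a, "mann_whitney_u")
        assert res_u.p_value == pytest.approx(1.0)

    def test_welch_flag(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0, 5, 30)
        res = two_group_compare(a, b, "welch_t")
        assert res.test_name == "welch_t"
        assert 0 < res.p_value <= 1

    def test_sex_distribution_chi_square(self):
        # male/female counts 25/7 vs 54/12: not significant
        res = two_group_compare([25, 7], [54, 12], "chi_square")
        assert res.p_value > 0.05

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(2024)
        n_rep, alpha = 10_000, 0.05
        rejections = 0
        for _ in range(n_rep):
            a = rng.standard_normal(15)
            b = rng.standard_normal(15)
            if two_group_compare(a, b, "students_t").p_value < alpha:
                rejections += 1
        assert abs(rejections / n_rep - alpha) <= 0.01

    def test_insufficient_n(self):
        with pytest.raises(StatsValidationError):
            two_group_compare([1.0], [1.0, 2.0], "students_t")


class TestSimpleRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = simple_regression(x, 2 * x + 1)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r == pytest.approx(1.0)

    def test_pearson_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=500)
        y = 0.4 * x + rng.normal(size=500)
        res = simple_regression(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        r_manual = np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2))
        assert res.r == pytest.approx(r_manual, abs=1e-12)

    def test_null_relationship(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=10_000)
        y = rng.normal(size=10_000)
        assert abs(simple_regression(x, y).r) < 0.03

    def test_constant_x_rejected(self):
        with pytest.raises(StatsValidationError):
            simple_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestMultivariableRegression:
    def test_planted_signal(self):
        rng = np.random.default_rng(7)
        n = 1000
        X = pd.DataFrame(
            {
                "signal": rng.normal(size=n),
                "noise1": rng.normal(size=n),
                "noise2": rng.normal(size=n),
            }
        )
        y = 3.0 * X.signal + rng.normal(size=n)
        res = multivariable_regression(y, X)
        assert res.term_table.loc["signal", "p_value"] < 0.001
        assert res.term_table.loc["noise1", "p_value"] > 0.05
        assert res.term_table.loc["noise2", "p_value"] > 0.05

    def test_reduces_to_simple_regression(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=50)
        y = 1.5 * x + rng.normal(size=50)
        multi = multivariable_regression(y, pd.DataFrame({"x": x}))
        simple = simple_regression(x, y)
        assert multi.slope == pytest.approx(simple.slope, abs=1e-10)
        assert multi.term_table.loc["x", "p_value"] == pytest.approx(
            simple.p_value, abs=1e-10
        )

    def test_duplicated_predictor_rejected(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=30)
        X = pd.DataFrame({"a": x, "b": x})
        with pytest.raises(StatsValidationError, match="rank"):
            multivariable_regression(rng.normal(size=30), X)

    def test_logistic_median_split_variant(self):
        rng = np.random.default_rng(10)
        n = 400
        X = pd.DataFrame({"x": rng.normal(size=n)})
        y = 2.0 * X.x + rng.normal(size=n)
        res = multivariable_regression(y, X, logistic_median_split=True)
        assert res.term_table.loc["x", "p_value"] < 0.001


class TestSampleSize:
    def test_unit_effect_90pct_power(self):
        n1, n2 = t_test_sample_size(1.0, 1.0, power=0.9, alpha=0.05)
        assert (n1, n2) == (23, 23)
        # normal-approximation cross-check: ceil(2*(z_{.975}+z_{.9})^2)+1
        from scipy.stats import norm
        approx = int(np.ceil(2 * (norm.ppf(0.975) + norm.ppf(0.9)) ** 2)) + 1
        assert abs(n1 - approx) <= 1

    def test_larger_effect_needs_fewer(self):
        n_small, _ = t_test_sample_size(1.0, 1.0, power=0.9)
        n_large, _ = t_test_sample_size(2.0, 1.0, power=0.9)
        assert n_large < n_small

    def test_two_to_one_allocation(self):
        n1, n2 = t_test_sample_size(1.0, 1.0, power=0.9, allocation_ratio=2.0)
        assert n2 == 2 * n1

    def test_unreachable_power_capped(self):
        with pytest.raises(StatsValidationError):
            t_test_sample_size(1e-4, 1.0, power=0.9)

    def test_zero_effect_rejected(self):
        with pytest.raises(StatsValidationError):
            t_test_sample_size(0.0, 1.0)
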