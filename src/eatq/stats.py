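"""Agreement, comparison, regression and power statistics.

The battery mirrors what an observational imaging study needs:

* Bland–Altman agreement between two observers (mean difference d and
  limits d ± 1.96·SD of the differences, optionally on a percent scale);
* two-group comparisons (Student's/Welch's t, Mann–Whitney U, chi-square);
* simple and multivariable (block-entry) linear regression;
* two-sample t-test sample-size calculation.

Thin wrappers around scipy.stats and statsmodels with the study's
conventions baked in: two-sided p-values, sample SD (n−1) and pooled
variance for the default t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.power import TTestIndPower

__all__ = [
    "StatsValidationError",
    "AgreementResult",
    "ComparisonResult",
    "RegressionResult",
    "bland_altman",
    "limits_from_summary",
    "two_group_compare",
    "simple_regression",
    "multivariable_regression",
    "t_test_sample_size",
]

DEFAULT_LIMIT_FACTOR = 1.96
DEFAULT_ALPHA = 0.05


class StatsValidationError(ValueError):
    """Invalid input to a statistical routine."""


@dataclass
class AgreementResult:
    """Bland–Altman summary of paired measurements."""

    mean_difference_d: float
    sd_differences: float
    lower_limit: float
    upper_limit: float
    limit_factor: float
    n_pairs: int
    relative: bool


@dataclass
class ComparisonResult:
    test_name: str
    statistic: float
    p_value: float
    group_summaries: dict = field(default_factory=dict)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p_value: float
    n: int
    term_table: pd.DataFrame | None = None


def limits_from_summary(
    mean_difference_d: float, sd_differences: float, limit_factor: float = DEFAULT_LIMIT_FACTOR
) -> tuple[float, float]:
    """Limits of agreement reconstructed from a reported (d, SD) pair."""
    if sd_differences < 0:
        raise StatsValidationError("SD of differences must be non-negative")
    half = limit_factor * sd_differences
    return mean_difference_d - half, mean_difference_d + half


def bland_altman(
    pairs: Sequence[tuple[float, float]],
    relative: bool = True,
    limit_factor: float = DEFAULT_LIMIT_FACTOR,
) -> AgreementResult:
    """Bland–Altman agreement analysis of paired measurements.

    In relative mode (the convention for observer agreement on volumetric
    measures) each difference a−b is expressed as a percentage of the pair
    mean.  The SD uses the n−1 denominator; limits are d ± limit_factor·SD.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise StatsValidationError("pairs must be a sequence of (a, b) tuples")
    if len(arr) < 2:
        raise StatsValidationError(f"need at least 2 pairs, got {len(arr)}")
    diffs = arr[:, 0] - arr[:, 1]
    if relative:
        means = arr.mean(axis=1)
        if np.any(means <= 0):
            raise StatsValidationError("relative mode requires positive pair means")
        diffs = 100.0 * diffs / means
    d = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    lower, upper = limits_from_summary(d, sd, limit_factor)
    return AgreementResult(
        mean_difference_d=d,
        sd_differences=sd,
        lower_limit=lower,
        upper_limit=upper,
        limit_factor=limit_factor,
        n_pairs=len(arr),
        relative=relative,
    )


def two_group_compare(
    values_a: Sequence[float] | np.ndarray,
    values_b: Sequence[float] | np.ndarray,
    test_name: str = "students_t",
) -> ComparisonResult:
    """Two-sided comparison of two independent groups.

    ``students_t`` uses the pooled-variance t-test; ``welch_t`` drops the
    equal-variance assumption.  ``mann_whitney_u`` is the rank test.  For
    ``chi_square`` pass the two rows of a contingency table of counts.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if test_name == "chi_square":
        table = np.vstack([a, b])
        if np.any(table < 0):
            raise StatsValidationError("chi-square requires non-negative counts")
        chi2, p, _, _ = sps.chi2_contingency(table)
        summaries = {"table": table}
        return ComparisonResult("chi_square", float(chi2), float(p), summaries)
    if len(a) < 2 or len(b) < 2:
        raise StatsValidationError("each group needs at least 2 observations")
    summaries = {
        "a": {"n": len(a), "mean": float(a.mean()), "sd": float(a.std(ddof=1))},
        "b": {"n": len(b), "mean": float(b.mean()), "sd": float(b.std(ddof=1))},
    }
    if test_name == "students_t":
        stat, p = sps.ttest_ind(a, b, equal_var=True)
    elif test_name == "welch_t":
        stat, p = sps.ttest_ind(a, b, equal_var=False)
    elif test_name == "mann_whitney_u":
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise StatsValidationError(f"unknown test {test_name!r}")
    return ComparisonResult(test_name, float(stat), float(p), summaries)


def simple_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Least-squares line y = slope·x + intercept with Pearson r.

    The two-sided p-value comes from the t distribution with n−2 degrees
    of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise StatsValidationError("x and y must have equal length")
    if len(x) < 3:
        raise StatsValidationError(f"need n >= 3, got {len(x)}")
    if np.ptp(x) == 0:
        raise StatsValidationError("x is constant; regression undefined")
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p_value=float(res.pvalue),
        n=len(x),
    )


def multivariable_regression(
    outcome: Sequence[float],
    predictors: pd.DataFrame,
    logistic_median_split: bool = False,
) -> RegressionResult:
    """Block-entry multivariable regression of a continuous outcome.

    All predictors enter simultaneously into an ordinary least-squares
    model with intercept; the term table reports per-term coefficient,
    standard error and two-sided p.  ``logistic_median_split=True``
    instead dichotomises the outcome at its median and fits a logistic
    model, for users who want a literal logistic analysis of a continuous
    outcome.
    """
    y = np.asarray(outcome, dtype=float)
    X = pd.DataFrame(predictors).astype(float)
    n, k = X.shape
    if len(y) != n:
        raise StatsValidationError("outcome and predictors must have equal length")
    if n <= k + 1:
        raise StatsValidationError(f"need n > n_predictors + 1, got n={n}, k={k}")
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(n), X.to_numpy()]))
    if rank < k + 1:
        corr = X.corr().abs()
        collinear = [
            f"{a}~{b}"
            for i, a in enumerate(corr.columns)
            for b in corr.columns[i + 1 :]
            if corr.loc[a, b] > 0.999999
        ]
        raise StatsValidationError(
            f"design matrix rank deficient (rank {rank} < {k + 1}); "
            f"collinear terms: {collinear or 'unidentified'}"
        )
    design = sm.add_constant(X)
    if logistic_median_split:
        y_bin = (y > np.median(y)).astype(float)
        fit = sm.Logit(y_bin, design).fit(disp=0)
        r = float("nan")
    else:
        fit = sm.OLS(y, design).fit()
        r = float(np.sqrt(fit.rsquared))
    term_table = pd.DataFrame(
        {
            "coefficient": fit.params,
            "std_error": fit.bse,
            "p_value": fit.pvalues,
        }
    )
    slope = float(fit.params.iloc[1]) if k >= 1 else float("nan")
    overall_p = float(fit.f_pvalue) if not logistic_median_split else float(fit.llr_pvalue)
    return RegressionResult(
        slope=slope,
        intercept=float(fit.params.iloc[0]),
        r=r,
        p_value=overall_p,
        n=n,
        term_table=term_table,
    )


def t_test_sample_size(
    mean_diff: float,
    sd: float,
    power: float = 0.9,
    alpha: float = DEFAULT_ALPHA,
    allocation_ratio: float = 1.0,
    max_n: int = 10**7,
) -> tuple[int, int]:
    """Smallest group sizes for a two-sided two-sample t-test.

    ``allocation_ratio`` is n2/n1 (e.g. 2.0 enrols two subjects in group 2
    per subject in group 1).  Solved with the noncentral-t power function;
    returns (n1, n2) as the smallest integers reaching the target power.
    """
    if sd <= 0:
        raise StatsValidationError("sd must be positive")
    if mean_diff == 0:
        raise StatsValidationError("zero effect: required n is unbounded")
    if not 0 < power < 1 or not 0 < alpha < 1:
        raise StatsValidationError("power and alpha must lie in (0, 1)")
    if allocation_ratio <= 0:
        raise StatsValidationError("allocation ratio must be positive")
    effect = abs(mean_diff) / sd
    solver = TTestIndPower()
    try:
        with np.errstate(all="ignore"):
            n1_cont = solver.solve_power(
                effect_size=effect, alpha=alpha, power=power, ratio=allocation_ratio
            )
    except Exception as exc:
        raise StatsValidationError(
            f"sample-size solver failed (effect {effect:.3g}, power {power}): {exc}"
        ) from exc
    if not np.isfinite(n1_cont) or n1_cont > max_n:
        raise StatsValidationError(
            f"required sample size exceeds {max_n}; effect too small or power too high"
        )
    n1 = max(2, int(np.ceil(n1_cont)))
    # step down while the integer pair still meets the target power
    while n1 > 2:
        achieved = solver.power(
            effect_size=effect, nobs1=n1 - 1, alpha=alpha, ratio=allocation_ratio
        )
        if achieved >= power:
            n1 -= 1
        else:
            break
    n2 = max(2, int(np.ceil(n1 * allocation_ratio)))
    return n1, n2
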