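"""Weighted prevalence and cross-cohort comparison statistics.

Prevalence estimates carry Wilson 95% confidence intervals computed on the
effective sample size (sum w)^2 / sum w^2, so oversampling weights neither
understate nor overstate the information in a designed subsample.  Cohorts are
compared with Pearson chi-square tests, Cochran-Armitage linear-trend tests,
percent changes, prevalence ratios, and the sample skewness of z-score
distributions (population-moment convention g1 = m3 / m2^(3/2)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, chi2_contingency, skew
from statsmodels.stats.proportion import proportion_confint

from .inequality import TrendResult

__all__ = [
    "PrevalenceEstimate",
    "prevalence",
    "chisq_test",
    "chisq_linear_trend",
    "percent_change",
    "prevalence_ratio",
    "sample_skewness",
]


@dataclass(frozen=True)
class PrevalenceEstimate:
    """Weighted prevalence with effective counts and Wilson 95% CI."""

    numerator: float
    denominator: float
    prevalence: float
    ci_low: float
    ci_high: float


def prevalence(outcomes, weights=None) -> PrevalenceEstimate:
    """Weighted prevalence sum(w*y)/sum(w) with an effective-sample-size Wilson CI.

    ``numerator`` and ``denominator`` are effective counts: the denominator is
    (sum w)^2 / sum w^2 (equal to n under equal weights) and the numerator is
    prevalence times that.
    """
    y = np.asarray(outcomes, dtype=float)
    if y.size == 0:
        raise ValueError("need at least one subject")
    if np.any((y != 0) & (y != 1)):
        raise ValueError("outcomes must be binary 0/1")
    w = np.ones(y.size) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("total weight must be positive")
    p = float(np.sum(w * y) / total)
    n_eff = float(total**2 / np.sum(w**2))
    lo, hi = proportion_confint(p * n_eff, n_eff, alpha=0.05, method="wilson")
    return PrevalenceEstimate(
        numerator=p * n_eff,
        denominator=n_eff,
        prevalence=p,
        ci_low=float(lo),
        ci_high=float(hi),
    )


def chisq_test(counts) -> TrendResult:
    """Pearson chi-square test on a 2 x k table (no continuity correction).

    Rows are outcome yes/no, columns the groups being compared (cohorts);
    df = k - 1.  Counts may be non-integer (effective counts under weights).
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] != 2 or table.shape[1] < 2:
        raise ValueError("expected a 2 x k table with k >= 2")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) <= 0) or np.any(table.sum(axis=1) <= 0):
        raise ValueError("zero row or column margin: expected counts undefined")
    res = chi2_contingency(table, correction=False)
    return TrendResult(
        statistic=float(res.statistic),
        df=int(res.dof),
        p_value=float(res.pvalue),
        kind="chisq",
    )


def chisq_linear_trend(counts, scores) -> TrendResult:
    """Cochran-Armitage test for linear trend in proportions, df = 1.

    ``counts`` is a 2 x k table (successes row first); ``scores`` are strictly
    monotone per-column scores (e.g. cohort years).  The statistic is invariant
    to affine transformations of the scores, and for k = 2 it equals the
    Pearson chi-square on the 2 x 2 table.
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] != 2 or table.shape[1] < 2:
        raise ValueError("expected a 2 x k table with k >= 2")
    x = np.asarray(scores, dtype=float)
    if x.size != table.shape[1]:
        raise ValueError("one score per column required")
    d = np.diff(x)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("scores must be strictly monotone")
    successes = table[0]
    n = table.sum(axis=0)
    if np.any(n <= 0):
        raise ValueError("every column needs a positive total")
    N = n.sum()
    p_bar = successes.sum() / N
    if p_bar <= 0 or p_bar >= 1:
        raise ValueError("overall proportion degenerate (0 or 1)")
    x_bar = np.sum(n * x) / N
    num = np.sum(successes * (x - x_bar)) ** 2
    den = p_bar * (1 - p_bar) * (np.sum(n * x**2) - N * x_bar**2)
    stat = float(num / den)
    return TrendResult(statistic=stat, df=1, p_value=float(chi2.sf(stat, 1)), kind="chisq_trend")


def percent_change(p_from: float, p_to: float) -> float:
    """Signed percent change 100 * (p_to - p_from) / p_from; no rounding."""
    if p_from <= 0:
        raise ValueError("baseline proportion must be positive")
    return 100.0 * (p_to - p_from) / p_from


def prevalence_ratio(p_a: float, p_b: float) -> float:
    """Ratio p_a / p_b of two prevalences."""
    if p_b <= 0:
        raise ValueError("reference prevalence must be positive")
    return p_a / p_b


def sample_skewness(values) -> float:
    """Sample skewness g1 = m3 / m2^(3/2) (population central moments, no
    small-sample correction)."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 values")
    if np.var(v) == 0:
        raise ValueError("zero variance: skewness undefined")
    return float(skew(v, bias=True))
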