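"""Slope and relative indices of inequality over socioeconomic midpoint ranks.

Subjects are grouped into income quantiles (quintiles by default).  Each group
gets a midpoint (ridit) rank r_i = (cumulative share below it) + (its own
share)/2, spanning 0-1; exact quintiles give (0.1, 0.3, 0.5, 0.7, 0.9).

* SII (slope index of inequality): slope of outcome prevalence regressed on the
  midpoint rank, reported in percentage points — the absolute prevalence
  difference between the extremes of the socioeconomic hierarchy (rank 1 vs 0).
* RII (relative index of inequality): exponentiated slope from logistic
  regression of the outcome on the midpoint rank — an odds ratio comparing the
  top to the bottom of the hierarchy.

Sampling weights are supported throughout (inverse-probability weights from an
oversampling design, used as frequency weights in the likelihoods).  Cochran-Q
heterogeneity and inverse-variance meta-trend tests compare the SII/RII
coefficients across cohorts on the estimation scale (linear for SII, log-odds
for RII).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.stats import chi2
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .exceptions import ConvergenceError

__all__ = [
    "RankedGroups",
    "InequalityResult",
    "TrendResult",
    "assign_quantiles",
    "sii_grouped",
    "sii_individual",
    "rii_logistic",
    "heterogeneity_test",
    "meta_trend_test",
]

_Z95 = 1.959963984540054  # two-sided 95% normal critical value


@dataclass(frozen=True)
class RankedGroups:
    """Quantile membership with realized shares and midpoint ranks.

    ``group_index`` is 1-based and contiguous over non-empty groups;
    ``shares`` sum to 1 and ``midpoint_ranks`` are strictly increasing.
    """

    k_requested: int
    group_index: np.ndarray
    shares: np.ndarray
    midpoint_ranks: np.ndarray
    nominal: bool = False

    @property
    def n_groups(self) -> int:
        return len(self.shares)

    @property
    def rank_per_subject(self) -> np.ndarray:
        return self.midpoint_ranks[self.group_index - 1]


@dataclass(frozen=True)
class TrendResult:
    statistic: float
    df: int
    p_value: float
    kind: str


@dataclass(frozen=True)
class InequalityResult:
    """SII or RII point estimate with standard error and 95% CI.

    ``estimate`` is in percentage points for the SII and an odds ratio for the
    RII.  ``std_error`` is on the estimation scale: percentage points for the
    SII, log-odds for the RII; ``slope`` is the raw regression coefficient on
    that scale (equal to ``estimate`` for the SII, ``log(estimate)`` for the
    RII), which is the scale on which heterogeneity tests operate.
    """

    kind: str  # "SII" | "RII"
    estimate: float
    std_error: float
    ci_low: float
    ci_high: float
    slope: float
    method: str  # "grouped" | "individual"
    weighted: bool
    n: int


def assign_quantiles(values, k: int, weights=None, nominal: bool = False) -> RankedGroups:
    """Assign subjects to ``k`` (weighted) quantile groups of ``values``.

    Boundaries fall at cumulative shares j/k of the (weighted) distribution.
    Tied values are never split across a boundary: a tied block goes entirely
    to the group in which its inclusive cumulative share lands, so heavy ties
    produce unequal groups and non-nominal midpoint ranks.  Group shares are
    computed from realized sizes; with ``nominal=True`` the midpoint ranks are
    fixed at (i - 0.5)/k instead (worked-example reproduction).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if np.isnan(values).any():
        raise ValueError("missing values must be removed before quantile assignment")
    if k < 1:
        raise ValueError("k must be >= 1")
    n = values.size
    if n < k:
        raise ValueError(f"need at least k={k} subjects, got {n}")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != values.shape or np.any(w < 0) or not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite, non-negative, one per subject")
        if w.sum() <= 0:
            raise ValueError("total weight must be positive")
    order = np.argsort(values, kind="mergesort")
    sorted_vals = values[order]
    cum = np.cumsum(w[order]) / w.sum()
    # inclusive CDF: each subject takes the cumulative share at the end of its
    # tied block
    block_end = np.searchsorted(sorted_vals, sorted_vals, side="right") - 1
    F = cum[block_end]
    g_sorted = np.clip(np.ceil(F * k - 1e-9).astype(int), 1, k)
    groups = np.empty(n, dtype=int)
    groups[order] = g_sorted
    present = np.unique(groups)
    remap = {g: i + 1 for i, g in enumerate(present)}
    group_index = np.array([remap[g] for g in groups])
    shares = np.array(
        [w[group_index == i + 1].sum() for i in range(len(present))]
    ) / w.sum()
    if nominal:
        ranks = (present - 0.5) / k
    else:
        cum_below = np.concatenate([[0.0], np.cumsum(shares)[:-1]])
        ranks = cum_below + shares / 2.0
    return RankedGroups(
        k_requested=k,
        group_index=group_index,
        shares=shares,
        midpoint_ranks=ranks,
        nominal=nominal,
    )


def _check_slope_identity(slope, intercept, ranks, prev, tol=1e-10):
    # the SII must equal fitted prevalence at rank 1 minus at rank 0
    fitted_gap = (intercept + slope * 1.0) - (intercept + slope * 0.0)
    assert abs(fitted_gap - slope) < tol


def sii_grouped(prevalences, ranks, group_sizes=None, weighted: bool = False) -> InequalityResult:
    """SII from (weighted) least squares of group prevalence on midpoint rank.

    ``prevalences`` are proportions in [0, 1]; the estimate and its standard
    error are reported in percentage points.  With ``group_sizes`` the fit is
    size-weighted.  Two groups give a point estimate with the CI marked
    unavailable (NaN); fewer than two raise.
    """
    prev = np.asarray(prevalences, dtype=float)
    r = np.asarray(ranks, dtype=float)
    if prev.size != r.size or prev.size < 2:
        raise ValueError("need >= 2 groups with matching prevalences and ranks")
    if np.any((prev < 0) | (prev > 1)):
        raise ValueError("prevalences must be proportions in [0, 1]")
    if np.any((r <= 0) | (r >= 1)):
        raise ValueError("midpoint ranks must lie strictly inside (0, 1)")
    w = np.ones(prev.size) if group_sizes is None else np.asarray(group_sizes, float)
    X = sm.add_constant(r)
    res = sm.WLS(prev, X, weights=w).fit()
    slope = float(res.params[1]) * 100.0
    _check_slope_identity(res.params[1], res.params[0], r, prev)
    if prev.size > 2:
        se = float(res.bse[1]) * 100.0
        ci_low, ci_high = slope - _Z95 * se, slope + _Z95 * se
    else:
        se = ci_low = ci_high = float("nan")
    return InequalityResult(
        kind="SII",
        estimate=slope,
        std_error=se,
        ci_low=ci_low,
        ci_high=ci_high,
        slope=slope,
        method="grouped",
        weighted=weighted or group_sizes is not None,
        n=prev.size,
    )


def sii_individual(outcomes, ranks, weights=None) -> InequalityResult:
    """SII from an individual-level linear-probability regression.

    Weighted least squares of the binary outcome on each subject's group
    midpoint rank, with a heteroskedasticity-robust (HC1) standard error; the
    slope times 100 is the SII in percentage points.  With equal weights the
    point estimate equals :func:`sii_grouped` on the collapsed data with size
    weights.
    """
    y = np.asarray(outcomes, dtype=float)
    r = np.asarray(ranks, dtype=float)
    if y.size != r.size or y.size < 2:
        raise ValueError("need >= 2 subjects with matching outcomes and ranks")
    w = np.ones(y.size) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive total")
    X = sm.add_constant(r)
    res = sm.WLS(y, X, weights=w).fit(cov_type="HC1")
    slope = float(res.params[1]) * 100.0
    se = float(res.bse[1]) * 100.0
    return InequalityResult(
        kind="SII",
        estimate=slope,
        std_error=se,
        ci_low=slope - _Z95 * se,
        ci_high=slope + _Z95 * se,
        slope=slope,
        method="individual",
        weighted=weights is not None,
        n=y.size,
    )


def rii_logistic(outcomes, ranks, weights=None, trials=None) -> InequalityResult:
    """RII from maximum-likelihood logistic regression on midpoint ranks.

    Two input forms give identical point estimates:

    * individual: ``outcomes`` binary per subject, ``ranks`` the subject's
      group midpoint rank, optional frequency/design ``weights``;
    * grouped: ``outcomes`` = successes per group (may be non-integer),
      ``trials`` = group sizes.

    The RII is exp(slope); the 95% CI is exp(slope +- 1.96 * SE).
    ``std_error`` is reported on the log-odds scale.
    """
    y = np.asarray(outcomes, dtype=float)
    r = np.asarray(ranks, dtype=float)
    if y.size != r.size:
        raise ValueError("outcomes and ranks must align")
    if trials is not None:
        t = np.asarray(trials, dtype=float)
        if np.any(t <= 0) or np.any(y < 0) or np.any(y > t):
            raise ValueError("grouped input needs 0 <= successes <= trials > 0")
        endog = y / t
        vw = t * (np.ones(y.size) if weights is None else np.asarray(weights, float))
        method = "grouped"
        n = int(round(t.sum()))
    else:
        if np.any((y != 0) & (y != 1)):
            raise ValueError("individual outcomes must be binary 0/1")
        endog = y
        vw = np.ones(y.size) if weights is None else np.asarray(weights, dtype=float)
        method = "individual"
        n = y.size
    if np.any(vw < 0) or vw.sum() <= 0:
        raise ValueError("weights must be non-negative with positive total")
    successes = float(np.sum(endog * vw))
    failures = float(np.sum((1.0 - endog) * vw))
    if successes <= 0 or failures <= 0:
        raise ValueError("outcome has no variation: cannot fit a logistic model")
    X = sm.add_constant(r)
    model = sm.GLM(endog, X, family=sm.families.Binomial(), var_weights=vw)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(maxiter=100, tol=1e-10)
    except PerfectSeparationError as exc:  # pragma: no cover - scipy-version dependent
        raise ConvergenceError(f"complete separation in logistic fit: {exc}") from exc
    slope = float(res.params[1])
    se = float(res.bse[1])
    if not np.isfinite(slope) or not np.isfinite(se) or abs(slope) > 50:
        raise ConvergenceError(
            "logistic fit did not converge to a finite slope "
            f"(slope={slope!r}, se={se!r}); possible complete separation"
        )
    return InequalityResult(
        kind="RII",
        estimate=float(np.exp(slope)),
        std_error=se,
        ci_low=float(np.exp(slope - _Z95 * se)),
        ci_high=float(np.exp(slope + _Z95 * se)),
        slope=slope,
        method=method,
        weighted=weights is not None,
        n=n,
    )


def _check_meta_inputs(estimates, std_errors):
    b = np.asarray(estimates, dtype=float)
    s = np.asarray(std_errors, dtype=float)
    if b.size != s.size or b.size < 2:
        raise ValueError("need >= 2 estimates with standard errors")
    if np.any(~np.isfinite(b)) or np.any(~np.isfinite(s)) or np.any(s <= 0):
        raise ValueError("standard errors must be finite and positive")
    return b, s


def heterogeneity_test(estimates, std_errors) -> TrendResult:
    """Cochran-Q test of whether coefficients share a common true value.

    Q = sum (b_i - b_bar)^2 / se_i^2 with b_bar the inverse-variance-weighted
    mean; chi-square with (count - 1) degrees of freedom.  For the RII the
    inputs must be log-odds slopes, not odds ratios.
    """
    b, s = _check_meta_inputs(estimates, std_errors)
    w = 1.0 / s**2
    b_bar = float(np.sum(w * b) / np.sum(w))
    q = float(np.sum(w * (b - b_bar) ** 2))
    df = b.size - 1
    return TrendResult(statistic=q, df=df, p_value=float(chi2.sf(q, df)), kind="heterogeneity")


def meta_trend_test(estimates, std_errors, scores) -> TrendResult:
    """Linear trend in coefficients across cohorts (fixed-effect meta-regression).

    Inverse-variance-weighted regression of the coefficients on ``scores``
    (e.g. cohort years); the squared Wald statistic of the meta-regression
    slope is referred to chi-square with 1 df.
    """
    b, s = _check_meta_inputs(estimates, std_errors)
    x = np.asarray(scores, dtype=float)
    if x.size != b.size or np.unique(x).size < 2:
        raise ValueError("scores must align with estimates and not be constant")
    w = 1.0 / s**2
    x_bar = np.sum(w * x) / np.sum(w)
    sxx = np.sum(w * (x - x_bar) ** 2)
    slope = np.sum(w * (x - x_bar) * b) / sxx
    stat = float(slope**2 * sxx)  # slope^2 / var(slope), var = 1/sxx
    return TrendResult(statistic=stat, df=1, p_value=float(chi2.sf(stat, 1)), kind="meta_trend")
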