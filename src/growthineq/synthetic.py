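"""Synthetic birth cohorts with income-graded stunting and overweight risk.

The generator emulates the statistical structure the inequality analysis
assumes: a continuous family-income distribution, a linear risk gradient on the
relative income rank r in [0, 1] for stunting (P(haz < -2) = a + b*r) and for
overweight (P(bmiz > 2) = a' + b'*r), per-visit attrition, and an oversampling
design ("all low-birthweight children plus a fixed fraction of the rest") whose
inverse-probability weights the estimators must undo.

Latent z-scores are normal within income rank: to hit a tail probability p at
rank r the latent mean is shifted to -2 - Phi^{-1}(p) * sd (and symmetrically
+2 - Phi^{-1}(1-p) * sd for the overweight tail).  Raw length and weight are
produced by the inverse LMS transform against a supplied growth reference, so
the z-score engine recovers the latent scores exactly (round-trip).  A
child-level frailty shared across visits correlates birthweight with later
stunting, which is what makes unweighted estimation on the oversampled design
visibly biased.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm, rankdata

from .anthropometry import GrowthReference, inverse_lms
from .exceptions import DesignCoverageError

__all__ = [
    "LinearRisk",
    "CohortConfig",
    "Stratum",
    "SamplingDesign",
    "generate_cohort",
    "apply_sampling_design",
    "simulate_attrition",
    "low_birthweight_design",
    "write_cohort_csv",
    "COHORT_COLUMNS",
    "DAYS_PER_MONTH",
]

DAYS_PER_MONTH = 30.4375  # 365.25 / 12

#: cohort CSV schema (column order)
COHORT_COLUMNS = (
    "child_id",
    "cohort",
    "sex",
    "visit",
    "age_days",
    "weight_kg",
    "length_cm",
    "recumbent",
    "income",
    "birthweight_g",
    "sampling_weight",
)

_VISIT_LABELS = {0: "birth", 12: "1y", 24: "2y", 48: "4y"}


@dataclass(frozen=True)
class LinearRisk:
    """Linear risk-on-rank gradient p(r) = intercept + slope * r, r in [0, 1]."""

    intercept: float
    slope: float

    def __post_init__(self) -> None:
        for r in (0.0, 1.0):
            p = self.intercept + self.slope * r
            if not 0.0 <= p <= 1.0:
                raise ValueError(
                    f"risk {p:.3f} at rank {r} outside [0, 1]; "
                    "invalid gradient configuration"
                )

    def __call__(self, r):
        return self.intercept + self.slope * np.asarray(r, dtype=float)


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to generate one cohort deterministically.

    Income is log-normal (``income_log_mean``/``income_log_sd`` on the log
    scale), ties impossible.  ``attrition_rate`` is the per-follow-up-visit
    probability of a missed visit (the birth examination is always present).
    ``frailty_corr`` correlates each child's visit-level z-score noise with a
    child-level frailty, tying birthweight to later anthropometry.
    """

    cohort_label: str
    n_births: int
    income_log_mean: float = 6.0
    income_log_sd: float = 0.8
    visit_ages_months: Sequence[int] = (0, 12, 24, 48)
    stunting_gradient: LinearRisk = LinearRisk(0.28, -0.28)
    overweight_gradient: LinearRisk = LinearRisk(0.07, 0.08)
    haz_noise_sd: float = 1.0
    bmiz_noise_sd: float = 1.0
    attrition_rate: float = 0.08
    frailty_corr: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_births < 0:
            raise ValueError("n_births must be >= 0")
        if not 0.0 <= self.attrition_rate < 1.0:
            raise ValueError("attrition_rate must be in [0, 1)")
        if not 0.0 <= self.frailty_corr < 1.0:
            raise ValueError("frailty_corr must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        for key in ("stunting_gradient", "overweight_gradient"):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = LinearRisk(**raw[key])
        if "visit_ages_months" in raw:
            raw["visit_ages_months"] = tuple(raw["visit_ages_months"])
        return cls(**raw)


def visit_label(months: int) -> str:
    return _VISIT_LABELS.get(int(months), f"{int(months)}m")


def _tail_shifted_mean(p, cut, sd, upper):
    """Latent normal mean with P(z < cut) = p (or P(z > cut) = p if upper)."""
    p = np.clip(np.asarray(p, dtype=float), 1e-12, 1.0 - 1e-12)
    if upper:
        return cut - sd * norm.ppf(1.0 - p)
    return cut - sd * norm.ppf(p)


def generate_cohort(config: CohortConfig, reference: GrowthReference) -> pd.DataFrame:
    """Generate one cohort as a tidy frame, one row per child-visit.

    Deterministic given ``config.seed``.  Each child's relative income rank is
    the empirical quantile of its drawn income; visit-level latent haz and bmiz
    are drawn around the rank-dependent means, converted to raw length and BMI
    by the inverse LMS transform against ``reference``, and weight is
    ``BMI * (length/100)**2``.  Birthweight is the birth-visit weight in grams
    (10 g precision), computed for every child whether or not a birth row is
    requested.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_births
    if n == 0:
        return pd.DataFrame(columns=list(COHORT_COLUMNS))

    income = rng.lognormal(config.income_log_mean, config.income_log_sd, n)
    rank = (rankdata(income, method="average") - 0.5) / n
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    child_id = np.array(
        [f"{config.cohort_label}-{i:06d}" for i in range(1, n + 1)], dtype=object
    )
    frail_h = rng.standard_normal(n)
    frail_b = rng.standard_normal(n)
    rho = config.frailty_corr
    mix = np.sqrt(1.0 - rho**2)

    mu_h = _tail_shifted_mean(
        config.stunting_gradient(rank), -2.0, config.haz_noise_sd, upper=False
    )
    mu_b = _tail_shifted_mean(
        config.overweight_gradient(rank), 2.0, config.bmiz_noise_sd, upper=True
    )

    def measurements(age_days: float):
        z_h = mu_h + config.haz_noise_sd * (rho * frail_h + mix * rng.standard_normal(n))
        z_b = mu_b + config.bmiz_noise_sd * (rho * frail_b + mix * rng.standard_normal(n))
        L, M, S = reference.lookup("length_height_for_age", sex, np.full(n, age_days))
        length = inverse_lms(z_h, L, M, S)
        L, M, S = reference.lookup("bmi_for_age", sex, np.full(n, age_days))
        bmi = inverse_lms(z_b, L, M, S)
        weight = bmi * (length / 100.0) ** 2
        return length, weight

    months = sorted(int(m) for m in config.visit_ages_months)
    # birth anthropometry exists for every child (hospital record), even when
    # a birth visit row is not requested
    birth_length, birth_weight = measurements(0.0)
    birthweight_g = np.round(birth_weight * 1000.0, -1)

    frames = []
    for m in months:
        age_days = round(m * DAYS_PER_MONTH)
        if m == 0:
            length, weight = birth_length, birth_weight
            keep = np.ones(n, dtype=bool)
        else:
            length, weight = measurements(float(age_days))
            keep = rng.random(n) >= config.attrition_rate
        frames.append(
            pd.DataFrame(
                {
                    "child_id": child_id[keep],
                    "cohort": config.cohort_label,
                    "sex": sex[keep],
                    "visit": visit_label(m),
                    "age_days": float(age_days),
                    "weight_kg": weight[keep],
                    "length_cm": length[keep],
                    "recumbent": age_days <= 730,
                    "income": income[keep],
                    "birthweight_g": birthweight_g[keep],
                    "sampling_weight": 1.0,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out[list(COHORT_COLUMNS)]


@dataclass(frozen=True)
class Stratum:
    """A sampling stratum: a vectorised predicate on the cohort frame and an
    inclusion probability in (0, 1]."""

    name: str
    predicate: Callable[[pd.DataFrame], np.ndarray]
    inclusion_prob: float

    def __post_init__(self) -> None:
        if not 0.0 < self.inclusion_prob <= 1.0:
            raise ValueError("inclusion probability must be in (0, 1]")


@dataclass(frozen=True)
class SamplingDesign:
    strata: Sequence[Stratum]


def low_birthweight_design(threshold_g: float = 2500.0, pi_other: float = 0.2) -> SamplingDesign:
    """The oversampling design "all low-birthweight children plus a fraction
    ``pi_other`` of the remaining": certainty stratum below ``threshold_g``."""
    return SamplingDesign(
        strata=(
            Stratum("low_birthweight", lambda f: f["birthweight_g"].to_numpy(float) < threshold_g, 1.0),
            Stratum("other", lambda f: f["birthweight_g"].to_numpy(float) >= threshold_g, pi_other),
        )
    )


def apply_sampling_design(
    frame: pd.DataFrame, design: SamplingDesign, seed: int
) -> pd.DataFrame:
    """Subsample children per the design and attach inverse-probability weights.

    Selection is at the child level (one draw per ``child_id``; all of a
    selected child's visit rows are retained together).  Every row must match
    exactly one stratum; retained rows get ``sampling_weight = 1 / pi``.
    """
    if frame.empty:
        raise ValueError("cannot apply a sampling design to an empty cohort")
    n = len(frame)
    match_count = np.zeros(n, dtype=int)
    pi = np.full(n, np.nan)
    for stratum in design.strata:
        mask = np.asarray(stratum.predicate(frame), dtype=bool)
        match_count += mask
        pi[mask] = stratum.inclusion_prob
    if np.any(match_count != 1):
        bad = int(np.sum(match_count == 0)), int(np.sum(match_count > 1))
        raise DesignCoverageError(
            f"design does not partition the cohort: {bad[0]} rows match no "
            f"stratum, {bad[1]} rows match several"
        )
    ids = frame["child_id"].to_numpy(object)
    uniq, inverse = np.unique(ids, return_inverse=True)
    # stratum membership must be constant within child
    pi_per_child = np.full(len(uniq), np.nan)
    pi_per_child[inverse] = pi
    if np.any(np.abs(pi_per_child[inverse] - pi) > 0):
        raise DesignCoverageError("stratum membership varies within a child")
    rng = np.random.default_rng(seed)
    u = rng.random(len(uniq))
    selected_child = u < pi_per_child
    keep = selected_child[inverse]
    out = frame.loc[keep].copy()
    out["sampling_weight"] = 1.0 / pi[keep]
    return out.reset_index(drop=True)


def simulate_attrition(frame: pd.DataFrame, rate: float, seed: int) -> pd.DataFrame:
    """Drop each row independently with probability ``rate`` (deterministic per seed)."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("attrition rate must be in [0, 1)")
    if rate == 0.0:
        return frame.copy()
    rng = np.random.default_rng(seed)
    keep = rng.random(len(frame)) >= rate
    return frame.loc[keep].reset_index(drop=True)


def write_cohort_csv(frame: pd.DataFrame, path) -> None:
    """Write the cohort CSV with the canonical header; missing values empty."""
    frame[list(COHORT_COLUMNS)].to_csv(path, index=False, na_rep="")
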