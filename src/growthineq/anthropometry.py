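"""Growth-standard z-scores via the LMS method and nutritional-status classification.

A growth reference parameterises the distribution of a body measurement at each
age (or length) by a Box-Cox power ``L``, a median ``M`` and a coefficient of
variation ``S``.  The z-score of a measurement ``x`` is

    z = ((x / M)**L - 1) / (L * S)     if L != 0
    z = ln(x / M) / S                  if L == 0

Four indicators are supported: length/height-for-age (haz), weight-for-age
(waz), weight-for-length/height (whz) and BMI-for-age (bmiz).  Status cut-offs
use strict inequalities: stunting/underweight/wasting are z < -2 on the
respective indicator and overweight is bmiz > 2.

The plain LMS transform is applied throughout; the restricted transform some
growth-standard software applies to weight-based indicators beyond +-3 SD is
deliberately not implemented (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ReferenceRangeError, SchemaError

__all__ = [
    "GrowthReference",
    "lms_zscore",
    "inverse_lms",
    "compute_indicators",
    "classify",
    "INDICATORS",
    "Z_COLUMNS",
    "DEFAULT_PLAUSIBILITY",
]

#: canonical indicator names used in reference tables
INDICATORS = (
    "length_height_for_age",
    "weight_for_age",
    "weight_for_length_height",
    "bmi_for_age",
)

#: z-score column -> (reference indicator, index column of the cohort frame)
Z_COLUMNS = {
    "haz": ("length_height_for_age", "age_days"),
    "waz": ("weight_for_age", "age_days"),
    "whz": ("weight_for_length_height", "length_cm"),
    "bmiz": ("bmi_for_age", "age_days"),
}

#: biologically implausible ranges (inclusive bounds of the plausible region),
#: following standard growth-standard data-cleaning limits
DEFAULT_PLAUSIBILITY = {
    "haz": (-6.0, 6.0),
    "waz": (-6.0, 5.0),
    "whz": (-5.0, 5.0),
    "bmiz": (-5.0, 5.0),
}

_L_EPS = 1e-12  # |L| below this uses the logarithmic branch


def lms_zscore(x, L, M, S):
    """z-score of measurement ``x`` under LMS parameters.

    All arguments broadcast; ``x``, ``M`` and ``S`` must be positive where not
    NaN.  Continuous in ``L`` at 0 (log branch).
    """
    x, L, M, S = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (x, L, M, S))
    )
    for name, arr in (("x", x), ("M", M), ("S", S)):
        if np.any(arr[~np.isnan(arr)] <= 0):
            raise ValueError(f"{name} must be strictly positive")
    ratio = x / M
    with np.errstate(invalid="ignore", divide="ignore"):
        log_branch = np.log(ratio) / S
        Lsafe = np.where(np.abs(L) > _L_EPS, L, 1.0)
        power_branch = (ratio ** Lsafe - 1.0) / (Lsafe * S)
        z = np.where(np.abs(L) > _L_EPS, power_branch, log_branch)
    if z.ndim == 0:
        return float(z)
    return z


def inverse_lms(z, L, M, S):
    """Measurement with z-score ``z`` under LMS parameters (inverse transform).

    Requires ``1 + L*S*z > 0`` when ``L != 0``; round-trips with
    :func:`lms_zscore` to well below 1e-9.
    """
    z, L, M, S = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (z, L, M, S))
    )
    for name, arr in (("M", M), ("S", S)):
        if np.any(arr[~np.isnan(arr)] <= 0):
            raise ValueError(f"{name} must be strictly positive")
    base = 1.0 + L * S * z
    bad = (np.abs(L) > _L_EPS) & ~np.isnan(base) & (base <= 0)
    if np.any(bad):
        raise ValueError("z outside the domain of the inverse LMS transform")
    with np.errstate(invalid="ignore"):
        Lsafe = np.where(np.abs(L) > _L_EPS, L, 1.0)
        x = np.where(
            np.abs(L) > _L_EPS,
            M * np.where(base > 0, base, np.nan) ** (1.0 / Lsafe),
            M * np.exp(S * z),
        )
    if x.ndim == 0:
        return float(x)
    return x


_REFERENCE_COLUMNS = ("indicator", "sex", "index_value", "L", "M", "S")


@dataclass
class GrowthReference:
    """L/M/S parameter rows indexed by indicator, sex and age (or length).

    The table has one row per grid point with columns
    ``indicator, sex, index_value, L, M, S``; parameters at off-grid index
    values are linearly interpolated, with no extrapolation outside the grid.
    """

    table: pd.DataFrame
    _grids: dict = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in _REFERENCE_COLUMNS if c not in self.table.columns]
        if missing:
            raise SchemaError(f"reference table missing columns: {missing}")
        for (indicator, sex), grp in self.table.groupby(["indicator", "sex"]):
            grp = grp.sort_values("index_value")
            grid = grp["index_value"].to_numpy(float)
            if np.any(np.diff(grid) <= 0):
                raise ValueError(
                    f"index grid not strictly increasing for {indicator}/{sex}"
                )
            if np.any(grp["M"].to_numpy(float) <= 0) or np.any(
                grp["S"].to_numpy(float) <= 0
            ):
                raise ValueError(f"M and S must be positive for {indicator}/{sex}")
            self._grids[(indicator, sex)] = (
                grid,
                grp["L"].to_numpy(float),
                grp["M"].to_numpy(float),
                grp["S"].to_numpy(float),
            )

    @classmethod
    def from_csv(cls, path) -> "GrowthReference":
        return cls(pd.read_csv(path))

    def indicators(self):
        return sorted({k[0] for k in self._grids})

    def lookup(self, indicator: str, sex, index_value, out_of_range: str = "raise"):
        """Interpolated ``(L, M, S)`` at ``index_value`` for one indicator.

        ``sex`` and ``index_value`` may be arrays (broadcast together).  With
        ``out_of_range="raise"`` an index value outside the grid raises
        :class:`ReferenceRangeError`; with ``"nan"`` it yields NaN parameters.
        """
        sex_arr = np.asarray(sex, dtype=object)
        idx = np.asarray(index_value, dtype=float)
        sex_arr, idx = np.broadcast_arrays(sex_arr, idx)
        scalar = idx.ndim == 0
        sex_arr = np.atleast_1d(sex_arr)
        idx = np.atleast_1d(idx)
        out = [np.full(idx.shape, np.nan) for _ in range(3)]
        for s in pd.unique(sex_arr):
            key = (indicator, s)
            if key not in self._grids:
                raise KeyError(f"no reference rows for indicator={indicator} sex={s}")
            grid, L, M, S = self._grids[key]
            mask = sex_arr == s
            vals = idx[mask]
            inside = (vals >= grid[0]) & (vals <= grid[-1])
            if out_of_range == "raise" and np.any(~inside & ~np.isnan(vals)):
                bad = vals[~inside & ~np.isnan(vals)][0]
                raise ReferenceRangeError(
                    f"index value {bad} outside reference grid "
                    f"[{grid[0]}, {grid[-1]}] for {indicator}/{s}"
                )
            safe = np.where(inside, vals, np.nan)
            for j, param in enumerate((L, M, S)):
                out[j][mask] = np.interp(safe, grid, param)
        if scalar:
            return tuple(float(o[0]) for o in out)
        return tuple(out)


def lookup_reference(ref: GrowthReference, indicator: str, sex, index_value):
    """Functional alias for :meth:`GrowthReference.lookup` (raising variant)."""
    return ref.lookup(indicator, sex, index_value, out_of_range="raise")


def compute_indicators(
    frame: pd.DataFrame,
    reference: GrowthReference,
    plausibility: dict | None = None,
) -> pd.DataFrame:
    """Append haz/waz/whz/bmiz z-scores and implausibility flags to a cohort frame.

    Expects columns ``sex``, ``age_days``, ``weight_kg``, ``length_cm``.  BMI is
    ``weight_kg / (length_cm/100)**2``.  A missing measurement leaves the
    dependent z-scores missing (NaN), never zero; an index value outside the
    reference grid likewise yields a missing z-score.  ``<z>_flag`` columns mark
    biologically implausible values, which downstream prevalence computations
    must exclude.
    """
    plausibility = dict(DEFAULT_PLAUSIBILITY, **(plausibility or {}))
    out = frame.copy()
    sex = out["sex"].to_numpy(object)
    age = out["age_days"].to_numpy(float)
    weight = out["weight_kg"].to_numpy(float)
    length = out["length_cm"].to_numpy(float)
    with np.errstate(invalid="ignore"):
        bmi = weight / (length / 100.0) ** 2
    measures = {"haz": length, "waz": weight, "whz": weight, "bmiz": bmi}
    index_values = {"age_days": age, "length_cm": length}
    for zcol, (indicator, index_col) in Z_COLUMNS.items():
        x = measures[zcol]
        L, M, S = reference.lookup(
            indicator, sex, index_values[index_col], out_of_range="nan"
        )
        valid = ~np.isnan(x) & (x > 0) & ~np.isnan(M)
        z = np.full(len(out), np.nan)
        if valid.any():
            z[valid] = lms_zscore(x[valid], L[valid], M[valid], S[valid])
        lo, hi = plausibility[zcol]
        out[zcol] = z
        out[f"{zcol}_flag"] = ~np.isnan(z) & ((z < lo) | (z > hi))
    return out


#: nutritional-status column -> (z column, direction, cut-off); strict inequalities
STATUS_RULES = {
    "stunted": ("haz", "lt", -2.0),
    "underweight": ("waz", "lt", -2.0),
    "wasted": ("whz", "lt", -2.0),
    "overweight": ("bmiz", "gt", 2.0),
}


def classify(frame: pd.DataFrame) -> pd.DataFrame:
    """Append boolean status columns derived from z-scores at the +-2 cut-offs.

    ``stunted``/``underweight``/``wasted`` are z < -2 (strict) on haz/waz/whz;
    ``overweight`` is bmiz > 2 (strict); a z of exactly +-2 is classified
    negative.  Missing or implausibility-flagged z-scores give a missing status
    (pandas NA), excluded from downstream numerators and denominators.
    """
    out = frame.copy()
    for status, (zcol, direction, cut) in STATUS_RULES.items():
        z = out[zcol].to_numpy(float)
        flagged = out[f"{zcol}_flag"].to_numpy(bool)
        usable = ~np.isnan(z) & ~flagged
        positive = (z < cut) if direction == "lt" else (z > cut)
        col = pd.array([pd.NA] * len(out), dtype="boolean")
        col[usable] = positive[usable]
        out[status] = col
    return out
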