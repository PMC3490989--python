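"""End-to-end orchestration: cohort CSVs -> z-scores -> classification ->
income quintiles -> SII/RII -> cross-cohort trend and heterogeneity tests.

One :class:`AnalysisConfig` drives the whole run and the outputs mirror the
three summary tables of a repeated-cohort inequality analysis: overall
prevalence by cohort and visit, prevalence by income quintile with SII and RII,
and cross-cohort test statistics.  Everything is deterministic given the inputs
and configuration; output CSVs are byte-identical across reruns.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anthropometry import GrowthReference, classify, compute_indicators
from .exceptions import ConvergenceError, SchemaError
from .inequality import (
    assign_quantiles,
    heterogeneity_test,
    meta_trend_test,
    rii_logistic,
    sii_grouped,
    sii_individual,
)
from .synthetic import COHORT_COLUMNS
from .trends import chisq_linear_trend, chisq_test, percent_change, prevalence

logger = logging.getLogger("growthineq")

__all__ = [
    "AnalysisConfig",
    "AnalysisReport",
    "read_cohort_csv",
    "run_analysis",
    "render_report",
    "VISIT_WINDOWS_MONTHS",
]

#: visit label -> [lo, hi) age window in months; windows are wide because real
#: visit ages scatter around the nominal age (a "two-year" round can average
#: 19-24 months)
VISIT_WINDOWS_MONTHS = {
    "birth": (0.0, 1.0),
    "1y": (9.0, 18.0),
    "2y": (18.0, 30.0),
    "4y": (42.0, 60.0),
}

#: analysis indicator -> status column from :func:`growthineq.anthropometry.classify`
INDICATOR_STATUS = {
    "stunting": "stunted",
    "underweight": "underweight",
    "wasting": "wasted",
    "overweight": "overweight",
}

_DAYS_PER_MONTH = 30.4375


@dataclass
class AnalysisConfig:
    """Configuration of a full analysis run.

    ``cohort_files`` maps cohort label -> CSV path (insertion order is the
    temporal order used for trend scores; numeric labels are used as scores
    directly).  ``sii_method`` chooses the grouped (prevalence-on-rank,
    size-weighted) or individual (linear-probability, robust-SE) SII estimator;
    ``use_nominal_ranks`` fixes midpoint ranks at (i-0.5)/k instead of the
    realized group shares; ``weighted`` applies sampling weights throughout.
    """

    cohort_files: dict
    reference_file: str
    visits: tuple = ("birth", "1y", "2y", "4y")
    indicators: tuple = ("stunting", "overweight")
    k_groups: int = 5
    sii_method: str = "grouped"
    use_nominal_ranks: bool = False
    weighted: bool = True
    seed: int = 0
    output_dir: str | None = None
    visit_windows: dict = field(default_factory=lambda: dict(VISIT_WINDOWS_MONTHS))

    def __post_init__(self) -> None:
        if not self.cohort_files:
            raise ValueError("need at least one cohort")
        if self.k_groups < 2:
            raise ValueError("k_groups must be >= 2")
        if self.sii_method not in ("grouped", "individual"):
            raise ValueError("sii_method must be 'grouped' or 'individual'")
        unknown = set(self.indicators) - set(INDICATOR_STATUS)
        if unknown:
            raise ValueError(f"unknown indicators: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        if "cohorts" in raw:  # list of {label, path} mappings
            raw["cohort_files"] = {c["label"]: c["path"] for c in raw.pop("cohorts")}
        if "reference" in raw:
            raw["reference_file"] = raw.pop("reference")
        for key in ("visits", "indicators"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class AnalysisReport:
    """All output tables of one run plus reconciliation metadata."""

    prevalence_table: pd.DataFrame
    quintile_table: pd.DataFrame
    inequality_table: pd.DataFrame
    trend_table: pd.DataFrame
    change_table: pd.DataFrame
    metadata: dict

    def write(self, output_dir) -> None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.prevalence_table.to_csv(out / "prevalence.csv", index=False)
        self.quintile_table.to_csv(out / "quintile_prevalence.csv", index=False)
        self.inequality_table.to_csv(out / "inequality.csv", index=False)
        self.trend_table.to_csv(out / "trend_tests.csv", index=False)
        self.change_table.to_csv(out / "changes.csv", index=False)
        with open(out / "run_log.txt", "w") as fh:
            for key in sorted(self.metadata):
                fh.write(f"{key}: {self.metadata[key]}\n")
        with open(out / "report.txt", "w") as fh:
            fh.write(render_report(self))


_REQUIRED_COLUMNS = set(COHORT_COLUMNS)


def read_cohort_csv(path):
    """Read and validate a cohort CSV.

    Returns ``(frame, row_errors)`` where ``row_errors`` is a list of
    ``(row_index, reason)`` for malformed rows (collected and dropped, never
    silently).  A missing required column raises :class:`SchemaError` naming it.
    """
    frame = pd.read_csv(path)
    missing = _REQUIRED_COLUMNS - set(frame.columns)
    if missing:
        raise SchemaError(f"cohort file {path} missing required columns: {sorted(missing)}")
    errors = []

    def flag(mask, reason):
        for idx in frame.index[mask.fillna(False) if hasattr(mask, "fillna") else mask]:
            errors.append((int(idx), reason))

    flag(frame["weight_kg"].notna() & (frame["weight_kg"] <= 0), "non-positive weight_kg")
    flag(frame["length_cm"].notna() & (frame["length_cm"] <= 0), "non-positive length_cm")
    flag(frame["sampling_weight"].notna() & (frame["sampling_weight"] < 0), "negative sampling_weight")
    flag(~frame["sex"].isin(["male", "female"]), "sex not in {male, female}")
    flag(frame["age_days"].isna() | (frame["age_days"] < 0), "missing or negative age_days")
    flag(frame.duplicated(subset=["child_id", "visit"], keep=False)
         & frame.duplicated(subset=["child_id", "visit"], keep="first"),
         "duplicate (child_id, visit)")
    bad_rows = sorted({idx for idx, _ in errors})
    clean = frame.drop(index=bad_rows).reset_index(drop=True)
    if clean.empty:
        logger.warning("cohort file %s contains no valid data rows", path)
    if errors:
        logger.warning("cohort file %s: dropped %d malformed rows", path, len(bad_rows))
    n_missing = int(clean[["weight_kg", "length_cm", "income"]].isna().sum().sum())
    logger.info("read %s: %d rows, %d missing values", path, len(clean), n_missing)
    return clean, errors


def _assign_visits(frame: pd.DataFrame, windows: dict) -> pd.Series:
    months = frame["age_days"].to_numpy(float) / _DAYS_PER_MONTH
    visit = np.full(len(frame), None, dtype=object)
    for label, (lo, hi) in windows.items():
        visit[(months >= lo) & (months < hi)] = label
    return pd.Series(visit, index=frame.index)


def _cell(frame, indicator, weighted):
    """Analysable subset and weights for one cohort/visit/indicator cell."""
    status = INDICATOR_STATUS[indicator]
    sub = frame[frame[status].notna()]
    y = sub[status].to_numpy(dtype=object) == True  # noqa: E712  (nullable boolean)
    y = y.astype(float)
    w = sub["sampling_weight"].to_numpy(float) if weighted else np.ones(len(sub))
    return sub, y, w


def run_analysis(config: AnalysisConfig, reference: GrowthReference | None = None,
                 cohort_frames: dict | None = None) -> AnalysisReport:
    """Run the full pipeline and return an :class:`AnalysisReport`.

    ``cohort_frames`` (label -> DataFrame) bypasses file reading, for in-memory
    use; otherwise ``config.cohort_files`` are read and validated.  A visit
    absent from a cohort is reported as unavailable (NaN cells), never an
    abort.
    """
    reference = reference or GrowthReference.from_csv(config.reference_file)
    labels = list(config.cohort_files) if cohort_frames is None else list(cohort_frames)
    metadata = {
        "package_version": __version__,
        "seed": config.seed,
        "k_groups": config.k_groups,
        "sii_method": config.sii_method,
        "use_nominal_ranks": config.use_nominal_ranks,
        "weighted": config.weighted,
        "cohorts": ",".join(str(l) for l in labels),
    }
    cohorts = {}
    for label in labels:
        if cohort_frames is not None:
            frame, errors = cohort_frames[label].copy(), []
        else:
            frame, errors = read_cohort_csv(config.cohort_files[label])
        n_input = len(frame)
        frame = compute_indicators(frame, reference)
        frame = classify(frame)
        frame["visit"] = _assign_visits(frame, config.visit_windows)
        n_flagged = int(frame[[f"{z}_flag" for z in ("haz", "waz", "whz", "bmiz")]].any(axis=1).sum())
        metadata[f"n_rows_{label}"] = n_input
        metadata[f"n_rows_malformed_{label}"] = len({i for i, _ in errors})
        metadata[f"n_rows_flagged_{label}"] = n_flagged
        cohorts[label] = frame

    prev_rows, quintile_rows, ineq_rows = [], [], []
    results = {}  # (visit, indicator, label) -> dict of estimates
    for visit in config.visits:
        for indicator in config.indicators:
            for label in labels:
                frame = cohorts[label]
                sub = frame[frame["visit"] == visit]
                cell, y, w = _cell(sub, indicator, config.weighted)
                if len(cell) == 0:
                    prev_rows.append({"cohort": label, "visit": visit,
                                      "indicator": indicator, "n": 0,
                                      "prevalence": np.nan, "ci_low": np.nan,
                                      "ci_high": np.nan, "available": False})
                    continue
                est = prevalence(y, w)
                prev_rows.append({"cohort": label, "visit": visit,
                                  "indicator": indicator, "n": len(cell),
                                  "prevalence": 100 * est.prevalence,
                                  "ci_low": 100 * est.ci_low,
                                  "ci_high": 100 * est.ci_high, "available": True})
                res = {"prevalence": est.prevalence, "y": y, "w": w, "n": len(cell)}
                # inequality indices need income: restrict to income-present rows
                has_income = cell["income"].notna().to_numpy()
                cell, y, w = cell[has_income], y[has_income], w[has_income]
                try:
                    groups = assign_quantiles(
                        cell["income"].to_numpy(float), config.k_groups,
                        weights=w if config.weighted else None,
                        nominal=config.use_nominal_ranks)
                except ValueError as exc:
                    logger.warning("quantiles unavailable for %s/%s/%s: %s",
                                   label, visit, indicator, exc)
                    results[(visit, indicator, label)] = res
                    continue
                gp = []
                for i, rank in enumerate(groups.midpoint_ranks, start=1):
                    in_g = groups.group_index == i
                    p_g = float(np.sum(w[in_g] * y[in_g]) / np.sum(w[in_g]))
                    gp.append(p_g)
                    quintile_rows.append({"cohort": label, "visit": visit,
                                          "indicator": indicator, "group": i,
                                          "share": groups.shares[i - 1],
                                          "midpoint_rank": rank,
                                          "prevalence": 100 * p_g,
                                          "n_eff": float(np.sum(w[in_g]))})
                sizes = np.array([np.sum(w[groups.group_index == i + 1])
                                  for i in range(groups.n_groups)])
                if config.sii_method == "grouped":
                    sii = sii_grouped(gp, groups.midpoint_ranks, group_sizes=sizes,
                                      weighted=config.weighted)
                else:
                    sii = sii_individual(y, groups.rank_per_subject,
                                         weights=w if config.weighted else None)
                res["sii"] = sii
                try:
                    rii = rii_logistic(y, groups.rank_per_subject,
                                       weights=w if config.weighted else None)
                    res["rii"] = rii
                except (ValueError, ConvergenceError) as exc:
                    logger.warning("RII unavailable for %s/%s/%s: %s",
                                   label, visit, indicator, exc)
                    rii = None
                for r in (sii, rii):
                    if r is None:
                        continue
                    ineq_rows.append({"cohort": label, "visit": visit,
                                      "indicator": indicator, "index_kind": r.kind,
                                      "estimate": r.estimate, "se": r.std_error,
                                      "ci_low": r.ci_low, "ci_high": r.ci_high,
                                      "method": r.method, "weighted": r.weighted})
                results[(visit, indicator, label)] = res

    trend_rows, change_rows = [], []
    scores_all = _cohort_scores(labels)
    for visit in config.visits:
        for indicator in config.indicators:
            have = [l for l in labels if (visit, indicator, l) in results]
            if len(have) < 2:
                continue
            cells = [results[(visit, indicator, l)] for l in have]
            table = np.array([[np.sum(c["w"] * c["y"]) for c in cells],
                              [np.sum(c["w"] * (1 - c["y"])) for c in cells]])
            scores = [scores_all[labels.index(l)] for l in have]
            try:
                t = chisq_test(table)
                trend_rows.append({"cohorts": "|".join(map(str, have)), "visit": visit,
                                   "indicator": indicator, "test_kind": t.kind,
                                   "statistic": t.statistic, "df": t.df,
                                   "p_value": t.p_value})
            except ValueError as exc:
                logger.warning("chi-square unavailable for %s/%s: %s", visit, indicator, exc)
            if len(have) >= 3:
                try:
                    t = chisq_linear_trend(table, scores)
                    trend_rows.append({"cohorts": "|".join(map(str, have)), "visit": visit,
                                       "indicator": indicator, "test_kind": t.kind,
                                       "statistic": t.statistic, "df": t.df,
                                       "p_value": t.p_value})
                except ValueError as exc:
                    logger.warning("trend test unavailable for %s/%s: %s", visit, indicator, exc)
            for kind in ("sii", "rii"):
                fitted = [(l, c[kind]) for l, c in zip(have, cells) if kind in c]
                if len(fitted) < 2:
                    continue
                slopes = [r.slope for _, r in fitted]
                ses = [r.std_error for _, r in fitted]
                try:
                    het = heterogeneity_test(slopes, ses)
                    trend_rows.append({"cohorts": "|".join(str(l) for l, _ in fitted),
                                       "visit": visit, "indicator": indicator,
                                       "test_kind": f"heterogeneity_{kind}",
                                       "statistic": het.statistic, "df": het.df,
                                       "p_value": het.p_value})
                    if len(fitted) >= 3:
                        sc = [scores_all[labels.index(l)] for l, _ in fitted]
                        mt = meta_trend_test(slopes, ses, sc)
                        trend_rows.append({"cohorts": "|".join(str(l) for l, _ in fitted),
                                           "visit": visit, "indicator": indicator,
                                           "test_kind": f"meta_trend_{kind}",
                                           "statistic": mt.statistic, "df": mt.df,
                                           "p_value": mt.p_value})
                except ValueError as exc:
                    logger.warning("heterogeneity unavailable for %s/%s/%s: %s",
                                   visit, indicator, kind, exc)
            # percent change between first and last available cohort
            p0, p1 = cells[0]["prevalence"], cells[-1]["prevalence"]
            if p0 > 0:
                change_rows.append({"visit": visit, "indicator": indicator,
                                    "cohort_from": have[0], "cohort_to": have[-1],
                                    "p_from": 100 * p0, "p_to": 100 * p1,
                                    "percent_change": percent_change(p0, p1)})

    report = AnalysisReport(
        prevalence_table=pd.DataFrame(prev_rows),
        quintile_table=pd.DataFrame(quintile_rows),
        inequality_table=pd.DataFrame(ineq_rows),
        trend_table=pd.DataFrame(trend_rows),
        change_table=pd.DataFrame(change_rows),
        metadata=metadata,
    )
    if config.output_dir:
        report.write(config.output_dir)
    return report


def _cohort_scores(labels):
    """Trend scores: numeric labels (cohort years) or temporal order."""
    try:
        scores = [float(l) for l in labels]
        if len(set(scores)) == len(scores):
            return scores
    except (TypeError, ValueError):
        pass
    return list(range(len(labels)))


def render_report(report: AnalysisReport) -> str:
    """Plain-text presentation tables: prevalence to 1 decimal, SII to 1,
    RII to 2; unavailable cells shown as ``(-)``."""
    buf = io.StringIO()
    prev = report.prevalence_table
    buf.write("Prevalence (%) by cohort and visit\n")
    for indicator in prev["indicator"].unique():
        buf.write(f"\n[{indicator}]\n")
        sub = prev[prev["indicator"] == indicator]
        piv = sub.pivot(index="visit", columns="cohort", values="prevalence")
        for visit, row in piv.iterrows():
            cells = "  ".join(
                "(-)" if pd.isna(v) else f"{v:.1f}" for v in row.to_numpy()
            )
            buf.write(f"  {visit:>6}: {cells}\n")
    buf.write("\nInequality indices\n")
    for _, row in report.inequality_table.iterrows():
        digits = 1 if row["index_kind"] == "SII" else 2
        if pd.isna(row["ci_low"]):
            ci = "(CI unavailable)"
        else:
            ci = f"({row['ci_low']:.{digits}f}; {row['ci_high']:.{digits}f})"
        buf.write(
            f"  {row['cohort']} {row['visit']} {row['indicator']} "
            f"{row['index_kind']}: {row['estimate']:.{digits}f} {ci}\n"
        )
    buf.write("\nTests\n")
    for _, row in report.trend_table.iterrows():
        p = "<0.001" if row["p_value"] < 0.001 else f"{row['p_value']:.3f}"
        buf.write(
            f"  {row['visit']} {row['indicator']} {row['test_kind']}: "
            f"stat={row['statistic']:.2f} df={int(row['df'])} p={p}\n"
        )
    return buf.getvalue()
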