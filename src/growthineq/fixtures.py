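"""Bundled, checksummed fixtures: a synthetic LMS reference grid, a small
synthetic cohort, and published summary tables transcribed as machine-readable
CSVs.

The published tables come from the 1982/1993/2004 Pelotas (Brazil) birth-cohort
comparisons of child nutritional status: overall prevalence by cohort and visit,
and stunting/overweight prevalence by family-income quintile with the printed
SII and RII values.  Each row carries a ``provenance`` column naming the table
and row it was transcribed from; minus signs are normalised to ASCII.

The growth reference bundled here is synthetic (smooth, plausible L/M/S curves)
— real growth-standard tables in the same CSV schema are a drop-in replacement.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources

import numpy as np
import pandas as pd

from .anthropometry import GrowthReference
from .exceptions import ChecksumError, UnknownFixtureError

__all__ = [
    "load_fixture",
    "load_reference",
    "load_toy_cohort",
    "quintile_prevalences",
    "printed_index",
    "FIXTURES",
]

#: registered fixture name -> file name under growthineq/data
FIXTURES = {
    "growth_reference_synthetic": "growth_reference_synthetic.csv",
    "toy_cohort_synthetic": "toy_cohort_synthetic.csv",
    "prevalence_by_cohort": "prevalence_by_cohort.csv",
    "stunting_by_income_quintile": "stunting_by_income_quintile.csv",
    "overweight_by_income_quintile": "overweight_by_income_quintile.csv",
}

_QUINTILE_COLS = ["q1", "q2", "q3", "q4", "q5"]


def _data_dir():
    return resources.files("growthineq") / "data"


def _manifest() -> dict:
    with (_data_dir() / "manifest.json").open() as fh:
        return {entry["name"]: entry for entry in json.load(fh)}


def load_fixture(name: str) -> pd.DataFrame:
    """Load a registered fixture CSV, verifying its sha256 checksum."""
    if name not in FIXTURES:
        raise UnknownFixtureError(
            f"unknown fixture {name!r}; registered: {sorted(FIXTURES)}"
        )
    path = _data_dir() / FIXTURES[name]
    raw = path.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    expected = _manifest()[name]["sha256"]
    if digest != expected:
        raise ChecksumError(
            f"fixture {name!r} is corrupted: sha256 {digest} != manifest {expected}"
        )
    import io

    return pd.read_csv(io.BytesIO(raw))


def load_reference() -> GrowthReference:
    """The bundled synthetic growth reference as a :class:`GrowthReference`."""
    return GrowthReference(load_fixture("growth_reference_synthetic"))


def load_toy_cohort() -> pd.DataFrame:
    """A 200-row hand-checkable synthetic cohort (50 children x 4 visits)."""
    return load_fixture("toy_cohort_synthetic")


def quintile_prevalences(table: pd.DataFrame, cohort, visit: str) -> np.ndarray:
    """Poorest-to-richest quintile prevalences (percent) for one cohort/visit row."""
    row = table[(table["cohort"] == cohort) & (table["visit"] == visit)]
    if len(row) != 1:
        raise KeyError(f"no unique row for cohort={cohort} visit={visit}")
    return row[_QUINTILE_COLS].to_numpy(float).ravel()


def printed_index(table: pd.DataFrame, cohort, visit: str, kind: str):
    """Printed (estimate, ci_low, ci_high) for SII or RII in one row."""
    kind = kind.lower()
    if kind not in ("sii", "rii"):
        raise ValueError("kind must be 'SII' or 'RII'")
    row = table[(table["cohort"] == cohort) & (table["visit"] == visit)]
    if len(row) != 1:
        raise KeyError(f"no unique row for cohort={cohort} visit={visit}")
    cols = [kind, f"{kind}_lo", f"{kind}_hi"]
    return tuple(float(row[c].iloc[0]) for c in cols)
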