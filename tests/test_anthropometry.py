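"""LMS transform, reference interpolation, z-score computation, classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from growthineq.anthropometry import (
    DEFAULT_PLAUSIBILITY,
    classify,
    compute_indicators,
    inverse_lms,
    lms_zscore,
)
from growthineq.exceptions import ReferenceRangeError


@pytest.mark.parametrize(
    "x, L, M, S, expected",
    [
        (10.0, 0.7, 10.0, 0.05, 0.0),  # x at the median maps to zero
        (10.0, 0.0, 10.0, 0.05, 0.0),
        (11.0, 1.0, 10.0, 0.1, 1.0),
        (10.0 * np.exp(0.1), 0.0, 10.0, 0.1, 1.0),  # log branch
    ],
)
def test_lms_zscore_known_values(x, L, M, S, expected):
    assert lms_zscore(x, L, M, S) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "z, L, M, S, expected",
    [(0.0, 0.5, 7.3, 0.2, 7.3), (1.0, 1.0, 10.0, 0.1, 11.0)],
)
def test_inverse_lms_known_values(z, L, M, S, expected):
    assert inverse_lms(z, L, M, S) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("bad", [0.0, -1.0])
def test_nonpositive_inputs_rejected(bad):
    with pytest.raises(ValueError):
        lms_zscore(bad, 1.0, 10.0, 0.1)
    with pytest.raises(ValueError):
        lms_zscore(1.0, 1.0, bad, 0.1)
    with pytest.raises(ValueError):
        inverse_lms(0.0, 1.0, 10.0, bad)


def test_inverse_lms_out_of_domain():
    # 1 + L*S*z <= 0 has no corresponding measurement
    with pytest.raises(ValueError):
        inverse_lms(-15.0, 1.0, 10.0, 0.1)


@settings(derandomize=True, max_examples=300)
@given(
    z=st.floats(-4.5, 4.5),
    L=st.floats(-2.0, 2.0),
    M=st.floats(0.5, 120.0),
    S=st.floats(0.01, 0.25),
)
def test_lms_round_trip(z, L, M, S):
    """inverse then forward recovers the z-score to well below 1e-9."""
    if abs(L) > 1e-12 and 1.0 + L * S * z < 1e-3:
        return
    x = inverse_lms(z, L, M, S)
    assert abs(lms_zscore(x, L, M, S) - z) < 1e-9


def test_continuity_at_L_zero():
    xs = np.array([4.0, 9.0, 10.0, 11.0, 25.0])
    for M in (5.0, 10.0, 20.0):
        for S in (0.05, 0.1, 0.2):
            z_small = lms_zscore(xs, 1e-8, M, S)
            z_zero = lms_zscore(xs, 0.0, M, S)
            assert np.all(np.abs(z_small - z_zero) < 1e-6)


@settings(derandomize=True, max_examples=200)
@given(
    x=st.floats(1.0, 50.0),
    dx=st.floats(0.01, 5.0),
    L=st.floats(-2.0, 2.0),
    S=st.floats(0.01, 0.25),
)
def test_lms_strictly_increasing_in_x(x, dx, L, S):
    assert lms_zscore(x + dx, L, 10.0, S) > lms_zscore(x, L, 10.0, S)


class TestReferenceLookup:
    def test_exact_at_grid_points(self, reference):
        row = reference.table.iloc[7]
        L, M, S = reference.lookup(row["indicator"], row["sex"], row["index_value"])
        assert (L, M, S) == (row["L"], row["M"], row["S"])

    def test_midpoint_interpolation(self, tiny_reference):
        L, M, S = tiny_reference.lookup("weight_for_age", "male", 50.0)
        assert M == pytest.approx(9.5, abs=1e-12)
        assert L == pytest.approx(1.0) and S == pytest.approx(0.1)

    def test_interpolation_matches_linear_oracle(self):
        # fine synthetic grid whose M is an exact line: interpolation must
        # reproduce the closed form everywhere
        from growthineq.anthropometry import GrowthReference

        grid = np.linspace(0.0, 100.0, 41)
        table = pd.DataFrame(
            {
                "indicator": "weight_for_age",
                "sex": "male",
                "index_value": grid,
                "L": 0.5,
                "M": 3.0 + 0.12 * grid,
                "S": 0.1,
            }
        )
        ref = GrowthReference(table)
        queries = np.linspace(0.0, 100.0, 997)
        _, M, _ = ref.lookup("weight_for_age", ["male"] * len(queries), queries)
        assert np.max(np.abs(M - (3.0 + 0.12 * queries))) < 1e-12

    def test_out_of_range_raises(self, reference):
        with pytest.raises(ReferenceRangeError):
            reference.lookup("length_height_for_age", "male", 1e6)

    def test_out_of_range_nan_mode(self, reference):
        L, M, S = reference.lookup(
            "length_height_for_age", "male", 1e6, out_of_range="nan"
        )
        assert np.isnan(M)


def _record(reference, haz, bmiz, age_days=365.0, sex="male"):
    L, M, S = reference.lookup("length_height_for_age", sex, age_days)
    length = inverse_lms(haz, L, M, S)
    L, M, S = reference.lookup("bmi_for_age", sex, age_days)
    bmi = inverse_lms(bmiz, L, M, S)
    return {
        "sex": sex,
        "age_days": age_days,
        "length_cm": length,
        "weight_kg": bmi * (length / 100.0) ** 2,
    }


class TestComputeIndicators:
    def test_round_trip_of_constructed_record(self, reference):
        frame = pd.DataFrame([_record(reference, haz=-2.5, bmiz=0.3)])
        out = compute_indicators(frame, reference)
        assert out["haz"].iloc[0] == pytest.approx(-2.5, abs=1e-9)
        assert out["bmiz"].iloc[0] == pytest.approx(0.3, abs=1e-9)
        assert not out[["haz_flag", "bmiz_flag"]].any().any()

    def test_implausible_haz_flagged(self, reference):
        frame = pd.DataFrame([_record(reference, haz=-7.0, bmiz=0.0)])
        out = compute_indicators(frame, reference)
        assert out["haz"].iloc[0] == pytest.approx(-7.0, abs=1e-9)
        assert bool(out["haz_flag"].iloc[0])

    def test_missing_weight_leaves_other_scores(self, reference):
        rec = _record(reference, haz=-1.0, bmiz=0.0)
        rec["weight_kg"] = np.nan
        out = compute_indicators(pd.DataFrame([rec]), reference)
        assert out["haz"].iloc[0] == pytest.approx(-1.0, abs=1e-9)
        assert out[["waz", "whz", "bmiz"]].isna().all().all()

    def test_plausibility_limits_configurable(self, reference):
        frame = pd.DataFrame([_record(reference, haz=-4.5, bmiz=0.0)])
        out = compute_indicators(frame, reference, plausibility={"haz": (-4.0, 4.0)})
        assert bool(out["haz_flag"].iloc[0])
        assert DEFAULT_PLAUSIBILITY["haz"] == (-6.0, 6.0)


def _zframe(haz=0.0, waz=0.0, whz=0.0, bmiz=0.0, flags=()):
    row = {"haz": haz, "waz": waz, "whz": whz, "bmiz": bmiz}
    row.update({f"{z}_flag": z in flags for z in ("haz", "waz", "whz", "bmiz")})
    return pd.DataFrame([row])


class TestClassify:
    def test_boundary_is_strict(self):
        # exactly -2 is not stunted ("below -2" read strictly)
        assert classify(_zframe(haz=-2.0))["stunted"].iloc[0] == False  # noqa: E712
        assert classify(_zframe(haz=-2.0000001))["stunted"].iloc[0] == True  # noqa: E712

    def test_overweight_above_two(self):
        assert classify(_zframe(bmiz=2.5))["overweight"].iloc[0] == True  # noqa: E712
        assert classify(_zframe(bmiz=2.0))["overweight"].iloc[0] == False  # noqa: E712

    def test_all_zero_scores_all_negative(self):
        out = classify(_zframe())
        assert not out[["stunted", "underweight", "wasted", "overweight"]].any().any()

    def test_flagged_scores_give_missing_status(self):
        out = classify(_zframe(haz=-7.0, flags=("haz",)))
        assert out["stunted"].isna().iloc[0]
        assert out["underweight"].iloc[0] == False  # noqa: E712

    def test_classification_monotone_in_haz(self, reference):
        grid = np.linspace(-5.5, 1.0, 40)
        frames = pd.DataFrame([_record(reference, haz=h, bmiz=0.0) for h in grid])
        out = classify(compute_indicators(frames, reference))
        stunted = out["stunted"].to_numpy(dtype=bool)
        # once not stunted while haz increases, never stunted again
        assert np.all(np.diff(stunted.astype(int)) <= 0)
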