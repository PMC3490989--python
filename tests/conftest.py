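import numpy as np
import pytest

from growthineq.fixtures import load_reference


@pytest.fixture(scope="session")
def reference():
    return load_reference()


@pytest.fixture(scope="session")
def tiny_reference():
    """Hand-written two-row-per-indicator reference for interpolation checks."""
    import pandas as pd

    from growthineq.anthropometry import GrowthReference

    rows = []
    for indicator in (
        "length_height_for_age",
        "weight_for_age",
        "weight_for_length_height",
        "bmi_for_age",
    ):
        for sex in ("male", "female"):
            rows.append((indicator, sex, 0.0, 1.0, 9.0, 0.1))
            rows.append((indicator, sex, 100.0, 1.0, 10.0, 0.1))
    return GrowthReference(
        pd.DataFrame(rows, columns=["indicator", "sex", "index_value", "L", "M", "S"])
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)
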