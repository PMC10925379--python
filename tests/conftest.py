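import numpy as np
import pandas as pd
import pytest

from crtcascade import FeatureSchema, FeatureTable, SyntheticCohortSpec, generate
from crtcascade.tabular_io import FeatureDef


@pytest.fixture
def toy_schema():
    return FeatureSchema(
        features={
            "age": FeatureDef("continuous", 1),
            "qrsd": FeatureDef("continuous", 1),
            "psd": FeatureDef("continuous", 2),
            "scar": FeatureDef("continuous", 2),
        },
        outcome_name="response",
    )


@pytest.fixture
def toy_csv(tmp_path, toy_schema):
    df = pd.DataFrame({
        "age": [60.0, 55.0, 70.0, 65.0],
        "qrsd": [150.0, 160.0, 140.0, 155.0],
        "psd": [40.0, 55.0, 60.0, 45.0],
        "scar": [10.0, 30.0, 20.0, 15.0],
        "response": [0, 1, 0, 1],
    })
    path = tmp_path / "toy.csv"
    df.to_csv(path, index=False)
    return path


@pytest.fixture
def toy_table():
    rng = np.random.default_rng(42)
    n = 60
    X = pd.DataFrame({
        "a": rng.standard_normal(n),
        "b": rng.standard_normal(n),
        "c": rng.standard_normal(n),
        "d": rng.standard_normal(n),
    })
    y = (X["a"] + 0.5 * X["b"] + 0.3 * rng.standard_normal(n) > 0).astype(int)
    return FeatureTable(X=X, y=pd.Series(y, name="response"),
                        stage_of={"a": 1, "b": 1, "c": 2, "d": 2})


@pytest.fixture(scope="session")
def small_cohort():
    """n=218 CRT-like cohort with the default ambiguous subgroup."""
    return generate(SyntheticCohortSpec(n=218, seed=7))


@pytest.fixture(scope="session")
def medium_cohort():
    return generate(SyntheticCohortSpec(n=500, seed=11))
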