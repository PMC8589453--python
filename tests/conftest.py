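import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import bioage as ba

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def kdm_panel() -> list[str]:
    return [s.name for s in ba.kdm8_specs()]


@pytest.fixture(scope="session")
def control_cohort() -> pd.DataFrame:
    """A mid-sized control cohort under the default generative laws."""
    return ba.generate_controls(ba.GenerativeConfig(n_subjects=2000, seed=11))


@pytest.fixture(scope="session")
def trained_models(control_cohort, kdm_panel):
    """(train, test, kdm model, mlr model) on raw (untransformed) markers."""
    train, test = ba.train_test_split(control_cohort, 2 / 3, seed=5)
    kdm = ba.fit_kdm(train, kdm_panel)
    mlr = ba.fit_mlr(train, kdm_panel)
    return train, test, kdm, mlr


def make_cohort(values: dict, ca=None, gender=None, group="control") -> pd.DataFrame:
    """Small helper building a cohort frame from column -> list mappings."""
    n = len(next(iter(values.values()))) if values else len(ca)
    df = pd.DataFrame(values)
    df.insert(0, "subject_id", [f"s{i}" for i in range(n)])
    df.insert(1, "ca", ca if ca is not None else np.full(n, 50.0))
    df.insert(2, "gender", gender if gender is not None else ["female"] * n)
    df.insert(3, "group", group)
    return df
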