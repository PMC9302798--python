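import numpy as np
import pandas as pd
import pytest

from liferisk.classify import apply_exclusions, resolve_state_histories
from liferisk.registry import GeneratorConfig, generate_registry


@pytest.fixture(scope="session")
def dense_config():
    """Dense-observation study conditions: one measurement every integer age
    under observation, no contaminating records. Isolates estimator sampling
    error from onset-detection delay."""
    return GeneratorConfig(
        n_persons=100_000,
        seed=11,
        dense_testing=True,
        gestational_fraction=0.0,
        inpatient_fraction=0.0,
        measurement_type_mix={"FPG": 0.7, "HbA1c": 0.29, "OGTT2h": 0.01},
    )


@pytest.fixture(scope="session")
def dense_registry(dense_config):
    return generate_registry(dense_config)


@pytest.fixture(scope="session")
def dense_histories(dense_config, dense_registry):
    return resolve_state_histories(
        apply_exclusions(dense_registry),
        linkage_end_year=dense_config.period_range[1],
    )


@pytest.fixture(scope="session")
def default_config():
    """Default opportunistic-testing study conditions."""
    return GeneratorConfig(n_persons=50_000, seed=3)


@pytest.fixture(scope="session")
def default_registry(default_config):
    return generate_registry(default_config)


def make_histories(rows: list[dict]) -> pd.DataFrame:
    """Hand-built resolved histories with sensible defaults."""
    defaults = {
        "sex": "F", "birth_year": 1950, "entry_age": 0.0,
        "pre_onset_age": np.nan, "dm_onset_age": np.nan, "death_age": np.nan,
        "censor_age": 110.0, "linkage_end_age": 111.0, "n_measurements": 1,
    }
    out = []
    for i, row in enumerate(rows):
        rec = {"person_id": i, **defaults, **row}
        rec["followup_years"] = rec["censor_age"] - rec["entry_age"]
        out.append(rec)
    return pd.DataFrame(out)
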