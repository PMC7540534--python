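import dataclasses

import numpy as np
import pandas as pd
import pytest

import lrtrial as lt
from lrtrial.trial_data import FeatureKind, FeatureSchema, FeatureSpec


@pytest.fixture(scope="session")
def tiny_schema() -> FeatureSchema:
    return FeatureSchema(features=(
        FeatureSpec("x1", FeatureKind.CONTINUOUS),
        FeatureSpec("x2", FeatureKind.ORDINAL, lo=0, hi=4),
        FeatureSpec("x3", FeatureKind.BINARY),
        FeatureSpec("color", FeatureKind.CATEGORICAL,
                    levels=("red", "green", "blue")),
    ))


@pytest.fixture
def tiny_dataset(tiny_schema) -> lt.TrialDataset:
    df = pd.DataFrame({
        "subject_id": ["a", "b", "c", "d"],
        "arm": ["ACTIVE", "PLACEBO", "ACTIVE", "PLACEBO"],
        "baseline_hdd": [20, 25, 4, 28],
        "outcome_hdd": [5, 20, 0, 28],
        "x1": [1.5, -0.25, 3.0, np.nan],
        "x2": [0, 4, 2, 1],
        "x3": [1, 0, 0, 1],
        "color": ["red", "green", "blue", "red"],
    })
    return lt.TrialDataset(df, tiny_schema)


@pytest.fixture(scope="session")
def default_sim():
    """One moderately sized default simulation shared across tests."""
    ds, oracle = lt.simulate_trial(lt.default_config(n_subjects=338, seed=11))
    return ds, oracle


@pytest.fixture(scope="session")
def clean_sim():
    """Fully observed simulation (no missingness) for model tests."""
    cfg = lt.default_config(n_subjects=500, seed=5,
                            missing_rate_items=0.0,
                            missing_rate_outcome=0.0)
    ds, oracle = lt.simulate_trial(cfg)
    return ds.derive_outcomes(), oracle


@pytest.fixture(scope="session")
def fitted_model(clean_sim):
    ds, _ = clean_sim
    return lt.fit_treated_model(ds, lt.ForestConfig(n_trees=200, seed=3))


def single_feature_config(n: int, seed: int, noise_sd: float = 0.0,
                          slope: float = 2.0) -> lt.SimulationConfig:
    """Outcome driven by a single ordinal item: h = slope * x, g = 0."""
    from lrtrial.synthetic_trial import EffectSpec, FeatureBlock
    return lt.SimulationConfig(
        n_subjects=n, seed=seed, noise_sd=noise_sd,
        feature_blocks=(FeatureBlock("x", 1, 0, 8, 0.0),),
        prognosis=EffectSpec(kind="linear", intercept=6.0,
                             coefficients={"x_q01": slope},
                             centers={"x_q01": 4.0}),
        effect=EffectSpec("zero"),
    )
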