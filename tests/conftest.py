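import dataclasses

import numpy as np
import pandas as pd
import pytest

from brainsex import GenerativeConfig, TrainingParams, generate_cohort
from brainsex import tables as T


def fast_params(**kw) -> TrainingParams:
    """Boosting settings small enough for test budgets."""
    base = dict(learning_rate=0.1, initial_rounds=30, outer_folds=5, inner_folds=3,
                max_depth=2, max_features="sqrt", seed=0)
    base.update(kw)
    return TrainingParams(**base)


def small_config(**kw) -> GenerativeConfig:
    base = dict(n_subjects=120, n_features_limbic=8, n_features_nonlimbic=12,
                n_sites=3, seed=0)
    base.update(kw)
    return GenerativeConfig(**base)


def null_config(**kw) -> GenerativeConfig:
    """Every injected effect zero: features are eTIV scaling plus noise."""
    base = dict(
        sex_effect_sd_units={"limbic": 0.0, "nonlimbic": 0.0},
        age_slope_sd_units_per_year={"F": 0.0, "M": 0.0},
        puberty_effect_sd_units={"limbic": 0.0, "nonlimbic": 0.0},
        site_shift_sd_units=0.0,
        site_scale_range=(1.0, 1.0),
        distress_limbic_coupling=0.0,
    )
    base.update(kw)
    return small_config(**base)


@pytest.fixture(scope="session")
def demo_cohort():
    cfg = small_config(n_subjects=200, seed=11)
    cohort, truth = generate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture()
def toy_cross_sectional():
    """Deterministic one-row-per-subject table for matching tests."""
    rng = np.random.default_rng(7)
    n = 40
    return pd.DataFrame({
        T.SUBJECT: [f"S{i:03d}" for i in range(n)],
        T.SESSION: T.BASELINE,
        T.SEX: ["F", "M"] * (n // 2),
        T.AGE: rng.uniform(120, 200, n),
        T.ETIV: rng.normal(1.5e6, 5e4, n),
        T.EULER: rng.normal(-50, 10, n).round(),
        T.SITE: "site01",
    })
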