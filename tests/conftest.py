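import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from momscreen import AnalyteSpec, GeneratorConfig, MapSpec, generate_cohort

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


def small_panel():
    """Four analytes: two with study effect sizes, one heavily censored, one null."""
    return (
        AnalyteSpec("taurine", "amine", median_intercept=120.0,
                    median_slope=-0.001, momr_eo=0.79),
        AnalyteSpec("glycylglycine", "amine", median_intercept=8.0, momr_lo=0.72),
        AnalyteSpec("oxylipin_cens", "oxylipin", median_intercept=2.0,
                    log10_mom_sd=0.15, lod_quantile=0.25),
        AnalyteSpec("amine_null", "amine", median_intercept=50.0,
                    median_slope=0.001),
    )


@pytest.fixture
def small_config():
    return GeneratorConfig(n_controls=120, n_eo=20, n_lo=25,
                           analytes=small_panel(), seed=7)


@pytest.fixture
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture
def study_config():
    """Study-scale design (500/68/99) over the small panel, for fast pipeline runs."""
    return GeneratorConfig(n_controls=500, n_eo=68, n_lo=99,
                           analytes=small_panel(), seed=11)


def toy_subjects(n=6, seed=0):
    """Minimal valid subject table for unit tests that only need covariates."""
    rng = np.random.default_rng(seed)
    ga = rng.integers(56, 98, n)
    return pd.DataFrame({
        "subject_id": [f"T{i:03d}" for i in range(n)],
        "group": ["control"] * n,
        "ga_sampling_days": ga,
        "weight_kg": rng.normal(65, 8, n).clip(45),
        "smoking": rng.random(n) < 0.3,
        "nulliparous": rng.random(n) < 0.5,
        "history_htn": rng.random(n) < 0.1,
        "ethnicity": rng.choice(["european", "other"], n),
        "sbp_mmHg": np.full(n, 120.0),
        "dbp_mmHg": np.full(n, 80.0),
        "ga_delivery_weeks": np.full(n, 40.0),
        "birthweight_centile": rng.uniform(0, 100, n),
    })
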