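"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cohortsom import cohort as coh
from cohortsom import synthetic as syn


@pytest.fixture(scope="session")
def default_config() -> syn.GeneratorConfig:
    return syn.GeneratorConfig(n_participants=2000, seed=1)


@pytest.fixture(scope="session")
def small_synthetic() -> syn.SyntheticCohort:
    """A fully simulated cohort (baseline + incidence + loss), n=800."""
    return syn.generate_full(syn.GeneratorConfig(n_participants=800, seed=7))


@pytest.fixture(scope="session")
def small_cohort(small_synthetic) -> pd.DataFrame:
    return coh.derive_clinical_flags(small_synthetic.cohort)


def make_participants(n: int = 1, **overrides) -> pd.DataFrame:
    """A minimal schema-complete cohort table with constant defaults."""
    base = {
        "id": [f"T{i:04d}" for i in range(n)],
        "sex": "female",
        "age": 40.0,
        "region": "north",
        "urban": 0,
        "height": 160.0,
        "weight": 55.0,
        "waist": 75.0,
        "sbp": 115.0,
        "dbp": 75.0,
        "glucose": 5.0,
        "triglycerides": 100.0,
        "hdl": 55.0,
        "total_cholesterol": 150.0,
        "hemoglobin": 135.0,
        "ferritin": 90.0,
        "education": "medium",
        "occupation": "manual",
        "smoking": "none",
        "income_level": "medium",
        "on_antihypertensives": 0,
        "anemia_baseline": 0,
    }
    for col in coh.INTAKE_COLUMNS:
        base[col] = 10.0
    base.update(overrides)
    return pd.DataFrame(base)
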