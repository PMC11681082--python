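"""Shared fixtures: cohort configurations used across the suite.

``clean_config`` builds generator configurations whose trajectories stay
strictly inside the HUI utility range (ages capped, modest noise), so that
linear-model estimands coincide with the generator's coefficients — the
right regime for checking the fitting machinery itself.  The package
defaults, in contrast, emulate the ceiling-censored distribution of real
HUI data and are exercised by the calibration tests.
"""

import numpy as np
import pytest

import huitraj as ht

#: cubic age profile used as generator truth in machinery checks
AGE_PROFILE = {"age": -2.26e-2, "age^2": 5.48e-4, "age^3": -4.41e-6}
NO2_PROFILE = {"no2": -3.44e-3, "no2:age": 1.70e-4, "no2:age^2": -1.88e-6}

NO_ATTRITION = {"survival": {"Intercept": 30.0}, "response": {"Intercept": 30.0}}


def _clean_config(seed, n=800, no2=True, attrition="default", intercept=0.8,
                  residual_sd=0.09, **kwargs):
    cfg = ht.CohortConfig(
        n_participants=n, seed=seed,
        age_mean=42.0, age_sd=11.0, age_min=20.0, age_max=60.0,
        random_effect_sd={"intercept": 0.12, "age_slope": 0.002},
        residual_sd=residual_sd, **kwargs)
    fe = {"Intercept": intercept} | dict(AGE_PROFILE)
    if no2:
        fe |= dict(NO2_PROFILE)
    cfg.true_fixed_effects = fe
    if attrition == "none":
        cfg.attrition_coefficients = {k: dict(v) for k, v in NO_ATTRITION.items()}
    return cfg


@pytest.fixture(scope="session")
def clean_config():
    """Factory for in-range generator configurations."""
    return _clean_config


@pytest.fixture(scope="session")
def default_cohort_20k():
    """One large cohort at full package defaults, shared by the
    calibration tests."""
    return ht.generate_cohort(ht.CohortConfig(n_participants=20000, seed=20260927))


@pytest.fixture(scope="session")
def small_clean_cohort():
    """A small in-range cohort with exposure effects, for fast fits."""
    return ht.generate_cohort(_clean_config(seed=42, n=500))
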