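"""Shared fixtures: small synthetic datasets with known generating hazards."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dfyears import CohortSpec, HazardSpec, generate_cohort


def weibull_data(n: int, seed: int, gamma0: float = -9.0, gamma1: float = 2.0,
                 followup: float = 15.0) -> pd.DataFrame:
    """Left-truncated Weibull sample: ln H(t) = gamma0 + gamma1 ln t."""
    rng = np.random.default_rng(seed)
    entry = rng.uniform(40.0, 50.0, n)
    e = rng.exponential(size=n)
    h0 = np.exp(gamma0) * entry**gamma1
    t_event = ((h0 + e) * np.exp(-gamma0)) ** (1.0 / gamma1)
    exit_ = np.minimum(t_event, entry + followup)
    event = (t_event <= exit_).astype(int)
    return pd.DataFrame(
        {"entry_age": entry, "exit_age": exit_, "event": event, "cat": "all"}
    )


def two_rate_cohort(n: int, seed: int, a1: float = 0.02, a2: float = 0.01,
                    followup: float = 35.0) -> pd.DataFrame:
    """Two exponential categories A (rate a1) and B (rate a2), long follow-up."""
    spec = CohortSpec(
        name="two",
        n=n,
        sex_split=1.0,
        entry_age_mean=45.0,
        entry_age_sd=3.0,
        admin_followup=followup,
        category_prevalence={"A": 0.5, "B": 0.5},
        disease_hazard={"A": HazardSpec("exponential", a1),
                        "B": HazardSpec("exponential", a2)},
        death_hazard=HazardSpec("exponential", 1e-12),
        female_hazard_ratio=1.0,
    )
    return generate_cohort(spec, seed)


@pytest.fixture(scope="session")
def weibull5000():
    return weibull_data(5000, seed=101)


@pytest.fixture(scope="session")
def gompertz_cohort():
    """Single-category Gompertz cohort resembling one consortium study."""
    spec = CohortSpec(
        name="g",
        n=20000,
        sex_split=1.0,
        entry_age_mean=45.0,
        entry_age_sd=8.0,
        admin_followup=20.0,
        category_prevalence={"only": 1.0},
        disease_hazard={"only": HazardSpec("gompertz", 0.0095, 0.045)},
        death_hazard=HazardSpec("exponential", 1e-12),
        female_hazard_ratio=1.0,
    )
    return generate_cohort(spec, 202), HazardSpec("gompertz", 0.0095, 0.045)
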