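"""Shared fixtures and panel builders for the test suite."""

import numpy as np
import pandas as pd
import pytest

from crpbmd import CohortConfig, generate_cohort


def make_panel(rng, n_women=200, obs_per_stage=2, beta=(0.0, 0.0, 0.0),
               noise_sd=1.0, x_sd=1.0, alpha_sd=1.0):
    """Observation-level panel with woman effects and stage-specific slopes.

    Each woman contributes ``obs_per_stage`` observations in every combined
    MT stage; the outcome responds to the exposure with the stage's slope.
    Used for calibration of the interaction test, where only the error
    structure of the fitted model matters.
    """
    m = 3 * obs_per_stage
    n = n_women * m
    woman = np.repeat(np.arange(n_women), m)
    stage = np.tile(np.repeat([1, 2, 3], obs_per_stage), n_women)
    x = rng.normal(0.0, x_sd, n)
    alpha = np.repeat(rng.normal(0.0, alpha_sd, n_women), m)
    y = alpha + np.asarray(beta)[stage - 1] * x + rng.normal(0.0, noise_sd, n)
    return pd.DataFrame({"woman_id": woman, "stage": stage, "log2_crp": x, "slope": y})


def make_random_small_panel(rng):
    """Random small panel (8-15 women, 3-5 obs each) for oracle-equivalence
    tests; sized so the within model stays identified (n > k + G)."""
    G = int(rng.integers(8, 16))
    sizes = rng.integers(3, 6, G)
    woman = np.repeat(np.arange(G), sizes)
    n = len(woman)
    x = rng.normal(0, 1, n)
    z = rng.normal(0, 1, n)
    stage = rng.integers(1, 4, n)
    y = 0.5 * x - 0.2 * z + np.repeat(rng.normal(0, 1, G), sizes) + rng.normal(0, 1, n)
    return pd.DataFrame(
        {
            "woman_id": woman,
            "log2_crp": x,
            "bmi": z,
            "smoking": rng.integers(0, 2, n),
            "diabetes": 0,
            "alcohol": rng.integers(0, 4, n),
            "stage": stage,
            "slope": y,
        }
    )


@pytest.fixture(scope="session")
def small_cohort():
    """One seeded 300-woman cohort shared by read-only tests."""
    cfg = CohortConfig(n_women=300, seed=20260922)
    return cfg, *generate_cohort(cfg)
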