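"""Shared fixtures: canonical schedules and small synthetic subjects."""

import numpy as np
import pytest
from hypothesis import settings

import painlearn as pl

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")
from painlearn.learning_models import LearningParams


@pytest.fixture(scope="session")
def instructed_schedule():
    return pl.generate_trial_schedule("instructed", 1, seed=0)


@pytest.fixture(scope="session")
def uninstructed_schedule():
    return pl.generate_trial_schedule("uninstructed", 1, seed=0)


@pytest.fixture(scope="session")
def schedule_pool():
    """Four cached schedules covering both groups and both orders."""
    return [
        pl.generate_trial_schedule(group, order, seed=0)
        for group in ("instructed", "uninstructed")
        for order in (1, 2)
    ]


@pytest.fixture(scope="session")
def noise_free_subject(instructed_schedule):
    """Noise-free pain generated from known (alpha, rho, beta0, beta1)."""
    params = LearningParams(model="irw_fixed_init", alpha=0.3, rho=0.7)
    spec = pl.GenerativeSpec(noise_sd=0.0, beta0=1.0, beta_temp=0.0,
                             beta_ev=2.0)
    pain, _ = pl.generate_pain(instructed_schedule, spec, seed=1,
                               params=params)
    return instructed_schedule, pain, params
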