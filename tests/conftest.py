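"""Shared fixtures: default parameters, reference trajectories, synthetic data.

Expensive simulations are session-scoped so the suite runs each of them once.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from surfkin import (
    KineticParameters,
    compute_performance,
    design_config,
    simulate_batch_free,
    simulate_fed_batch,
)
from surfkin.synthetic import NoiseModel, batch_experiment_config, generate_experiment_set

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params() -> KineticParameters:
    return KineticParameters.defaults()


@pytest.fixture(scope="session")
def design_traj_28(params):
    """Batch-free design run at the selected operating point F0 = 28 g/h."""
    return simulate_batch_free(design_config(params, F0=28.0))


@pytest.fixture(scope="session")
def design_perf_28(design_traj_28):
    return compute_performance(design_traj_28)


@pytest.fixture(scope="session")
def hist_traj_025(params):
    """Triggered fed-batch run at feeding growth rate 0.25 1/h."""
    return simulate_fed_batch(batch_experiment_config(params, 0.25))


@pytest.fixture(scope="session")
def noiseless_noise_model() -> NoiseModel:
    return NoiseModel(
        cv={s: 0.0 for s in ("X", "S", "P", "A")}, floor_sd=0.0, detection_limit=0.0
    )


@pytest.fixture(scope="session")
def clean_obs_025(params, noiseless_noise_model):
    """Single noiseless, jitter-free synthetic experiment at 0.25 1/h."""
    return generate_experiment_set(
        params,
        [0.25],
        replicates=1,
        noise=noiseless_noise_model,
        ic_jitter_cv=0.0,
        t_lag_jitter=0.0,
        seed=1,
    )[0]


@pytest.fixture(scope="session")
def clean_obs_pair(params, noiseless_noise_model):
    """Noiseless experiments at 0.25 and 0.4 1/h (the 0.4 run activates the
    acetate inhibition pathway, making K_I and b_max identifiable)."""
    return generate_experiment_set(
        params,
        [0.25, 0.4],
        replicates=1,
        noise=noiseless_noise_model,
        ic_jitter_cv=0.0,
        t_lag_jitter=0.0,
        seed=1,
    )
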