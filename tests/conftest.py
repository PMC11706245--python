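import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from codonpmf import (
    average_trials,
    load_preset,
    probability_from_state,
    run_abf,
)
from codonpmf.system import DynamicsSpec


@pytest.fixture(scope="session")
def smooth_spec():
    """Gentle validation system: bin-center values resolve the landscape."""
    return load_preset("smooth")


@pytest.fixture(scope="session")
def flat_spec():
    return load_preset("flat")


@pytest.fixture(scope="session")
def route_validation_run(smooth_spec):
    """Documented estimator-validation run: smooth system, 5 trials x 4e6
    steps, timestep 2e-3, seeds 300..304.  Returns (P_avg, merged_state).
    """
    merged = None
    p_trials = []
    for t in range(5):
        dyn = DynamicsSpec(n_steps=4_000_000, seed=300 + t, timestep=2e-3)
        run = run_abf(smooth_spec, dyn)
        p_trials.append(probability_from_state(run.state, smooth_spec))
        if merged is None:
            merged = run.state
        else:
            merged.counts += run.state.counts
            merged.force_sum += run.state.force_sum
    return average_trials(p_trials), merged


@pytest.fixture(scope="session")
def aug_checkpoint_run():
    """Documented converged ABF run on the AUG preset with checkpoints."""
    spec = load_preset("AUG")
    dyn = DynamicsSpec(n_steps=4_000_000, seed=1000)
    return spec, run_abf(spec, dyn, checkpoint_fractions=(0.25, 0.5, 0.75, 1.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
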