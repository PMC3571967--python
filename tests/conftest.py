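import numpy as np
import pytest
from hypothesis import settings

from nwstress.preprocess import condition_profiles, log_and_baseline
from nwstress.simulate import SimulationConfig, simulate

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """A 200-entity noisy dataset with planted clusters, interactions and
    trend changes."""
    cfg = SimulationConfig(n_entities=200, noise_sigma=0.25, seed=11)
    return simulate(cfg)


@pytest.fixture(scope="session")
def noiseless_sim():
    """Noise-free dataset: condition values equal the planted truth."""
    cfg = SimulationConfig(
        n_entities=120,
        noise_sigma=0.0,
        frac_interaction=0.0,
        frac_trend_change=0.0,
        seed=7,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def leaf_profiles(small_sim):
    matrix, metadata, _truth = small_sim
    logm = log_and_baseline(matrix)
    return condition_profiles(logm, metadata, "leaf", "optimal")


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
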