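import numpy as np
import pytest
from hypothesis import settings

from abbscore import SimConfig, simulate_cohort
from abbscore.ab_model import default_model

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def clean_model():
    """Default genotype AB model (het 0.5, symmetric hom error classes)."""
    return default_model()


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort shared by aggregation/classifier tests."""
    return simulate_cohort(SimConfig(n_samples=100, n_sites=400, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
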