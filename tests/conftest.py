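import numpy as np
import pytest

from vmrcall.simulate import SimConfig, simulate_blacklist, simulate_methylomes


@pytest.fixture(scope="session")
def default_fixture():
    """Noise-free default synthetic methylome (50k CpGs, 54 samples)."""
    return simulate_methylomes(SimConfig(seed=0))


@pytest.fixture(scope="session")
def noisy_fixture():
    """Default fixture with truncated Gaussian noise, SD 5 percent."""
    return simulate_methylomes(SimConfig(noise_sd=5.0, seed=1))


@pytest.fixture(scope="session")
def small_fixture():
    """A smaller noise-free fixture for cheaper tests (8k CpGs)."""
    return simulate_methylomes(SimConfig(n_cpgs=8000, seed=11))


@pytest.fixture(scope="session")
def default_blacklist(default_fixture):
    matrix, truth = default_fixture
    return simulate_blacklist(truth, seed=3, sites=matrix.sites)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
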