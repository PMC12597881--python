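import numpy as np
import pytest

from qtraitsem import QTraitConfig, preset, simulate_covstruct


def population_covstruct(name: str, seed: int = 7):
    """A near-noiseless draw: S is Sigma_true up to ~1e-14 perturbation."""
    sc = preset(name)
    sc.se_scale = 1e-8
    sc.seed = seed
    return sc, simulate_covstruct(sc)


@pytest.fixture(scope="session")
def null_population():
    return population_covstruct("null_k5")


@pytest.fixture(scope="session")
def ad_population():
    return population_covstruct("ad_like")


@pytest.fixture(scope="session")
def g_population():
    return population_covstruct("g_like")


@pytest.fixture(scope="session")
def noisy_null():
    sc = preset("null_k5")
    sc.seed = 11
    return sc, simulate_covstruct(sc)


@pytest.fixture(scope="session")
def weak_signal():
    """Common-pathway truth with a marginal correlate-factor effect."""
    sc = preset("null_k5")
    sc.b_true = 0.07
    sc.seed = 21
    return sc, simulate_covstruct(sc)


@pytest.fixture
def config():
    return QTraitConfig(seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
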