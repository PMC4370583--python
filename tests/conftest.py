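import numpy as np
import pytest

from floquetbias import NoiseSpec, generate_ar1


@pytest.fixture(scope="session")
def unit_normal() -> NoiseSpec:
    return NoiseSpec("normal", 1.0)


@pytest.fixture(scope="session")
def noiseless() -> NoiseSpec:
    return NoiseSpec("normal", 0.0)


@pytest.fixture()
def random_series():
    """Factory for seeded stochastic AR(1) series."""

    def make(lam=0.75, n=100, seed=42, family="normal", sigma=1.0):
        return generate_ar1(lam, n, NoiseSpec(family, sigma), seed)

    return make


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
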