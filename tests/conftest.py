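import numpy as np
import pytest

from diffusefit import (
    NoiseModel,
    OpticalProperties,
    SensorGeometry,
    make_grid,
    simulate_profile,
)

MILK_ETA = 1.347


@pytest.fixture(scope="session")
def default_grid():
    return make_grid(SensorGeometry())


@pytest.fixture(scope="session")
def noiseless():
    """Factory: exact model profile on the default detector grid."""

    def _make(mu_a, mu_s_prime, eta=MILK_ETA, channel="R"):
        props = OpticalProperties(mu_a=mu_a, mu_s_prime=mu_s_prime, eta=eta)
        return simulate_profile(
            props, noise=NoiseModel(relative_sigma=0.0), channel=channel
        )

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
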