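import numpy as np
import pytest
from hypothesis import settings

from glycomsi import phantom

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def kidney_phantom():
    """The default kidney phantom at a fixed seed, shared across tests."""
    spec = phantom.default_kidney_spec(seed=1)
    return phantom.make_phantom(spec)


@pytest.fixture(scope="session")
def small_phantom():
    """A reduced 24x16 phantom for fast end-to-end tests."""
    spec = phantom.default_kidney_spec(seed=7)
    spec.nx, spec.ny = 24, 16
    spec.treated_center = (7.0, 8.0)
    spec.treated_semiaxes = (5.5, 6.5)
    spec.control_center = (18.0, 8.0)
    spec.control_semiaxes = (4.0, 5.0)
    spec.calibrant_spots = ((0, 0), (1, 0))
    spec.noise_rate = 2.0
    return phantom.make_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
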