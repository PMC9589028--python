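import numpy as np
import pytest

from ssdr.phantom import PhantomSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """A 16^3 phantom spec for fast unit tests."""
    return PhantomSpec(grid_shape=(16, 16, 16), n_branches=2,
                       radius_range=(0.8, 1.5), bifurcation_prob=0.2,
                       n_aneurysms=0, aneurysm_radius_range=(1.0, 1.5),
                       background_noise_sd=0.0, seed=3)


@pytest.fixture
def smooth_blob():
    """A smooth Gaussian blob volume for interpolation-tolerance tests."""
    x = np.linspace(-1.0, 1.0, 32)
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    return np.exp(-(X ** 2 + Y ** 2 + Z ** 2) / 0.3)
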