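import numpy as np
import pytest

from decontrast import phantom
from decontrast.types import Volume3D


@pytest.fixture(scope="session")
def default_sample() -> phantom.PhantomSample:
    """One default 32³ phantom subject, shared read-only across tests."""
    return phantom.make_phantom(phantom.PhantomParams(seed=7))


@pytest.fixture(scope="session")
def clean_sample() -> phantom.PhantomSample:
    """Noise-free phantom (texture sigma 0) for exact-intensity checks."""
    return phantom.make_phantom(phantom.PhantomParams(noise_sigma=0.0, seed=7))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(123)


@pytest.fixture
def random_volume(rng) -> Volume3D:
    return Volume3D(rng.random((12, 12, 12)), voxel_size_mm=2.0)
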