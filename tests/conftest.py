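import numpy as np
import pytest

from hsiband import Hypercube, WavelengthAxis


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_axis():
    return WavelengthAxis(start_nm=325.0, step_nm=0.728, n_channels=10)


@pytest.fixture
def small_cube(rng, small_axis):
    """A 4x4x10 cube of random non-negative intensities."""
    return Hypercube(values=rng.random((4, 4, 10)), axis=small_axis)


def random_cube(rng, y=4, x=4, n=8):
    axis = WavelengthAxis(start_nm=400.0, step_nm=1.0, n_channels=n)
    return Hypercube(values=rng.random((y, x, n)), axis=axis)
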