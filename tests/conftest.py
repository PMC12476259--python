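import numpy as np
import pytest

from holoseg.imaging import RasterImage
from holoseg.osh import OSHParams, reference_gain
from holoseg.phantom import PhantomSpec


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def ref_params():
    """Reference-scaled OSH chain parameters used across pipeline tests."""
    return OSHParams(scale="reference")


@pytest.fixture(scope="session")
def ref_gain(ref_params):
    return reference_gain((224, 224), ref_params.filter_radius_frac,
                          ref_params.soft_edge, ref_params.amplitude_sigma)


@pytest.fixture(scope="session")
def small_spec():
    """Phantom study conditions, two images per class."""
    return PhantomSpec(n_per_class=2, seed=424242)


@pytest.fixture()
def gradient_image():
    """Simple non-constant GRAY image."""
    x = np.linspace(0.0, 1.0, 64)
    return RasterImage(np.tile(x, (64, 1)), "GRAY")
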