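import numpy as np
import pytest

from siqr import PhantomSpec, make_phantom


def small_spec(**kw) -> PhantomSpec:
    """64-cube phantom, scaled to fit, for cheaper unit tests."""
    defaults = dict(
        shape=(64, 64, 64),
        wm_radii=(16.0, 20.0, 14.0),
        gm_thickness=3.0,
        csf_thickness=3.0,
    )
    defaults.update(kw)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def phantom96():
    """Default 96-cube phantom with ground-truth segmentation."""
    return make_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def phantom64():
    """Smaller phantom for unit tests of the measures."""
    return make_phantom(small_spec())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
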