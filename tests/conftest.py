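import numpy as np
import pytest

from cfrm.classify import ModelConfig
from cfrm.spectral_io import RamanMap, Spectrum, WavenumberAxis, default_axis


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def tiny_axis():
    return WavenumberAxis(np.array([100.0, 200.0, 300.0]))


@pytest.fixture
def full_axis():
    return default_axis()


def make_random_map(rng, h, w, m, wn_lo=400.0, wn_hi=3300.0):
    axis = WavenumberAxis(np.sort(rng.uniform(wn_lo, wn_hi, size=m)))
    return RamanMap(rng.uniform(0, 10, size=(h, w, m)), axis)


@pytest.fixture
def random_map_factory(rng):
    return lambda h, w, m: make_random_map(rng, h, w, m)


@pytest.fixture
def small_model_config():
    """Cheap architecture used where only mechanics, not accuracy, matter."""
    return ModelConfig(
        channel_reduction=(80, 16),
        groups=(8, 8),
        spatial_convs=(16,),
        fc_widths=(32, 6),
        seed=7,
    )


@pytest.fixture
def smooth_spectrum(full_axis):
    """Smooth positive reference-like spectrum on the full 1600-channel axis."""
    wn = full_axis.values
    y = (
        0.6
        + 0.3 * np.exp(-0.5 * ((wn - 1200.0) / 450.0) ** 2)
        + 0.4 * np.exp(-0.5 * ((wn - 2600.0) / 380.0) ** 2)
    )
    return Spectrum(y, full_axis)
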