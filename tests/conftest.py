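import numpy as np
import pytest
import scipy.ndimage

from quadholo import OpticalConfig, SampleField


@pytest.fixture
def rng():
    return np.random.default_rng(20230427)


def make_smooth_sample(rng, shape=(64, 64), amplitude=3.0, pixel_size=0.345):
    """Random band-limited phase object with alpha == 1."""
    phase = scipy.ndimage.gaussian_filter(rng.normal(size=shape), 4) * amplitude / 0.1
    phase -= phase.mean()
    return SampleField(
        transmission=np.exp(1j * phase),
        pixel_size=pixel_size,
        truth_phase=phase,
        truth_thickness=np.abs(phase) * 0.532 / (2 * np.pi * 0.52),
        n_s=1.52,
        n_m=1.0,
        wavelength=0.532,
    )


@pytest.fixture
def smooth_sample(rng):
    return make_smooth_sample(rng)


@pytest.fixture
def small_config():
    return OpticalConfig(shape=(64, 64))
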