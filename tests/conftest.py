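import numpy as np
import pytest

from tracernmr import (
    IsotopomerDistribution,
    get_spin_system,
    render_multiplet,
    stick_pattern,
)
from tracernmr.spectra import Axis, Spectrum1D


@pytest.fixture
def serine_c2():
    return get_spin_system("serine", "C2")


@pytest.fixture
def creatine_c2():
    return get_spin_system("creatine", "C2")


@pytest.fixture
def make_c13_slice():
    """Factory: rendered ¹³C slice for a spin system + isotopomer mixture."""

    def _make(system, fractions, fwhm=1.5, step_hz=0.5, snr=None, seed=7,
              n_points=512, n15_shift_hz=-3.0):
        axis = Axis(150.9, system.shift_c, n_points * step_hz, n_points)
        offsets = (axis.values - system.shift_c) * axis.spectrometer_freq
        pattern = stick_pattern(system, IsotopomerDistribution(fractions), n15_shift_hz)
        y = np.asarray(render_multiplet(pattern, offsets, fwhm).intensity, dtype=float)
        if snr is not None:
            rng = np.random.default_rng(seed)
            y = y + (y.max() / snr) * rng.standard_normal(n_points)
        return Spectrum1D(axis, y)

    return _make


@pytest.fixture
def axis_1d():
    """600 MHz 1D NOESY axis (11.97 ppm / 7183.9 Hz sweep)."""
    return Axis(600.0, 4.8, 7183.9, 16384)
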