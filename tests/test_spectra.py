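"""FID simulation, 1D/2D processing, referencing, calibration and slicing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tracernmr import IsotopomerDistribution, get_spin_system
from tracernmr.spectra import (
    Axis,
    HSQCComponent,
    Spectrum1D,
    apodize,
    build_hsqc,
    calibrate_hsqc,
    extract_c13_slice,
    ft_spectrum,
    process_1d,
    reference_to_tmsp,
    simulate_fid,
)
from tracernmr.spin_model import render_multiplet, stick_pattern


class TestAxis:
    def test_values_descend(self, axis_1d):
        assert np.all(np.diff(axis_1d.values) < 0)

    @given(st.floats(-5, 15))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_ppm_hz_round_trip(self, ppm):
        axis = Axis(600.0, 4.8, 7183.9, 1024)
        assert axis.hz_to_ppm(axis.ppm_to_hz(ppm)) == pytest.approx(ppm, abs=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            Axis(600.0, 4.8, 7183.9, 1)


class TestSimulateFid:
    def test_single_peak_transforms_to_lorentzian_at_position(self, axis_1d):
        fid = simulate_fid([(3.0, 1.0, 5.0)], axis_1d)
        spec = ft_spectrum(fid).real
        assert axis_1d.values[np.argmax(spec)] == pytest.approx(3.0, abs=axis_1d.ppm_step)

    def test_two_equal_peaks_equal_heights(self, axis_1d):
        # on-grid positions so the sampled apex is the true apex
        p1 = float(axis_1d.values[axis_1d.index_of(2.0)])
        p2 = float(axis_1d.values[axis_1d.index_of(6.0)])
        fid = simulate_fid([(p1, 1.0, 5.0), (p2, 1.0, 5.0)], axis_1d)
        spec = ft_spectrum(fid).real
        h1 = spec[axis_1d.index_of(p1)]
        h2 = spec[axis_1d.index_of(p2)]
        assert h1 == pytest.approx(h2, rel=0.01)

    def test_deterministic_given_seed(self, axis_1d):
        a = simulate_fid([(3.0, 1.0, 5.0)], axis_1d, noise_sd=0.1, seed=42)
        b = simulate_fid([(3.0, 1.0, 5.0)], axis_1d, noise_sd=0.1, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_peak_outside_sweep_rejected(self, axis_1d):
        with pytest.raises(ValueError, match="outside the spectral width"):
            simulate_fid([(30.0, 1.0, 5.0)], axis_1d)

    def test_parseval_energy_preserved(self, axis_1d):
        fid = simulate_fid([(3.0, 1.0, 5.0), (1.2, 0.3, 8.0)], axis_1d)
        assert np.linalg.norm(ft_spectrum(fid)) == pytest.approx(
            np.linalg.norm(fid), rel=1e-6)


class TestProcess1D:
    def test_default_output_length_is_32k(self, axis_1d):
        fid = simulate_fid([(3.0, 1.0, 5.0)], axis_1d)
        spec = process_1d(fid, axis_1d)
        assert spec.axis.n_points == 32768

    @pytest.mark.parametrize("decay, lb", [(6.0, 0.3), (10.0, 0.3), (6.0, 1.0)])
    def test_linewidth_adds_exponential_broadening(self, axis_1d, decay, lb):
        # a decay R gives FWHM R/π; exponential apodization adds lb Hz
        fid = simulate_fid([(3.0, 1.0, decay)], axis_1d)
        spec = process_1d(fid, axis_1d, line_broadening=lb)
        y, v = spec.intensity, spec.axis.values * 600.0
        i = int(np.argmax(y))
        half = y[i] / 2
        li, ri = i, i
        while y[li] > half:
            li -= 1
        while y[ri] > half:
            ri += 1
        xl = np.interp(half, [y[li], y[li + 1]], [v[li], v[li + 1]])
        xr = np.interp(half, [y[ri], y[ri - 1]], [v[ri], v[ri - 1]])
        assert abs(xl - xr) == pytest.approx(decay / np.pi + lb, rel=0.03)

    def test_zero_fid_gives_zero_spectrum(self, axis_1d):
        spec = process_1d(np.zeros(1024, complex), axis_1d)
        np.testing.assert_array_equal(spec.intensity, 0.0)

    def test_insufficient_zero_fill_rejected(self, axis_1d):
        with pytest.raises(ValueError):
            process_1d(np.ones(4096, complex), axis_1d, zero_fill_to=1024)

    def test_processing_log_records_steps(self, axis_1d):
        spec = process_1d(simulate_fid([(3.0, 1.0, 5.0)], axis_1d), axis_1d)
        joined = " ".join(spec.processing_log)
        for word in ("apodization", "zero-fill", "phase", "baseline"):
            assert word in joined

    def test_cosine_squared_apodization_reduces_sidelobes(self):
        # truncated sinusoid: sinc sidelobes drop after cos² weighting
        n = 512
        t = np.arange(n)
        fid = np.exp(2j * np.pi * 0.123 * t)
        raw = np.abs(np.fft.fft(fid, 4096))
        win = np.abs(np.fft.fft(apodize(fid, "cosine_squared"), 4096))

        def max_sidelobe(y):
            # exclude the main lobe out to where it first falls below 1% of
            # the apex, then report the tallest remaining feature
            i = int(np.argmax(y))
            lo = i
            while lo > 0 and y[lo] > 0.01 * y[i]:
                lo -= 1
            hi = i
            while hi < len(y) - 1 and y[hi] > 0.01 * y[i]:
                hi += 1
            m = np.ones(len(y), bool)
            m[lo:hi + 1] = False
            return y[m].max() / y[i]

        assert max_sidelobe(win) < max_sidelobe(raw)


class TestReferencing:
    def test_shift_moves_all_peaks(self, axis_1d):
        spec = process_1d(simulate_fid([(3.0, 1.0, 5.0)], axis_1d), axis_1d)
        out = reference_to_tmsp(spec, tmsp_observed=0.05)
        assert out.axis.values[np.argmax(out.intensity)] == pytest.approx(
            2.95, abs=out.axis.ppm_step)

    def test_zero_observed_is_identity(self, axis_1d):
        spec = process_1d(simulate_fid([(3.0, 1.0, 5.0)], axis_1d), axis_1d)
        out = reference_to_tmsp(spec, 0.0)
        np.testing.assert_array_equal(out.axis.values, spec.axis.values)

    def test_double_application_idempotent(self, axis_1d):
        spec = process_1d(simulate_fid([(0.05, 1.0, 5.0)], axis_1d), axis_1d)
        once = reference_to_tmsp(spec, 0.05)
        # the TMSP peak now sits at 0.00; referencing again observes 0.00
        tmsp_now = once.axis.values[np.argmax(once.intensity)]
        twice = reference_to_tmsp(once, round(float(tmsp_now), 6))
        np.testing.assert_allclose(twice.axis.values, once.axis.values,
                                   atol=once.axis.ppm_step)


def _lactate_hsqc(offset_h=0.0, offset_c=0.0, n_h=256, n_c=1024):
    """Lactate HSQC whose axes are then mislabelled by the given offsets."""
    from tracernmr.spectra import HSQCSpectrum

    sys = get_spin_system("lactate", "C3")
    axis_h = Axis(600.0, 2.9, 2700.0, n_h)
    axis_c = Axis(150.9, 45.0, 9000.0, n_c)
    dist = IsotopomerDistribution({"singlet": 1.0})
    spec = build_hsqc([HSQCComponent(sys, dist, 1.0, 0.5)], axis_h, axis_c)
    if offset_h or offset_c:
        spec = HSQCSpectrum(axis_h.shifted(offset_h), axis_c.shifted(offset_c),
                            spec.intensity)
    return spec


class TestCalibrateHSQC:
    def test_known_offset_corrected(self):
        # mis-set axes put lactate at (1.36, 23.4); calibration restores it
        spec = _lactate_hsqc(offset_h=0.05, offset_c=0.5)
        obs = spec.peak_position()
        assert obs[0] == pytest.approx(1.36, abs=spec.axis_h.ppm_step)
        cal = calibrate_hsqc(spec, obs)
        assert cal.calibration_applied
        ph, pc = cal.peak_position()
        assert ph == pytest.approx(1.31, abs=cal.axis_h.ppm_step)
        assert pc == pytest.approx(22.9, abs=cal.axis_c.ppm_step)

    def test_reference_position_is_identity(self):
        spec = _lactate_hsqc()
        cal = calibrate_hsqc(spec, (1.31, 22.9))
        np.testing.assert_array_equal(cal.axis_h.values, spec.axis_h.values)
        np.testing.assert_array_equal(cal.axis_c.values, spec.axis_c.values)


class TestBuildHSQC:
    axes = (Axis(600.0, 2.9, 2700.0, 512), Axis(150.9, 45.0, 9000.0, 4096))

    def test_volume_proportional_to_label_fraction(self):
        sys = get_spin_system("alanine", "C2")
        dist = IsotopomerDistribution({"dd": 1.0})
        v = []
        for x in (0.3, 0.6):
            spec = build_hsqc([HSQCComponent(sys, dist, 1.0, x)], *self.axes)
            v.append(spec.volume(sys.shift_h, sys.shift_c, 0.1, 0.5))
        assert v[1] == pytest.approx(2 * v[0], rel=1e-9)

    def test_unlabelled_position_gives_no_signal(self):
        sys = get_spin_system("alanine", "C2")
        dist = IsotopomerDistribution({"dd": 1.0})
        spec = build_hsqc([HSQCComponent(sys, dist, 1.0, 0.0)], *self.axes)
        assert np.abs(spec.intensity).max() == 0.0

    def test_linear_in_components(self):
        d = IsotopomerDistribution({"singlet": 1.0})
        c1 = HSQCComponent(get_spin_system("lactate", "C3"), d, 1.0, 0.5)
        c2 = HSQCComponent(get_spin_system("alanine", "C2"), d, 2.0, 0.3)
        both = build_hsqc([c1, c2], *self.axes)
        sum_ = (build_hsqc([c1], *self.axes).intensity
                + build_hsqc([c2], *self.axes).intensity)
        np.testing.assert_allclose(both.intensity, sum_, rtol=1e-12)

    def test_out_of_window_peak_reported_not_dropped(self):
        d = IsotopomerDistribution({"singlet": 1.0})
        outside = HSQCComponent(
            get_spin_system("lactate", "C3"), d, 1.0, 0.5)
        narrow_h = Axis(600.0, 4.0, 600.0, 64)  # 3.5–4.5 ppm: excludes 1.31
        spec = build_hsqc([outside], narrow_h, self.axes[1])
        assert any("lactate" in line for line in spec.clipping_report)


class TestExtractSlice:
    def test_slice_reproduces_rendered_multiplet(self):
        sys = get_spin_system("serine", "C2")
        dist = IsotopomerDistribution({"dd": 0.6, "singlet": 0.4})
        axes = TestBuildHSQC.axes
        spec = build_hsqc([HSQCComponent(sys, dist, 1.0, 0.8)], *axes)
        sl = extract_c13_slice(spec, sys.shift_h)
        off = (axes[1].values - sys.shift_c) * axes[1].spectrometer_freq
        expected = np.asarray(render_multiplet(
            stick_pattern(sys, dist), off, 1.5).intensity)
        r = np.corrcoef(sl.intensity, expected)[0, 1]
        assert r > 0.999

    def test_empty_region_is_noise_bounded(self):
        sys = get_spin_system("serine", "C2")
        dist = IsotopomerDistribution({"singlet": 1.0})
        axes = TestBuildHSQC.axes
        noise_sd = 1e-4
        spec = build_hsqc([HSQCComponent(sys, dist, 1.0, 0.8)], *axes,
                          noise_sd=noise_sd, seed=3)
        sl = extract_c13_slice(spec, 1.0)  # far from any ¹H resonance
        assert np.abs(sl.intensity).max() <= 5 * noise_sd

    def test_zero_width_takes_single_column(self):
        spec = _lactate_hsqc()
        sl = extract_c13_slice(spec, 1.31, averaging_width=0.0)
        col = spec.intensity[:, spec.axis_h.index_of(1.31)]
        np.testing.assert_array_equal(sl.intensity, col)

    def test_window_overlapping_other_peak_warns(self):
        spec = _lactate_hsqc()
        sl = extract_c13_slice(spec, 1.31, averaging_width=0.2,
                               known_peaks_h=[1.36])
        assert any("warning" in line for line in sl.processing_log)


class TestSpectrumContainer:
    def test_round_trips_through_disk(self, tmp_path, axis_1d):
        spec = process_1d(simulate_fid([(3.0, 1.0, 5.0)], axis_1d), axis_1d,
                          water_region=(4.7, 4.9))
        spec.save(tmp_path / "s.json")
        back = Spectrum1D.load(tmp_path / "s.json")
        np.testing.assert_allclose(back.intensity, spec.intensity)
        assert back.axis == spec.axis
        assert back.excluded_regions == [(4.7, 4.9)]
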