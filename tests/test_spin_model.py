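"""Stick patterns, lineshape rendering and echo-antiecho phase distortion."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tracernmr.spin_model import (
    IsotopomerDistribution,
    SpinSystem,
    StickPattern,
    apply_echo_antiecho_distortion,
    render_multiplet,
    stick_pattern,
)


def brute_force_sticks(state, j_left, j_right, j_cn, n15_shift):
    """Independent oracle: enumerate ± sign combinations of J/2 splittings."""
    base, n15 = (state[:-4], True) if state.endswith("+n15") else (state, False)
    js = {"singlet": [], "d_left": [j_left], "d_right": [j_right],
          "dd": [j_left, j_right]}[base]
    center = n15_shift if n15 else 0.0
    if n15:
        js = js + [j_cn]
    lines = {}
    for signs in itertools.product([-1, 1], repeat=len(js)):
        pos = round(center + sum(s * j / 2 for s, j in zip(signs, js)), 9)
        lines[pos] = lines.get(pos, 0.0) + 1.0 / 2 ** len(js)
    return lines


class TestStickPattern:
    def test_serine_dd_line_positions(self, serine_c2):
        # doublet of doublets from J = 53.1 and 36.9 Hz: four equal lines
        pat = stick_pattern(serine_c2, IsotopomerDistribution({"dd": 1.0}))
        assert sorted(np.round(pat.offsets_hz, 6)) == [-45.0, -8.1, 8.1, 45.0]
        np.testing.assert_allclose(pat.amplitudes, 0.25)

    def test_singlet_single_line(self, serine_c2):
        pat = stick_pattern(serine_c2, IsotopomerDistribution({"singlet": 1.0}))
        assert pat.offsets_hz.tolist() == [0.0]
        assert pat.amplitudes.tolist() == [1.0]

    def test_half_doublet_half_singlet(self):
        sys = SpinSystem("x", "C2", 3.9, 54.7, 2, j_cc_left=54.5)
        pat = stick_pattern(sys, IsotopomerDistribution({"d_left": 0.5, "singlet": 0.5}))
        lines = dict(zip(np.round(pat.offsets_hz, 6), pat.amplitudes))
        assert lines == {-27.25: 0.25, 0.0: 0.5, 27.25: 0.25}

    @pytest.mark.parametrize("state", ["singlet", "d_left", "d_right", "dd",
                                       "singlet+n15", "dd+n15"])
    def test_matches_sign_enumeration_oracle(self, serine_c2, state):
        shift = -3.0
        pat = stick_pattern(serine_c2, IsotopomerDistribution({state: 1.0}), shift)
        expected = brute_force_sticks(state, 53.1, 36.9, 5.9, shift)
        got = dict(zip(np.round(pat.offsets_hz, 9), pat.amplitudes))
        assert got.keys() == expected.keys()
        for k in expected:
            assert got[k] == pytest.approx(expected[k])

    def test_missing_coupling_error_names_state(self, creatine_c2):
        # creatine C2 has no higher-numbered carbon, so d_right is impossible
        with pytest.raises(ValueError, match="d_right"):
            stick_pattern(creatine_c2, IsotopomerDistribution({"d_right": 1.0}))

    @given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=4),
           st.floats(10, 60), st.floats(10, 60))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_amplitude_conservation(self, raw, j1, j2):
        # total stick amplitude is invariant under splitting (label conservation)
        states = ["singlet", "d_left", "d_right", "dd"][: len(raw)]
        total = sum(raw)
        dist = IsotopomerDistribution({s: f / total for s, f in zip(states, raw)})
        sys = SpinSystem("x", "C2", 3.8, 57.0, 1, j_cc_left=j1, j_cc_right=j2)
        pat = stick_pattern(sys, dist)
        assert pat.total_amplitude == pytest.approx(1.0, abs=1e-9)

    @given(st.floats(10, 60), st.floats(10, 60), st.floats(0, 1))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_symmetric_without_isotope_shift(self, j1, j2, f_dd):
        sys = SpinSystem("x", "C2", 3.8, 57.0, 1, j_cc_left=j1, j_cc_right=j2)
        dist = IsotopomerDistribution({"dd": f_dd, "singlet": 1 - f_dd})
        pat = stick_pattern(sys, dist)
        lines = sorted(zip(np.round(pat.offsets_hz, 6), np.round(pat.amplitudes, 9)))
        mirrored = sorted(zip(-np.round(pat.offsets_hz, 6), np.round(pat.amplitudes, 9)))
        assert lines == mirrored


class TestDistributionValidation:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            IsotopomerDistribution({"singlet": 0.5, "dd": 0.4})

    def test_unknown_state_rejected(self):
        with pytest.raises(ValueError, match="unknown labelling state"):
            IsotopomerDistribution({"triplet": 1.0})

    def test_carbon_marginal_folds_n15(self):
        d = IsotopomerDistribution({"dd": 0.4, "dd+n15": 0.3, "singlet": 0.3})
        assert d.carbon_marginal()["dd"] == pytest.approx(0.7)


class TestRenderMultiplet:
    def test_single_stick_is_lineshape(self):
        axis = np.linspace(-50, 50, 2001)
        pat = StickPattern(np.array([7.0]), np.array([1.0]))
        out = render_multiplet(pat, axis, fwhm=2.0)
        y = np.asarray(out.intensity)
        assert axis[np.argmax(y)] == pytest.approx(7.0, abs=0.05)
        half = y >= y.max() / 2
        fwhm = axis[half].max() - axis[half].min()
        assert fwhm == pytest.approx(2.0, abs=0.11)

    @pytest.mark.parametrize("lineshape", ["lorentzian", "gaussian"])
    def test_integral_equals_total_amplitude(self, serine_c2, lineshape):
        axis = np.linspace(-200, 200, 8001)  # window 200×fwhm
        pat = stick_pattern(serine_c2, IsotopomerDistribution({"dd": 1.0}))
        y = np.asarray(render_multiplet(pat, axis, 2.0, lineshape).intensity)
        integral = np.trapezoid(y, axis)
        assert integral == pytest.approx(1.0, rel=0.01)

    def test_rendering_is_linear_in_patterns(self, serine_c2):
        axis = np.linspace(-60, 60, 1201)
        p1 = stick_pattern(serine_c2, IsotopomerDistribution({"dd": 1.0}))
        p2 = stick_pattern(serine_c2, IsotopomerDistribution({"singlet": 1.0}))
        merged = StickPattern(np.concatenate([p1.offsets_hz, p2.offsets_hz]),
                              np.concatenate([p1.amplitudes, p2.amplitudes]))
        y12 = (np.asarray(render_multiplet(p1, axis, 1.5).intensity)
               + np.asarray(render_multiplet(p2, axis, 1.5).intensity))
        ym = np.asarray(render_multiplet(merged, axis, 1.5).intensity)
        np.testing.assert_allclose(ym, y12, rtol=1e-12)

    def test_coarse_axis_flagged(self):
        pat = StickPattern(np.array([0.0]), np.array([1.0]))
        out = render_multiplet(pat, np.linspace(-10, 10, 11), fwhm=1.0)
        assert out.undersampled
        fine = render_multiplet(pat, np.linspace(-10, 10, 201), fwhm=1.0)
        assert not fine.undersampled

    def test_nonpositive_fwhm_rejected(self):
        pat = StickPattern(np.array([0.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            render_multiplet(pat, np.linspace(-1, 1, 5), fwhm=0.0)


class TestEchoAntiecho:
    def test_zero_delay_is_identity(self, serine_c2):
        pat = stick_pattern(serine_c2, IsotopomerDistribution({"dd": 1.0}))
        out = apply_echo_antiecho_distortion(pat, j2_cc=2.5, encoding_delay=0.0)
        np.testing.assert_array_equal(out.amplitudes, pat.amplitudes)

    def test_zero_j2_is_identity(self, serine_c2):
        pat = stick_pattern(serine_c2, IsotopomerDistribution({"dd": 1.0}))
        out = apply_echo_antiecho_distortion(pat, j2_cc=0.0, encoding_delay=0.1)
        np.testing.assert_array_equal(out.amplitudes, pat.amplitudes)

    def test_unit_phase_product_inverts_lines(self, serine_c2):
        # j2·delay = 1 → phase π → the rendered real part changes sign
        pat = stick_pattern(serine_c2, IsotopomerDistribution({"dd": 1.0}))
        rot = apply_echo_antiecho_distortion(pat, j2_cc=2.0, encoding_delay=0.5)
        axis = np.linspace(-60, 60, 1201)
        y0 = np.asarray(render_multiplet(pat, axis, 1.5).intensity)
        y1 = np.asarray(render_multiplet(rot, axis, 1.5).intensity)
        np.testing.assert_allclose(y1.real, -y0, atol=1e-12)

    def test_intermediate_phase_mixes_dispersion(self, serine_c2):
        pat = stick_pattern(serine_c2, IsotopomerDistribution({"singlet": 1.0}))
        rot = apply_echo_antiecho_distortion(pat, j2_cc=2.5, encoding_delay=0.1)
        axis = np.linspace(-60, 60, 1201)
        y = np.asarray(render_multiplet(rot, axis, 1.5).intensity).real
        assert (y < -1e-4).any()  # dispersive wings go negative

    def test_negative_delay_rejected(self, serine_c2):
        pat = stick_pattern(serine_c2, IsotopomerDistribution({"singlet": 1.0}))
        with pytest.raises(ValueError):
            apply_echo_antiecho_distortion(pat, 2.0, -0.1)
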