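"""Phase retrieval, calibration subtraction, unwrapping, thickness conversion."""

import numpy as np
import pytest

from quadholo import (
    BeadSpec,
    OpticalConfig,
    PhaseMap,
    bead_field,
    closed_form_intensities,
    phase_to_thickness,
    subtract_calibration,
    theoretical_resolution,
    uniform_field,
    unwrap_phase,
    wrap,
    wrapped_phase,
)
from quadholo.forward import HologramSet
from quadholo.reconstruct import count_residues

from conftest import make_smooth_sample


def holo_from_values(i1, i2, i3, i4, shape=(8, 8)):
    return HologramSet({1: np.full(shape, float(i1)), 2: np.full(shape, float(i2)),
                        3: np.full(shape, float(i3)), 4: np.full(shape, float(i4))})


class TestWrappedPhase:
    def test_zero_phase(self):
        pm = wrapped_phase(holo_from_values(1, 0, 0.5, 0.5))
        np.testing.assert_allclose(pm.values, 0.0, atol=1e-15)

    def test_quarter_phase(self):
        pm = wrapped_phase(holo_from_values(0.5, 0.5, 1, 0))
        np.testing.assert_allclose(pm.values, np.pi / 2)

    def test_full_quadrant_recovery(self):
        # a phase beyond pi/2 in magnitude needs the four-quadrant arctangent
        for phi in (-2.9, -1.8, 2.2, 3.0):
            i1 = 0.25 * (2 + 2 * np.cos(phi))
            i2 = 0.25 * (2 - 2 * np.cos(phi))
            i3 = 0.25 * (2 + 2 * np.sin(phi))
            i4 = 0.25 * (2 - 2 * np.sin(phi))
            pm = wrapped_phase(holo_from_values(i1, i2, i3, i4))
            np.testing.assert_allclose(pm.values, phi, atol=1e-12)

    def test_no_modulation_pixels_masked(self):
        h = holo_from_values(0.5, 0.5, 0.5, 0.5, shape=(8, 8))
        h.images[1][0, 0] += 0.3  # one modulated pixel
        pm = wrapped_phase(h)
        assert pm.valid[0, 0]
        assert not pm.valid[4, 4]
        assert pm.values[4, 4] == 0.0

    def test_round_trip_with_arm_offset(self, rng):
        sample = make_smooth_sample(rng)
        cfg = OpticalConfig(shape=(64, 64), arm_phase_offset=1.0)
        pm = wrapped_phase(closed_form_intensities(sample, cfg))
        expected = wrap(sample.truth_phase + 1.0)
        np.testing.assert_allclose(wrap(pm.values - expected), 0.0, atol=1e-10)


class TestCalibration:
    def test_self_subtraction_is_zero(self, rng):
        vals = wrap(rng.normal(size=(16, 16)) * 2)
        pm = PhaseMap(vals.copy())
        np.testing.assert_allclose(subtract_calibration(pm, pm).values, 0.0, atol=1e-15)

    def test_wrapping_arithmetic(self):
        pm = PhaseMap(np.full((4, 4), 3.0))
        cal = PhaseMap(np.full((4, 4), -3.0))
        out = subtract_calibration(pm, cal)
        np.testing.assert_allclose(out.values, 6.0 - 2 * np.pi, atol=1e-12)

    def test_removes_arm_offset(self, rng):
        sample = make_smooth_sample(rng)
        cfg = OpticalConfig(shape=(64, 64), arm_phase_offset=1.0)
        pm = wrapped_phase(closed_form_intensities(sample, cfg))
        empty = uniform_field(shape=(64, 64))
        cal = wrapped_phase(closed_form_intensities(empty, cfg))
        out = subtract_calibration(pm, cal)
        np.testing.assert_allclose(
            wrap(out.values - wrap(sample.truth_phase)), 0.0, atol=1e-10
        )

    def test_dims_mismatch_raises(self):
        with pytest.raises(ValueError, match="dims differ"):
            subtract_calibration(PhaseMap(np.zeros((8, 8))), PhaseMap(np.zeros((4, 4))))


class TestUnwrap:
    def test_ramp_recovered_to_constant(self):
        x = np.arange(200) * 0.05
        ramp = np.tile(x, (64, 1))
        out = unwrap_phase(PhaseMap(wrap(ramp))).values
        diff = out - ramp
        assert np.ptp(diff) < 1e-6

    def test_already_unwrapped_field_unchanged(self, rng):
        field = make_smooth_sample(rng, amplitude=0.2).truth_phase  # well inside (-pi, pi]
        out = unwrap_phase(PhaseMap(field.copy())).values
        diff = out - field
        assert np.ptp(diff) < 1e-8

    def test_thick_bead_dome_recovered(self):
        # 20 um bead: peak phase ~4.72 rad exceeds pi, so the wrapped map has
        # a genuine 2*pi discontinuity ring
        s = bead_field([BeadSpec(20.0, (44.0, 44.0), 1.49)], n_m=1.51, shape=(256, 256))
        assert np.abs(s.truth_phase).max() > np.pi
        wrapped = wrap(s.truth_phase)
        assert count_residues(wrapped) == 0
        out = unwrap_phase(PhaseMap(wrapped)).values
        diff = out - s.truth_phase
        rms = np.sqrt(np.mean((diff - diff.mean()) ** 2))
        assert rms < 1e-3

    def test_residue_count_on_clean_fields(self, rng):
        field = make_smooth_sample(rng).truth_phase
        assert count_residues(wrap(field)) == 0


class TestThickness:
    def test_bead_phase_to_thickness_printed_value(self):
        pm = PhaseMap(np.array([[2.35]]), wrapped=False)
        t = phase_to_thickness(pm, wavelength=0.532, n_s=1.49, n_m=1.51)
        assert t.values[0, 0] == pytest.approx(9.95, abs=5e-3)

    def test_linearity_in_phase_and_wavelength(self):
        pm1 = PhaseMap(np.array([[1.0]]), wrapped=False)
        pm2 = PhaseMap(np.array([[2.0]]), wrapped=False)
        t1 = phase_to_thickness(pm1, 0.532, 1.52, 1.0).values[0, 0]
        t2 = phase_to_thickness(pm2, 0.532, 1.52, 1.0).values[0, 0]
        t3 = phase_to_thickness(pm1, 1.064, 1.52, 1.0).values[0, 0]
        t4 = phase_to_thickness(pm1, 0.532, 2.04, 1.0).values[0, 0]
        assert t2 == pytest.approx(2 * t1)
        assert t3 == pytest.approx(2 * t1)
        assert t4 == pytest.approx(0.5 * t1)

    def test_zero_phase_zero_thickness(self):
        t = phase_to_thickness(PhaseMap(np.zeros((4, 4)), wrapped=False), 0.532, 1.52, 1.0)
        np.testing.assert_array_equal(t.values, 0.0)

    def test_matched_index_raises(self):
        with pytest.raises(ValueError, match="n_s == n_m"):
            phase_to_thickness(PhaseMap(np.ones((2, 2))), 0.532, 1.5, 1.5)

    def test_magnitude_reported_for_negative_phase(self):
        pm = PhaseMap(np.array([[-2.0]]), wrapped=False)
        t = phase_to_thickness(pm, 0.532, 1.49, 1.51)
        assert t.values[0, 0] > 0


class TestResolutionFormula:
    def test_system_hardware_value(self):
        assert theoretical_resolution(0.532, 0.25) == pytest.approx(1.064)

    def test_homogeneity(self):
        assert theoretical_resolution(0.532, 0.5) == pytest.approx(
            theoretical_resolution(0.532, 0.25) / 2
        )

    def test_zero_wavelength(self):
        assert theoretical_resolution(0.0, 0.25) == 0.0

    def test_invalid_na_raises(self):
        with pytest.raises(ValueError):
            theoretical_resolution(0.532, 0.0)
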