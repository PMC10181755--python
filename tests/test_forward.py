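"""Four-channel forward model: closed form, Jones chain, pupil, camera effects."""

import numpy as np
import pytest

from quadholo import (
    BeadSpec,
    ChannelTransform,
    MisalignmentModel,
    NoiseModel,
    OpticalConfig,
    apply_pupil,
    bead_field,
    closed_form_intensities,
    corrupt,
    propagate_system,
    uniform_field,
    usaf_phase_target,
    wrapped_phase,
)
from quadholo.forward import warp_channel

from conftest import make_smooth_sample


def constant_phase_sample(phase, shape=(16, 16)):
    s = uniform_field(shape=shape)
    s.transmission = np.exp(1j * phase) * np.ones(shape, dtype=complex)
    s.truth_phase = np.full(shape, float(phase))
    return s


class TestClosedForm:
    def test_zero_phase_channel_values(self):
        holos = closed_form_intensities(constant_phase_sample(0.0), OpticalConfig(shape=(16, 16)))
        np.testing.assert_allclose(holos.images[1], 1.0)
        np.testing.assert_allclose(holos.images[2], 0.0, atol=1e-15)
        np.testing.assert_allclose(holos.images[3], 0.5)
        np.testing.assert_allclose(holos.images[4], 0.5)

    def test_quarter_phase_channel_values(self):
        holos = closed_form_intensities(
            constant_phase_sample(np.pi / 2), OpticalConfig(shape=(16, 16))
        )
        np.testing.assert_allclose(holos.images[1], 0.5)
        np.testing.assert_allclose(holos.images[2], 0.5)
        np.testing.assert_allclose(holos.images[3], 1.0)
        np.testing.assert_allclose(holos.images[4], 0.0, atol=1e-15)

    def test_phase_round_trip(self, rng):
        sample = make_smooth_sample(rng)
        holos = closed_form_intensities(sample, OpticalConfig(shape=(64, 64)))
        recovered = wrapped_phase(holos).values
        expected = np.angle(np.exp(1j * sample.truth_phase))
        np.testing.assert_allclose(
            np.angle(np.exp(1j * (recovered - expected))), 0.0, atol=1e-10
        )

    def test_channel_sum_conservation(self, rng):
        sample = make_smooth_sample(rng)
        h = closed_form_intensities(sample, OpticalConfig(shape=(64, 64)))
        np.testing.assert_allclose(
            h.images[1] + h.images[2], h.images[3] + h.images[4], atol=1e-12
        )

    def test_dimension_mismatch_raises(self, rng):
        sample = make_smooth_sample(rng, shape=(32, 32))
        with pytest.raises(ValueError, match="does not match"):
            closed_form_intensities(sample, OpticalConfig(shape=(64, 64)))

    def test_fringe_modulation_bound(self, rng):
        sample = make_smooth_sample(rng)
        cfg = OpticalConfig(shape=(64, 64), a_o=1.2, a_r=0.9)
        h = closed_form_intensities(sample, cfg)
        bound = np.abs(sample.transmission) * cfg.a_o * cfg.a_r  # 2 * 1/4 * 2 * alpha AO AR
        assert np.all(np.abs(h.images[1] - h.images[2]) <= bound + 1e-12)


class TestJonesChainEquivalence:
    def test_matches_closed_form_on_random_samples(self, rng):
        cfg = OpticalConfig(shape=(32, 32), a_o=1.1, a_r=0.8, arm_phase_offset=0.3)
        for _ in range(20):
            sample = make_smooth_sample(rng, shape=(32, 32), amplitude=rng.uniform(0.5, 5))
            # random absorption too
            sample.transmission = sample.transmission * rng.uniform(0.2, 1.0)
            ref = closed_form_intensities(sample, cfg)
            chain = propagate_system(sample, cfg)
            for c in range(1, 5):
                np.testing.assert_allclose(chain.images[c], ref.images[c], atol=1e-13)

    def test_uniform_sample_gives_constant_images(self):
        h = propagate_system(uniform_field(shape=(16, 16)), OpticalConfig(shape=(16, 16)))
        for img in h.images.values():
            assert np.ptp(img) < 1e-14

    def test_opaque_sample_leaves_reference_only(self):
        s = uniform_field(shape=(16, 16))
        s.transmission = np.zeros((16, 16), dtype=complex)
        cfg = OpticalConfig(shape=(16, 16), a_r=0.7)
        h = propagate_system(s, cfg)
        for img in h.images.values():
            np.testing.assert_allclose(img, 0.25 * 0.7**2, atol=1e-14)


class TestPupil:
    def test_dc_field_unchanged(self):
        s = uniform_field(shape=(32, 32))
        out = apply_pupil(s, OpticalConfig(shape=(32, 32)))
        np.testing.assert_allclose(out.transmission, s.transmission, atol=1e-12)

    def test_huge_cutoff_passes_everything(self, rng):
        s = make_smooth_sample(rng, shape=(32, 32))
        out = apply_pupil(s, OpticalConfig(shape=(32, 32), na=1.0, wavelength=0.001))
        np.testing.assert_allclose(out.transmission, s.transmission, atol=1e-12)

    def test_energy_non_increasing(self, rng):
        s = make_smooth_sample(rng, shape=(64, 64))
        out = apply_pupil(s, OpticalConfig(shape=(64, 64)))
        assert np.sum(np.abs(out.transmission) ** 2) <= np.sum(np.abs(s.transmission) ** 2) + 1e-9

    def test_sub_resolution_bars_lose_modulation(self):
        # bars far below lambda/(2 NA) stop being separable after coherent
        # filtering, while bars well above it survive
        from quadholo.metrics import resolvable

        def bar_contrast(g, e):
            s = usaf_phase_target([(g, e)], height=0.2138, shape=(256, 256))
            cfg = OpticalConfig(shape=(256, 256), coherent_cutoff_enabled=True)
            phase = wrapped_phase(closed_form_intensities(s, cfg)).values
            r0, c0, rr, cc = s.features[(g, e)]["vbars"]
            prof = phase[r0 + rr // 2, max(c0 - 3, 0) : c0 + cc + 3]
            return resolvable(prof)

        ok_coarse, contrast_coarse = bar_contrast(7, 1)  # w = 3.9 um >> gamma
        ok_fine, contrast_fine = bar_contrast(10, 1)  # w = 0.49 um << gamma
        assert ok_coarse and contrast_coarse > 0.9
        assert not ok_fine
        assert contrast_fine < 0.1


class TestCorrupt:
    def test_noise_off_identity_transform_is_identity(self, rng):
        sample = make_smooth_sample(rng)
        h = closed_form_intensities(sample, OpticalConfig(shape=(64, 64)))
        out = corrupt(h, None, MisalignmentModel.identity())
        for c in range(1, 5):
            np.testing.assert_array_equal(out.images[c], h.images[c])

    def test_fixed_seed_is_deterministic(self, rng):
        sample = make_smooth_sample(rng)
        h = closed_form_intensities(sample, OpticalConfig(shape=(64, 64)))
        noise = NoiseModel(seed=7)
        a = corrupt(h, noise, None)
        b = corrupt(h, noise, None)
        for c in range(1, 5):
            np.testing.assert_array_equal(a.images[c], b.images[c])

    def test_quantization_grid(self, rng):
        sample = make_smooth_sample(rng)
        h = closed_form_intensities(sample, OpticalConfig(shape=(64, 64)))
        noise = NoiseModel(shot_noise=False, read_noise_sigma=0.0, seed=0)
        out = corrupt(h, noise, None)
        dn = out.images[1] * noise.photon_scale
        np.testing.assert_allclose(dn, np.round(dn), atol=1e-9)
        assert dn.max() <= 2**noise.bit_depth - 1

    def test_warp_roundtrip_inverse(self, rng):
        img = make_smooth_sample(rng, shape=(128, 128)).truth_phase
        tr = ChannelTransform((3.0, -2.0), 1.0, 1.01)
        back = warp_channel(warp_channel(img, tr), tr.inverse())
        inner = (slice(16, -16), slice(16, -16))
        # two bilinear resamplings leave only interpolation error
        np.testing.assert_allclose(back[inner], img[inner], atol=0.025 * np.ptp(img))

    def test_noise_monotonicity_in_phase_rms(self, rng):
        """More read noise cannot improve recovered-phase RMS (in expectation)."""
        sample = make_smooth_sample(rng, shape=(64, 64), amplitude=1.0)
        cfg = OpticalConfig(shape=(64, 64))
        h = closed_form_intensities(sample, cfg)
        truth = np.angle(np.exp(1j * sample.truth_phase))

        def mean_rms(sigma):
            errs = []
            for seed in range(8):
                noisy = corrupt(h, NoiseModel(shot_noise=False, read_noise_sigma=sigma, seed=seed), None)
                rec = wrapped_phase(noisy).values
                errs.append(np.sqrt(np.mean(np.angle(np.exp(1j * (rec - truth))) ** 2)))
            return np.mean(errs)

        assert mean_rms(2.0) <= mean_rms(20.0)
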