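import numpy as np
import pytest

import synthlung as sl
from synthlung.config import SignalConfig, Tissue, default_class_params
from synthlung.quantify import (
    FunctionalMap,
    _magnitude_mean,
    cardiac_waveform,
    chi_mean_factor,
    compute_jvent,
    compute_qa,
    compute_rvent,
    correct_magnitude_bias,
    correct_noise_floor_frames,
    estimate_background_sigma,
    estimate_cardiac_period,
    guided_filter,
    highpass_filter,
    remove_cardiac_component,
)
from synthlung.signals import add_coil_noise, class_signal

PARAMS = default_class_params(SignalConfig(), e_target=0.25)
DT = 0.192


def roi_like(shape):
    return np.ones(shape, dtype=bool)


class TestRVent:
    def test_recovers_quarter_expansion_from_state_signals(self):
        insp = np.full((4, 4), 16.0)
        exp_ = np.full((4, 4), 20.0)
        fmap = compute_rvent(insp, exp_, exp_, roi_like((4, 4)))
        np.testing.assert_allclose(fmap.values, 0.25)

    def test_no_signal_change_means_no_ventilation(self):
        img = np.full((4, 4), 12.0)
        np.testing.assert_allclose(
            compute_rvent(img, img, img, roi_like((4, 4))).values, 0.0
        )

    def test_linear_in_registration_signal(self):
        insp = np.full((2, 2), 16.0)
        exp_ = np.full((2, 2), 20.0)
        full = compute_rvent(insp, exp_, exp_, roi_like((2, 2))).values
        half = compute_rvent(insp, exp_, exp_ / 2, roi_like((2, 2))).values
        np.testing.assert_allclose(half, full / 2)

    def test_non_positive_signals_masked_and_counted(self):
        insp = np.full((3, 3), 16.0)
        insp[0, 0] = -1.0
        exp_ = np.full((3, 3), 20.0)
        fmap = compute_rvent(insp, exp_, exp_, roi_like((3, 3)))
        assert fmap.invalid == 1
        assert np.isnan(fmap.values[0, 0])


class TestJVent:
    def test_zero_field(self):
        fmap = compute_jvent(np.zeros((8, 8)), roi_like((8, 8)))
        np.testing.assert_allclose(fmap.values, 0.0)

    def test_uniform_stretch(self):
        y = np.arange(16, dtype=float)
        field = np.tile((0.25 * y)[:, None], (1, 6))
        fmap = compute_jvent(field, roi_like((16, 6)))
        np.testing.assert_allclose(fmap.values, 0.25)


class TestQA:
    def _single_voxel_frames(self, signal):
        return np.asarray(signal, dtype=float)[:, None, None]

    def test_no_cardiac_amplitude_gives_near_zero_qa(self):
        t = np.arange(250) * DT
        s = class_signal(PARAMS[Tissue.VV_QD], t)  # ventilation only
        roi = np.ones((1, 1), dtype=bool)
        fmap = compute_qa(
            self._single_voxel_frames(s), roi, DT, cardiac_period=0.8
        )
        # residual = spectral leakage of the truncated (non-periodic)
        # respiratory waveform into the cardiac band; well below 5% of the
        # default cardiac amplitude
        assert abs(fmap.values[0, 0]) < 0.05 * PARAMS[Tissue.VV_QV].a_q

    def test_single_voxel_matches_brute_force_oracle(self):
        t = np.arange(250) * DT
        s = class_signal(PARAMS[Tissue.VV_QV], t)
        roi = np.ones((1, 1), dtype=bool)
        fmap = compute_qa(self._single_voxel_frames(s), roi, DT)

        # independent oracle: hard spectral cutoff, group by the 25 distinct
        # cardiac phases of the sampling grid, pick extremal phase means
        spec = np.fft.rfft(s)
        freqs = np.fft.rfftfreq(len(s), DT)
        spec[freqs < 0.9] = 0.0
        filtered = np.fft.irfft(spec, n=len(s))
        phase_idx = np.round((t % 0.8) / 0.8 * 25).astype(int) % 25
        means = np.array([filtered[phase_idx == p].mean() for p in range(25)])
        expected = means.max() - means.min()
        assert fmap.values[0, 0] == pytest.approx(expected, rel=1e-6)
        # the phase-sampled peak-to-peak stays near the raw amplitude
        # (small deviations from respiratory spectral leakage)
        a_q = PARAMS[Tissue.VV_QV].a_q
        assert 0.8 * a_q < expected < 1.05 * a_q

    def test_estimated_cardiac_period_matches_model(self):
        t = np.arange(250) * DT
        s = class_signal(PARAMS[Tissue.VV_QV], t)
        period = estimate_cardiac_period(s, DT)
        assert period == pytest.approx(0.8, rel=0.01)

    def test_single_frame_mode_via_phase_bins_one(self):
        t = np.arange(250) * DT
        s = class_signal(PARAMS[Tissue.VV_QV], t)
        roi = np.ones((1, 1), dtype=bool)
        fmap = compute_qa(
            self._single_voxel_frames(s), roi, DT, cardiac_period=0.8, phase_bins=1
        )
        filtered = highpass_filter(s[:, None], DT)[:, 0]
        assert fmap.values[0, 0] == pytest.approx(filtered.max() - filtered.min())

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            highpass_filter(np.zeros((10, 1)), DT)


class TestCardiacSeparation:
    def test_removal_recovers_pure_ventilation_states(self):
        t = np.arange(250) * DT
        p = PARAMS[Tissue.VV_QV]
        s = class_signal(p, t)
        frames = np.tile(s[:, None, None], (1, 4, 4))
        roi = np.ones((4, 4), dtype=bool)
        template = cardiac_waveform(frames, roi, DT)
        cleaned = remove_cardiac_component(frames, template)
        vent_only = class_signal(
            sl.ClassSignalParams(s0=p.s0, a_v=p.a_v, tau_v=p.tau_v, n=p.n), t
        )
        # bounded by the respiratory leakage through the cardiac band
        assert np.abs(cleaned[:, 0, 0] - vent_only).max() < 0.3

    def test_voxels_without_cardiac_signal_unchanged(self):
        t = np.arange(250) * DT
        cardiac = class_signal(PARAMS[Tissue.VV_QV], t)
        flat = np.full_like(t, 8.0)
        frames = np.stack([cardiac, flat], axis=1)[:, :, None]
        roi = np.ones((2, 1), dtype=bool)
        template = cardiac_waveform(frames, roi, DT)
        cleaned = remove_cardiac_component(frames, template)
        np.testing.assert_allclose(cleaned[:, 1, 0], 8.0, atol=1e-6)


class TestNoiseFloor:
    def test_bias_curve_roundtrip(self):
        sigma, k = 3.0, 4
        s = np.linspace(0.0, 50.0, 40)
        observed = _magnitude_mean(s, sigma, k)
        np.testing.assert_allclose(
            correct_magnitude_bias(observed, sigma, k), s, atol=0.05
        )

    def test_background_sigma_estimate(self, rng):
        sigma = 2.5
        frames = add_coil_noise(np.zeros((40, 64, 64)), sigma, 4, rng)
        bg = np.ones((64, 64), dtype=bool)
        assert estimate_background_sigma(frames, bg) == pytest.approx(sigma, rel=0.01)

    def test_per_frame_correction_restores_signal_differences(self, rng):
        sigma = 4.0
        lo = add_coil_noise(np.full((2000, 8, 8), 16.0), sigma, 4, rng)
        hi = add_coil_noise(np.full((2000, 8, 8), 20.0), sigma, 4, rng)
        raw_diff = hi.mean() - lo.mean()
        corr_diff = (
            correct_noise_floor_frames(hi, sigma).mean()
            - correct_noise_floor_frames(lo, sigma).mean()
        )
        assert raw_diff < 3.8  # magnitude bias compresses the true 4.0
        assert corr_diff == pytest.approx(4.0, abs=0.1)

    def test_zero_sigma_is_identity(self):
        x = np.linspace(1, 5, 10)
        np.testing.assert_array_equal(correct_magnitude_bias(x, 0.0), x)
        np.testing.assert_array_equal(correct_noise_floor_frames(x, 0.0), x)

    def test_chi_mean_factor_for_four_channels(self):
        import math

        expected = math.sqrt(2) * math.gamma(2.5) / math.gamma(2.0)
        assert chi_mean_factor(4) == pytest.approx(expected, rel=1e-9)


class TestGuidedFilter:
    def test_constant_input_is_fixed_point(self):
        const = np.full((20, 20), 3.0)
        guide = np.random.default_rng(0).normal(size=(20, 20))
        np.testing.assert_allclose(guided_filter(const, guide), 3.0, atol=1e-9)

    def test_large_eps_approaches_box_mean(self):
        from scipy.ndimage import uniform_filter

        rng = np.random.default_rng(1)
        p = rng.normal(size=(30, 30))
        guide = rng.normal(size=(30, 30))
        out = guided_filter(p, guide, radius=3, eps=1e9)
        box = uniform_filter(p, size=7, mode="nearest")
        # double box filtering of b: compare against the twice-smoothed map
        np.testing.assert_allclose(out, uniform_filter(box, 7, mode="nearest"), atol=1e-3)

    def test_edges_preserved_better_than_box_filter(self):
        from scipy.ndimage import uniform_filter

        step = np.zeros((24, 24))
        step[:, 12:] = 1.0
        noisy = step + np.random.default_rng(2).normal(0, 0.05, step.shape)
        out = guided_filter(noisy, step, radius=3, eps=1e-4)
        box = uniform_filter(noisy, size=7, mode="nearest")
        edge_grad = lambda img: np.abs(np.diff(img, axis=1))[:, 10:14].max()
        assert edge_grad(out) > 2 * edge_grad(box)

    def test_non_positive_radius_rejected(self):
        with pytest.raises(ValueError):
            guided_filter(np.zeros((4, 4)), np.zeros((4, 4)), radius=0)
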