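"""Clutter recursion, variance localization and wavelet denoising.

The recursion tests unroll the filter by hand; the wavelet filter bank is
checked against an independent circular convolution/decimation oracle.
"""

import numpy as np
import pytest
import pywt
from hypothesis import given, settings, strategies as st

from sbda import (
    ClutterConfig,
    DenoiseConfig,
    RadarMatrix,
    SceneConfig,
    ValidationError,
    dwt_denoise,
    robust_variance_localize,
    simulate_scene,
    soft_threshold,
    suppress_clutter,
    variance_localize,
)


def _matrix(samples):
    return RadarMatrix(samples=np.asarray(samples, dtype=float), slow_period_s=0.05)


class TestClutterRecursion:
    def test_alpha_one_freezes_clutter_at_first_frame(self, rng):
        x = rng.normal(size=(50, 4))
        residual, clutter = suppress_clutter(_matrix(x), ClutterConfig(alpha=1.0))
        assert np.allclose(clutter.samples, x[0][None, :])
        np.testing.assert_allclose(residual.samples, x - x[0][None, :], atol=1e-14)

    def test_alpha_zero_tracks_raw_echo_exactly(self, rng):
        x = rng.normal(size=(50, 4))
        residual, clutter = suppress_clutter(_matrix(x), ClutterConfig(alpha=0.0))
        np.testing.assert_allclose(clutter.samples, x, atol=1e-14)
        np.testing.assert_allclose(residual.samples, 0.0, atol=1e-14)

    @pytest.mark.parametrize("alpha", [0.0, 0.3, 0.9, 1.0])
    def test_constant_input_gives_zero_residual(self, alpha):
        x = np.full((40, 3), 2.7)
        residual, _ = suppress_clutter(_matrix(x), ClutterConfig(alpha=alpha))
        np.testing.assert_allclose(residual.samples, 0.0, atol=1e-12)

    def test_step_response_matches_hand_unrolled_recursion(self):
        """Unit step at frame 5 under alpha=0.9: the residual decays as
        0.9^(t-4) (1-based frames), i.e. geometrically from 0.9 one frame
        after the step."""
        alpha = 0.9
        n = 40
        x = np.zeros((n, 1))
        x[5:, 0] = 1.0
        residual, clutter = suppress_clutter(_matrix(x), ClutterConfig(alpha=alpha))

        # independent oracle: explicit loop
        c = np.zeros(n)
        c[0] = x[0, 0]
        for t in range(1, n):
            c[t] = alpha * c[t - 1] + (1 - alpha) * x[t, 0]
        np.testing.assert_allclose(clutter.samples[:, 0], c, atol=1e-12)
        np.testing.assert_allclose(residual.samples[:, 0], x[:, 0] - c, atol=1e-12)

        # closed form after the step: residual = alpha^(t - t0 + 1)
        t = np.arange(5, n)
        np.testing.assert_allclose(
            residual.samples[5:, 0], alpha ** (t - 5 + 1), atol=1e-12
        )
        np.testing.assert_allclose(
            clutter.samples[5:, 0], 1 - alpha ** (t - 5 + 1), atol=1e-12
        )

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.floats(0.05, 0.95))
    def test_recursion_is_linear_under_zero_initialization(self, seed, alpha):
        rng = np.random.default_rng(seed)
        x1 = rng.normal(size=(30, 2))
        x2 = rng.normal(size=(30, 2))
        cfg = ClutterConfig(alpha=alpha, initial_clutter_policy="zeros")
        r12, _ = suppress_clutter(_matrix(x1 + x2), cfg)
        r1, _ = suppress_clutter(_matrix(x1), cfg)
        r2, _ = suppress_clutter(_matrix(x2), cfg)
        np.testing.assert_allclose(r12.samples, r1.samples + r2.samples, atol=1e-10)

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            suppress_clutter(_matrix(np.ones((3, 3))), ClutterConfig(alpha=1.5))


class TestVarianceLocalize:
    def test_noiseless_scene_selects_subject_bin(self, clean_scene):
        _, matrix, truth = clean_scene
        residual, _ = suppress_clutter(matrix)
        profile = variance_localize(residual)
        assert not profile.degenerate
        assert profile.selected_bin == truth.subject_bin

    def test_constant_matrix_flagged_degenerate(self):
        profile = variance_localize(_matrix(np.full((20, 5), 3.0)))
        assert profile.degenerate
        assert profile.selected_bin is None

    def test_two_sinusoids_larger_amplitude_wins(self):
        t = np.arange(200) * 0.05
        x = np.zeros((200, 10))
        x[:, 3] = 1.0 * np.sin(2 * np.pi * 0.25 * t)
        x[:, 7] = 2.0 * np.sin(2 * np.pi * 0.4 * t)
        profile = variance_localize(_matrix(x))
        assert profile.selected_bin == 7
        # brute-force two-pass variance oracle, every bin
        brute = np.array(
            [np.sum((x[:, j] - x[:, j].mean()) ** 2) / (x.shape[0] - 1) for j in range(10)]
        )
        np.testing.assert_allclose(profile.variances, brute, rtol=1e-12)

    def test_tie_breaks_to_lowest_bin(self):
        t = np.arange(100) * 0.05
        x = np.zeros((100, 6))
        x[:, 2] = np.sin(2 * np.pi * 0.3 * t)
        x[:, 4] = np.sin(2 * np.pi * 0.3 * t)
        assert variance_localize(_matrix(x)).selected_bin == 2

    def test_single_frame_rejected(self):
        with pytest.raises(ValidationError):
            variance_localize(_matrix(np.ones((1, 4))))

    def test_robust_localization_survives_movement_epochs(self):
        config = SceneConfig(
            duration_s=180, subject_bin=21, breathing_rate_bpm=14.0,
            noise_sigma=0.2, movement_epochs=((0.0, 30.0, 5.0), (120.0, 150.0, 5.0)),
            rng_seed=17,
        )
        matrix, truth = simulate_scene(config)
        residual, _ = suppress_clutter(matrix)
        profile = robust_variance_localize(residual)
        assert profile.selected_bin == truth.subject_bin


# ---------------------------------------------------------------------------
# wavelet denoising
# ---------------------------------------------------------------------------


def _oracle_dwt_periodized(x, wavelet_name):
    """Single-level DWT by direct circular convolution and dyadic
    decimation, independent of the library transform."""
    w = pywt.Wavelet(wavelet_name)
    lo, hi = np.array(w.dec_lo), np.array(w.dec_hi)
    n, taps = len(x), len(lo)

    def conv(filt):
        return np.array(
            [sum(filt[k] * x[(m - k) % n] for k in range(taps)) for m in range(n)]
        )

    idx = (taps // 2 + 2 * np.arange(n // 2)) % n
    return conv(lo)[idx], conv(hi)[idx]


class TestWavelet:
    def test_zero_threshold_is_identity(self, rng):
        signal = rng.normal(size=1200)
        out = dwt_denoise(signal, DenoiseConfig(threshold_scale=0.0))
        assert np.linalg.norm(out - signal) / np.linalg.norm(signal) < 1e-8

    def test_zero_input_gives_zero_output(self):
        out = dwt_denoise(np.zeros(256))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_denoising_beats_identity_on_noisy_sinusoid(self):
        rng = np.random.default_rng(7)
        t = np.arange(1200) / 20.0
        clean = np.sin(2 * np.pi * 0.25 * t)
        noisy = clean + rng.normal(0, 0.3, t.size)
        out = dwt_denoise(noisy)
        rmse_in = np.sqrt(np.mean((noisy - clean) ** 2))
        rmse_out = np.sqrt(np.mean((out - clean) ** 2))
        assert rmse_out < rmse_in

    def test_too_short_signal_error_names_minimum_length(self):
        with pytest.raises(ValidationError, match="32"):
            dwt_denoise(np.ones(20), DenoiseConfig(levels=5))

    def test_output_length_equals_input_length(self, rng):
        for n in (100, 127, 256, 1000):
            assert dwt_denoise(rng.normal(size=n)).size == n

    def test_filter_bank_matches_convolution_decimation_oracle(self, rng):
        """The analysis filter bank agrees with a direct circular
        convolution + decimation implementation on length-64 signals,
        cascaded over three levels."""
        for wavelet_name in ("db2", "db4"):
            x = rng.normal(size=64)
            approx = x
            coeffs = pywt.wavedec(x, wavelet_name, level=3, mode="periodization")
            oracle_details = []
            for _ in range(3):
                approx, detail = _oracle_dwt_periodized(approx, wavelet_name)
                oracle_details.append(detail)
            np.testing.assert_allclose(coeffs[0], approx, atol=1e-10)
            for lib_detail, oracle_detail in zip(coeffs[:0:-1], oracle_details):
                np.testing.assert_allclose(lib_detail, oracle_detail, atol=1e-10)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.lists(st.floats(-100, 100), min_size=1, max_size=50),
        st.floats(0, 50),
    )
    def test_soft_threshold_is_a_contraction(self, values, threshold):
        coeffs = np.array(values)
        out = soft_threshold(coeffs, threshold)
        assert np.all(np.abs(out) <= np.abs(coeffs) + 1e-15)
        assert np.all(np.abs(out[np.abs(coeffs) <= threshold]) == 0.0)
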