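"""Simulator contracts: scene construction, determinism, ground truth, and
the matrix file dialects."""

import numpy as np
import pytest

from sbda import (
    ParseError,
    RadarMatrix,
    SceneConfig,
    ValidationError,
    load_scene_config,
    read_matrix,
    simulate_scene,
    write_matrix,
)


class TestSimulateScene:
    def test_static_scene_is_pure_dc_in_slow_time(self):
        config = SceneConfig(
            duration_s=10, breathing_amp=0.0, noise_sigma=0.0, clutter_profile=2.5
        )
        matrix, _ = simulate_scene(config)
        assert np.all(matrix.samples == matrix.samples[0])
        assert np.allclose(matrix.samples, 2.5)

    def test_noiseless_subject_bin_is_exact_sinusoid(self):
        config = SceneConfig(
            duration_s=60, breathing_rate_bpm=15.0, subject_bin=10,
            noise_sigma=0.0, clutter_profile=1.0, rng_seed=3,
        )
        matrix, _ = simulate_scene(config)
        t = matrix.times_s
        expected = 1.0 + np.sin(2 * np.pi * 0.25 * t)
        np.testing.assert_allclose(matrix.samples[:, 10], expected, atol=1e-12)

    def test_same_seed_bit_identical(self):
        config = SceneConfig(
            duration_s=30, noise_sigma=0.3,
            movement_epochs=((5.0, 10.0, 2.0),), rng_seed=7,
        )
        m1, _ = simulate_scene(config)
        m2, _ = simulate_scene(config)
        assert np.array_equal(m1.samples, m2.samples)

    def test_subject_bin_variance_matches_closed_form(self):
        """Sample variance of sinusoid amp A plus noise sigma is
        A^2/2 + sigma^2; checked as a mean over 50 seeds."""
        amp, sigma = 1.0, 0.05
        variances = []
        for seed in range(50):
            config = SceneConfig(
                duration_s=60, breathing_rate_bpm=15.0, breathing_amp=amp,
                noise_sigma=sigma, subject_bin=10, rng_seed=seed,
            )
            matrix, _ = simulate_scene(config)
            variances.append(matrix.samples[:, 10].var(ddof=1))
        expected = 0.5 * amp**2 + sigma**2
        assert abs(np.mean(variances) - expected) < 0.1 * expected

    def test_noiseless_variance_confined_to_subject_neighbourhood(self):
        config = SceneConfig(duration_s=30, subject_bin=10, noise_sigma=0.0)
        matrix, _ = simulate_scene(config)
        var = matrix.samples.var(axis=0)
        inside = np.arange(8, 13)  # triangular kernel spans +/-2 bins
        outside = np.setdiff1d(np.arange(matrix.n_bins), inside)
        assert np.all(var[outside] == 0.0)
        assert np.all(var[inside] > 0.0)

    def test_noiseless_spectrum_peaks_at_breathing_frequency(self):
        config = SceneConfig(duration_s=60, breathing_rate_bpm=18.0, noise_sigma=0.0)
        matrix, truth = simulate_scene(config)
        x = matrix.samples[:, truth.subject_bin]
        x = x - x.mean()
        mag = np.abs(np.fft.rfft(x))
        freqs = np.fft.rfftfreq(x.size, matrix.slow_period_s)
        peak = freqs[np.argmax(mag)]
        assert abs(peak - 18.0 / 60.0) <= freqs[1]

    def test_movement_epochs_set_mask_and_truth_mirrors_config(self):
        config = SceneConfig(
            duration_s=60, subject_bin=7, breathing_rate_bpm=12.0,
            movement_epochs=((10.0, 20.0, 3.0),), rng_seed=1,
        )
        matrix, truth = simulate_scene(config)
        assert truth.breathing_rate_bpm == 12.0
        assert truth.subject_bin == 7
        assert truth.movement_mask.shape == (matrix.n_frames,)
        assert truth.movement_mask[200:400].all()
        assert not truth.movement_mask[:200].any()
        assert not truth.movement_mask[400:].any()

    def test_position_shift_changes_post_epoch_profile(self):
        base = dict(
            duration_s=90, noise_sigma=0.0, breathing_amp=0.0,
            movement_epochs=((30.0, 60.0, 3.0),), rng_seed=5,
        )
        shifted, _ = simulate_scene(SceneConfig(position_shift_sigma=1.0, **base))
        unshifted, _ = simulate_scene(SceneConfig(position_shift_sigma=0.0, **base))
        # before the epoch both are the static profile
        assert np.array_equal(shifted.samples[:600], unshifted.samples[:600])
        # after it, the shifted scene sits at a new static level
        tail = shifted.samples[1200:]
        assert np.all(tail == tail[0])
        assert not np.allclose(tail[0], shifted.samples[0])

    @pytest.mark.parametrize(
        "bad",
        [
            dict(breathing_rate_bpm=0.0),
            dict(breathing_rate_bpm=-5.0),
            dict(breathing_rate_bpm=700.0),  # 11.7 Hz > Nyquist at 20 fps
            dict(subject_bin=40),
            dict(subject_bin=-1),
            dict(noise_sigma=-0.1),
            dict(movement_epochs=((50.0, 70.0, 1.0),)),  # beyond duration
            dict(movement_epochs=((10.0, 5.0, 1.0),)),  # reversed
            dict(duration_s=-1.0),
        ],
    )
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValidationError):
            simulate_scene(SceneConfig(duration_s=bad.pop("duration_s", 60.0), **bad))


class TestMatrixIO:
    @pytest.mark.parametrize("fmt,suffix", [("text", ".csv"), ("binary", ".bin")])
    def test_round_trip(self, tmp_path, fmt, suffix):
        config = SceneConfig(duration_s=5, noise_sigma=0.1, rng_seed=2)
        matrix, _ = simulate_scene(config)
        path = tmp_path / f"m{suffix}"
        write_matrix(matrix, path, fmt=fmt)
        back = read_matrix(path)
        np.testing.assert_array_equal(back.samples, matrix.samples)
        assert back.slow_period_s == matrix.slow_period_s
        assert back.fast_period == matrix.fast_period

    def test_one_by_one_matrix_round_trips(self, tmp_path):
        matrix = RadarMatrix(samples=np.array([[3.25]]), slow_period_s=0.05)
        for name, fmt in [("a.csv", "text"), ("a.bin", "binary")]:
            path = tmp_path / name
            write_matrix(matrix, path, fmt=fmt)
            back = read_matrix(path)
            assert back.samples.shape == (1, 1)
            assert back.samples[0, 0] == 3.25

    def test_t0_preserved(self, tmp_path):
        matrix = RadarMatrix(
            samples=np.ones((2, 2)), slow_period_s=0.05, t0=1234.5
        )
        for name in ("b.csv", "b.bin"):
            path = tmp_path / name
            write_matrix(matrix, path)
            assert read_matrix(path).t0 == 1234.5

    def test_ragged_row_names_the_row(self, tmp_path):
        path = tmp_path / "ragged.csv"
        path.write_text("# slow_period_s=0.05\n1.0,2.0\n1.0,2.0,3.0\n")
        with pytest.raises(ParseError, match="3"):
            read_matrix(path)

    def test_non_numeric_cell_names_line_and_field(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("# slow_period_s=0.05\n1.0,2.0\n1.0,oops\n")
        with pytest.raises(ParseError, match="field 2"):
            read_matrix(path)

    def test_missing_header_rejected(self, tmp_path):
        path = tmp_path / "nohdr.csv"
        path.write_text("1.0,2.0\n")
        with pytest.raises(ParseError, match="slow_period_s"):
            read_matrix(path)

    def test_truncated_binary_rejected(self, tmp_path):
        matrix = RadarMatrix(samples=np.ones((4, 3)), slow_period_s=0.05)
        path = tmp_path / "t.bin"
        write_matrix(matrix, path, fmt="binary")
        path.write_bytes(path.read_bytes()[:-8])
        with pytest.raises(ParseError, match="size mismatch"):
            read_matrix(path)


def test_scene_config_from_yaml(tmp_path):
    path = tmp_path / "scene.yaml"
    path.write_text(
        "duration_s: 45\n"
        "breathing_rate_bpm: 17.5\n"
        "subject_bin: 4\n"
        "noise_sigma: 0.1\n"
        "movement_epochs:\n"
        "  - [5.0, 10.0, 2.0]\n"
        "rng_seed: 9\n"
    )
    config = load_scene_config(path)
    assert config.breathing_rate_bpm == 17.5
    assert config.movement_epochs == ((5.0, 10.0, 2.0),)
    with pytest.raises(ParseError, match="unknown"):
        bad = tmp_path / "bad.yaml"
        bad.write_text("durationn_s: 45\n")
        load_scene_config(bad)
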