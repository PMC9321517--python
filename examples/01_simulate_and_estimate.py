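"""Simulate a quiet night of breathing and recover the rate end to end.

Builds a 2-minute radar scene with a subject breathing at 16.5 breaths/min
behind static clutter and mild noise, runs the full pipeline, and prints
the recovered rate next to the ground truth.
"""

from sbda import PipelineConfig, SceneConfig, run_sbda, simulate_scene

scene = SceneConfig(
    duration_s=120.0,
    breathing_rate_bpm=16.5,
    subject_bin=12,
    noise_sigma=0.2,
    rng_seed=42,
)
matrix, truth = simulate_scene(scene)
estimate, report = run_sbda(matrix, PipelineConfig(rng_seed=0))

print(f"ground truth : {truth.breathing_rate_bpm:.2f} breaths/min at bin {truth.subject_bin}")
print(f"estimate     : {estimate.rate_bpm:.2f} breaths/min (peak {estimate.peak_freq_hz:.4f} Hz)")
print(f"localized bin: {report.selected_bin}; kept {report.n_kept_windows}/{report.n_windows} windows")
print(f"selected IMFs: {list(report.selected_imfs)} with band-energy ratios "
      f"{[round(report.imf_ratios[i], 3) for i in report.selected_imfs]}")
# The estimate should sit within one FFT bin (~0.3 bpm) of the truth; the
# selected IMFs are the oscillatory modes whose energy concentrates in the
# respiration band.
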