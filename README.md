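# sbda — sleep breathing detection from UWB radar matrices

Non-contact breathing-rate monitoring for sleep: an impulse-radio
ultra-wideband (IR-UWB) radar records, at 20 frames/s, the reflected
amplitude per range cell; chest-wall motion modulates the reflection at
the sleeper's range bin, while the room contributes static clutter and
body movements inject large aperiodic artifacts.  This package implements
the full extraction pipeline for such slow-time × fast-time matrices,
aimed at researchers in contactless vital-sign monitoring who need a
reproducible, testable reference implementation with a ground-truthed
scene simulator.

## The method

Given a radar matrix `R ∈ ℝ^{M×N}` (M slow-time frames, N fast-time bins):

1. **Clutter suppression** — recursive background estimate per bin,
   `C(t,τ) = α·C(t−1,τ) + (1−α)·x(t,τ)`, α ∈ [0,1] (default 0.9);
   the residual `x − C` removes the static room echo.
2. **Subject localization** — the breathing bin maximizes slow-time
   variance; the half-peak width of the variance curve is preserved and
   averaged into one slow-time series (the pipeline uses a
   movement-robust median-across-windows variant).
3. **Wavelet denoising** — 5-level Daubechies DWT, soft thresholding of
   detail coefficients at a robust universal threshold.
4. **Motion gating** — each 30 s window is fitted with
   `y = Σᵢ aᵢ sin(bᵢt + cᵢ)` and scored with
   `R² = 1 − SS_res/SS_tot`; windows with `R² ≥ 0.5` are kept, the rest
   are rejected as body movement.
5. **EEMD** — ensemble empirical mode decomposition (from-scratch
   cubic-spline sifting, 100 noise trials at 0.2·σ) splits the kept
   signal into intrinsic mode functions; IMFs whose respiration-band
   energy fraction `E_rj/E_j ≥ δ_r = 0.5` are summed into the breathing
   signal.
6. **Rate** — the strongest in-band peak of the Hann-tapered, zero-padded
   FFT gives the rate in breaths/min (BPM = 60·f_peak).

Two ungated literature baselines (autocorrelation + FFT and mean
subtraction + FFT), percentage-error and Bland–Altman agreement
statistics, and a synthetic radar-scene generator with movement epochs
and ground truth complete the package.  See `docs/methods.md` for the
full model and conventions.

## Worked example

```python
from sbda import PipelineConfig, SceneConfig, run_sbda, simulate_scene

scene = SceneConfig(duration_s=120.0, breathing_rate_bpm=16.5,
                    subject_bin=12, noise_sigma=0.2, rng_seed=42)
matrix, truth = simulate_scene(scene)
estimate, report = run_sbda(matrix, PipelineConfig(rng_seed=0))
print(estimate.rate_bpm, report.selected_bin, report.n_kept_windows)
```

prints (see `examples/01_simulate_and_estimate.py`):

```
ground truth : 16.50 breaths/min at bin 12
estimate     : 16.41 breaths/min (peak 0.2734 Hz)
localized bin: 12; kept 4/4 windows
selected IMFs: [2, 3, 4] with band-energy ratios [0.865, 0.99, 0.522]
```

The estimate lands within one FFT bin (~0.3 bpm) of the truth; the
selected IMFs are the modes whose spectral energy concentrates in the
respiration band.  On a cohort with movement epochs
(`examples/04_compare_methods.py`) the gated pipeline stays near the FFT
resolution while the ungated baselines are derailed by movement and
posture changes:

```
        method  mean % error  bias (bpm)  LoA width
          sbda          0.76       0.019      0.548
  autocorr_fft         35.80       4.670     25.870
   meansub_fft         96.40       6.244     63.418
```

The other example scripts demonstrate movement gating
(`02_movement_gating.py`) and the decomposition itself
(`03_decompose_breathing.py`).

## Command line

A thin CLI mirrors the stages:

```bash
sbda simulate --duration-s 120 --bpm 15 scene.csv   # write a synthetic matrix
sbda run scene.csv                                  # full pipeline → BPM
sbda denoise scene.csv series.csv                   # localized denoised series
sbda gate scene.csv                                 # per-window R² table
sbda decompose scene.csv                            # IMF energy-ratio table
sbda evaluate pairs.csv                             # Bland–Altman report
```

Matrix files are either commented-header CSV (`# slow_period_s=0.05`
header lines, one frame per row) or a little-endian binary dialect
(magic `SBDM`); both are read transparently.

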