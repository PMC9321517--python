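# Methods

This note documents the signal model, the algorithmic choices and the
numerical conventions of the package, and what the synthetic validation
does and does not demonstrate.

## Signal model

An impulse-radio UWB radar pointed at a sleeping person returns, at a slow
time rate of 20 frames/s, an amplitude per fast-time (range) bin.  The
package works on the resulting M x N slow-time x fast-time matrix:

* **static clutter** — every static reflector contributes a constant
  amplitude per bin, a DC term along slow time;
* **breathing** — chest-wall displacement modulates the reflection
  amplitude at the subject's range bin quasi-sinusoidally at the breathing
  frequency (0.1–0.8 Hz covers 6–48 breaths/min); the pulse illuminates
  several range cells, so the modulation leaks into neighbouring bins;
* **body movement** — gross movements (position shifts, limb activity)
  produce large aperiodic excursions across bins, tens of times the chest
  excursion;
* **receiver noise** — additive white Gaussian.

Fast time is treated as unitless bins throughout: rate extraction never
needs the bin-to-metre conversion.

## The pipeline

1. **Clutter suppression.** Exponential recursion
   `C(t) = alpha*C(t-1) + (1-alpha)*x(t)` per bin, residual `x - C`.
   `alpha` (default 0.9, i.e. a ~0.5 s time constant at 20 fps) trades
   clutter adaptation speed against breathing attenuation: `alpha = 1`
   freezes the estimate, `alpha = 0` yields a zero residual.  The clutter
   estimate is seeded with the first received frame (a "zeros" policy is
   available); the recursion is linear in the input under zero seeding.

2. **Subject localization.** Breathing concentrates slow-time variance at
   the subject's bin.  `variance_localize` takes the per-bin sample
   variance, selects the argmax (ties to the lowest bin) and preserves the
   contiguous half-peak interval around it.  Two conventions matter:

   * the half-peak rule is applied to the variance *excess* over the
     cross-bin median, because noise and whole-body movement raise every
     bin by a common floor and the subject's peak rides on top of it;
   * the pipeline itself uses `robust_variance_localize`, which takes the
     per-bin **median of per-window variances** (window length = the gate
     window).  Full-record variance assumes a mostly quiet record; when
     movement occupies a substantial fraction of it, slow covariance
     fluctuations between the shared movement excursion and per-bin noise
     exceed the breathing excess and the argmax becomes unreliable.  The
     median across windows lets quiet windows outvote movement windows.
     The plain full-record localizer remains exported and is what the
     mean-subtraction baseline uses — its fragility under movement is part
     of the comparison.

   The slow-time series passed downstream is the arithmetic mean over the
   preserved bins (configurable to the single selected bin).

3. **Wavelet denoising.** 5-level Daubechies (default `db4`) DWT with
   symmetric extension; soft thresholding of all detail coefficients at
   the robust universal threshold
   `lambda = scale * median(|D_1|)/0.6745 * sqrt(2 ln L)`, with the noise
   scale taken from the finest detail band only — respiration lives far
   below Nyquist, so that band is essentially pure noise, whereas
   per-level scale estimates would shrink the signal-bearing coarse
   levels.  `scale = 0` disables shrinkage and the transform round-trips
   to 1e-8 relative.  Signals must be at least `2^levels` samples.

4. **Periodicity gating.** The denoised series is tiled into 30 s windows
   (a standard segment length for respiratory periodicity checks; the
   trailing partial window is dropped).  Each window is fitted with a sine
   series `sum_i a_i sin(b_i t + c_i)` (default one term) by nonlinear
   least squares, multi-started from the three strongest spectral peaks in
   0.05–1 Hz with amplitude/phase solved linearly per start.  The fit is
   scored with `R^2 = 1 - SS_res/SS_tot`; windows with `R^2 >= 0.5`
   (boundary-inclusive) and a converged fit are kept.  Conventions:
   zero-variance windows score 0 (reject-by-default); `R^2` may be
   negative for fits worse than the mean, which falls below any gate in
   [0, 1].  Kept windows are concatenated — zero-filling gaps would
   manufacture edge modes in the decomposition, while concatenation joins
   contribute only isolated broadband transients.

5. **Ensemble empirical mode decomposition.** EMD extracts intrinsic mode
   functions by cubic-spline envelope sifting (envelopes through the local
   maxima/minima with the two outermost extrema mirrored past each end).
   A sift stops on a Cauchy criterion (normalized squared envelope-mean
   energy < 0.2) combined with the extrema/zero-crossing condition, capped
   at 50 iterations; decomposition stops when the residue has fewer than
   two maxima or minima.  `input = sum(IMFs) + residue` holds to
   floating-point accuracy by construction.  The ensemble variant averages
   the k-th IMF over (default) 100 trials with fresh white noise of
   sigma = 0.2 x the input SD; modes produced by fewer than half the
   trials are dropped, and the residue is defined as input minus the
   summed averaged IMFs so the ensemble decomposition remains an exact
   identity.  With one trial and zero noise the ensemble reduces exactly
   to plain EMD.

6. **IMF selection and rate.** Each IMF is scored by the fraction of its
   spectral energy (one-sided magnitude-squared spectrum, interior bins
   doubled) inside the respiration band; IMFs with ratio >= 0.5 are summed
   into the breathing signal.  Two band presets circulate in the
   literature this implements, 0.2–0.8 Hz (`"method"`, the module default)
   and 0.1–0.35 Hz (`"results"`); they are mutually inconsistent and
   neither covers the full adult range alone, so the end-to-end pipeline
   defaults the selection band to the rate search band (0.1–0.8 Hz,
   6–48 bpm) — a legitimate rate anywhere in the searched range must never
   be rejected by the selection stage.  The breathing rate is 60x the
   frequency of the strongest in-band peak of the Hann-tapered,
   zero-padded FFT (padding to >= 0.005 Hz resolution, i.e. 0.3 bpm;
   ties resolve to the lower frequency).  Records shorter than 30 s are
   refused.

### Baselines

Two literature approaches are re-implemented at one-sentence fidelity for
side-by-side comparison; neither gates movement.

* **Autocorrelation + FFT** — each bin's mean-subtracted series is
  band-limited to the search band, and the bin maximizing the
  autocorrelation energy over nonzero lags (up to 10 s) is selected; the
  rate comes from the FFT of that bin's series.  The band-limiting
  reflects that the localization targets breathing periodicity; without
  it, the piecewise-DC residuals left by posture changes dominate the
  autocorrelation energy.
* **Mean subtraction + FFT** — the per-bin slow-time mean is the clutter
  estimate; localization is plain full-record variance argmax; the rate
  comes from the FFT of the selected bin's residual.

### Agreement statistics

Percentage error is `100 |estimate - reference| / reference` (asymmetric
by design: the reference is the denominator).  Bland–Altman agreement
reports per-pair mean and difference, the bias (mean difference) and the
limits of agreement `bias ± 1.96 * SD` with the sample (ddof = 1) SD.

## The synthetic scene generator

`simulate_scene` builds matrices with known ground truth: per-bin constant
clutter, additive sinusoidal breathing (optional second harmonic) leaked
through a triangular kernel over ±2 bins (peak weight 1 at the subject
bin), movement epochs, and white noise.  Movement is shared across all
bins — whole-body motion displaces every reflecting surface coherently —
and each epoch is an equal-power blend of a broadband drift+jerk component
(mean-removed random walk plus white jitter) and a quasi-rhythmic limb
component whose tempo drifts by at least 0.15 Hz across the epoch.  The
blend is deliberate: a pure random walk is spectrally so concentrated that
a single sine explains most of it, which would defeat the very gate the
artifact exercises, while the drifting limb rhythm reproduces the
in-band confusion that breaks ungated FFT pickers.  One-second ramps at
the epoch edges and a ramped-in permanent per-bin clutter shift
(`position_shift_sigma`, default 1.5) model the body settling into a new
posture without injecting artificial steps.

Default study conditions for the cohort driver: 20 scenes of 180 s at
20 fps with 30 range bins, breathing rates uniform in 10–25 bpm with
amplitude 1, noise sigma 0.2, and two 30 s movement epochs per scene of
amplitude 5 (gross movement dominating chest excursion) aligned to gate
windows.

**What passing tests show** — that each stage honours its mathematical
contract (recursion, identities, selection rule), that the gate separates
sinusoidal from aperiodic windows at realistic SNR, and that the full
pipeline recovers known rates and rejects known movement under the scene
model above, ordering the three methods as the clinical comparison found.
**What they do not show** — performance on real radar data: the generator
has no multipath, no harmonically rich real chest waveforms beyond an
optional second harmonic, no heart-rate component, no radar self-motion,
no range migration of the subject across bins, and movement epochs are
aligned to window boundaries.  Real recordings can only be judged with
real references.

## Numerical conventions and degenerate inputs

* Clutter recursion runs as a vectorized IIR filter; tests verify it
  against an explicitly unrolled loop.
* A perfectly static residual (zero variance in every bin) raises a
  degenerate-scene error rather than selecting an arbitrary bin; an empty
  gate result ("no periodic segments") and an empty IMF selection ("no
  respiratory component") are likewise explicit errors naming the stage.
* Monotone signals decompose to zero IMFs with the input as residue.
* The pipeline is deterministic for a fixed seed: the ensemble seed is
  derived from the pipeline seed, and the simulator is bit-reproducible.
* Matrix files: a commented-header CSV text dialect and a little-endian
  binary dialect (magic `SBDM`), both carrying the slow-time period;
  parse errors name the offending line and field.

## Known limitations

* EMD/EEMD have no convergence theory; the stopping parameters are
  standard but heuristic, and are exposed (`SiftStop`).
* The ensemble size (100) dominates runtime; 10–30 trials are usually
  indistinguishable on clean data.
* Localization assumes one subject; two breathing sources would need a
  multi-peak extension of the variance profile.
* Windows are rejected, never corrected: heavy movers yield fewer usable
  segments rather than degraded estimates.
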