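"""Static-clutter suppression, subject localization and wavelet denoising.

In a static bedroom the background echo is a DC component along slow time,
modelled by the exponential recursion

    C(t, tau) = alpha * C(t-1, tau) + (1 - alpha) * x(t, tau)

with suppression parameter alpha in [0, 1]: alpha = 1 freezes the clutter
estimate, alpha = 0 tracks the raw echo exactly (zero residual).  The
subject's range bin carries the breathing energy, so it is located as the
argmax of the per-bin slow-time variance; the half-peak width of the
variance curve is preserved so that neighbouring bins illuminated by the
same pulse can contribute to the slow-time series.  That series is then
denoised with a multi-level Daubechies DWT and soft thresholding of the
detail coefficients (robust MAD universal threshold per level).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.signal import lfilter

from .errors import DegenerateSceneError, ValidationError
from .scene import RadarMatrix

__all__ = [
    "ClutterConfig",
    "VarianceProfile",
    "DenoiseConfig",
    "suppress_clutter",
    "variance_localize",
    "dwt_denoise",
    "soft_threshold",
]


@dataclass(frozen=True)
class ClutterConfig:
    """alpha: clutter memory in [0, 1]; initial_clutter_policy: how C is
    seeded at the first frame ("first-frame" or "zeros")."""

    alpha: float = 0.9
    initial_clutter_policy: str = "first-frame"

    def validate(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError(f"alpha must lie in [0, 1]; got {self.alpha}")
        if self.initial_clutter_policy not in ("first-frame", "zeros"):
            raise ValidationError(
                f"initial_clutter_policy must be 'first-frame' or 'zeros'; "
                f"got {self.initial_clutter_policy!r}"
            )


@dataclass(frozen=True)
class VarianceProfile:
    """Per-bin slow-time variance with the selected subject bin and the
    contiguous half-peak interval around it (inclusive bounds)."""

    variances: np.ndarray
    selected_bin: int | None
    width_lo: int | None
    width_hi: int | None
    degenerate: bool

    @property
    def preserved_bins(self) -> np.ndarray:
        if self.degenerate:
            return np.empty(0, dtype=int)
        return np.arange(self.width_lo, self.width_hi + 1)


@dataclass(frozen=True)
class DenoiseConfig:
    """wavelet_name: Daubechies family member (default db4); levels:
    decomposition depth (default 5); threshold_scale: multiplier on the
    per-level robust universal threshold (0 disables shrinkage)."""

    wavelet_name: str = "db4"
    levels: int = 5
    threshold_mode: str = "soft"
    threshold_scale: float = 1.0

    def validate(self) -> None:
        if self.levels < 1:
            raise ValidationError(f"levels must be >= 1; got {self.levels}")
        if self.threshold_mode != "soft":
            raise ValidationError("only soft thresholding is supported")
        if not (np.isfinite(self.threshold_scale) and self.threshold_scale >= 0):
            raise ValidationError("threshold_scale must be finite and >= 0")
        if not self.wavelet_name.startswith("db"):
            raise ValidationError(
                f"wavelet_name must be a Daubechies identifier (dbN); got {self.wavelet_name!r}"
            )


def suppress_clutter(
    matrix: RadarMatrix, config: ClutterConfig = ClutterConfig()
) -> tuple[RadarMatrix, RadarMatrix]:
    """Run the recursive clutter estimator along slow time, per fast-time bin.

    Returns ``(residual, clutter)`` with the same shape and metadata as the
    input; ``residual = x - C``.  With the default "first-frame" policy the
    clutter estimate is seeded with the first received frame, so the first
    residual frame is exactly zero.
    """
    config.validate()
    x = matrix.samples
    alpha = config.alpha

    if config.initial_clutter_policy == "first-frame":
        c_init = x[0]
    else:
        c_init = np.zeros(x.shape[1])

    if alpha == 1.0:
        # degenerate IIR (b = 0): clutter frozen at its seed
        clutter = np.tile(c_init, (x.shape[0], 1))
    else:
        # C[t] = (1-alpha) x[t] + alpha C[t-1]; zi carries alpha * C[-1]
        zi = (alpha * c_init)[None, :]
        clutter, _ = lfilter([1.0 - alpha], [1.0, -alpha], x, axis=0, zi=zi)

    residual = x - clutter
    make = lambda s: RadarMatrix(
        samples=s,
        slow_period_s=matrix.slow_period_s,
        fast_period=matrix.fast_period,
        t0=matrix.t0,
    )
    return make(residual), make(clutter)


def variance_localize(residual: RadarMatrix) -> VarianceProfile:
    """Locate the subject's range bin as the argmax of per-bin slow-time
    sample variance (ties break to the lowest index) and record the maximal
    contiguous interval around the peak where variance >= half the peak.

    The half-peak rule is applied to the variance *excess* over the
    cross-bin median: receiver noise and whole-body movement raise every
    bin's variance by a common floor, and preserving the width of the curve
    means preserving the peak that rides on that floor, not the floor
    itself.  A perfectly static residual (zero variance everywhere) is
    flagged degenerate with no bin selected.
    """
    if residual.n_frames < 2:
        raise ValidationError("variance localization needs >= 2 slow-time frames")
    variances = residual.samples.var(axis=0, ddof=1)
    return _profile_from_variances(variances)


def _profile_from_variances(variances: np.ndarray) -> VarianceProfile:
    peak = float(variances.max())
    if peak <= 0.0:
        return VarianceProfile(
            variances=variances, selected_bin=None, width_lo=None, width_hi=None,
            degenerate=True,
        )
    sel = int(np.argmax(variances))
    background = float(np.median(variances)) if variances.size > 1 else 0.0
    excess = variances - background
    half = 0.5 * excess[sel]
    lo = sel
    while lo > 0 and excess[lo - 1] >= half:
        lo -= 1
    hi = sel
    while hi < variances.size - 1 and excess[hi + 1] >= half:
        hi += 1
    return VarianceProfile(
        variances=variances, selected_bin=sel, width_lo=lo, width_hi=hi,
        degenerate=False,
    )


def robust_variance_localize(
    residual: RadarMatrix, window_s: float = 30.0
) -> VarianceProfile:
    """Movement-robust subject localization.

    Plain full-record variance assumes a mostly quiet record; a strong
    movement epoch raises every bin's variance and its slow covariance with
    per-bin noise swamps the breathing excess.  Here each bin's variance is
    computed per window and the per-bin *median* across windows is used, so
    movement windows (a minority of the record) are outvoted by quiet ones.
    The argmax / half-peak-width logic is unchanged; with a single window
    this reduces to :func:`variance_localize`.
    """
    if residual.n_frames < 2:
        raise ValidationError("variance localization needs >= 2 slow-time frames")
    wlen = int(round(window_s / residual.slow_period_s))
    n_win = residual.n_frames // max(wlen, 1)
    if wlen < 2 or n_win < 2:
        return variance_localize(residual)
    windows = residual.samples[: n_win * wlen].reshape(n_win, wlen, residual.n_bins)
    per_window = windows.var(axis=1, ddof=1)
    variances = np.median(per_window, axis=0)
    return _profile_from_variances(variances)


def extract_series(
    residual: RadarMatrix, profile: VarianceProfile, mode: str = "mean"
) -> np.ndarray:
    """Slow-time series to denoise: arithmetic mean over the preserved
    half-peak bins (default) or the single selected bin."""
    if profile.degenerate:
        raise DegenerateSceneError("static scene: no subject bin to extract")
    if mode == "mean":
        return residual.samples[:, profile.preserved_bins].mean(axis=1)
    if mode == "single":
        return residual.samples[:, profile.selected_bin].copy()
    raise ValidationError(f"unknown series mode {mode!r}; use 'mean' or 'single'")


def soft_threshold(coeffs: np.ndarray, threshold: float) -> np.ndarray:
    """Soft shrinkage: sign(c) * max(|c| - threshold, 0)."""
    return np.sign(coeffs) * np.maximum(np.abs(coeffs) - threshold, 0.0)


def dwt_denoise(
    signal: np.ndarray,
    config: DenoiseConfig = DenoiseConfig(),
    width_hint: VarianceProfile | None = None,
) -> np.ndarray:
    """Denoise a slow-time series by multi-level Daubechies DWT with soft
    thresholding of the detail coefficients.

    The threshold is the robust universal threshold

        lambda = threshold_scale * median(|D_1|) / 0.6745 * sqrt(2 ln L)

    with D_1 the finest detail band and L the signal length, applied to the
    detail coefficients of every level; ``threshold_scale = 0`` reduces the
    routine to
    analysis followed by synthesis (the identity, up to rounding).
    ``width_hint`` carries the variance-curve localization for provenance;
    the width enters the pipeline through the multi-bin averaging that
    produced ``signal``.
    """
    config.validate()
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValidationError("dwt_denoise expects a 1-D slow-time series")
    min_len = 2 ** config.levels
    if signal.size < min_len:
        raise ValidationError(
            f"signal of length {signal.size} too short for {config.levels} "
            f"decomposition levels; need at least {min_len} samples"
        )
    wavelet = pywt.Wavelet(config.wavelet_name)
    coeffs = pywt.wavedec(signal, wavelet, level=config.levels, mode="symmetric")
    if config.threshold_scale > 0:
        # noise scale from the finest detail band, where respiration
        # (far below Nyquist) contributes essentially nothing
        sigma = float(np.median(np.abs(coeffs[-1]))) / 0.6745
        lam = config.threshold_scale * sigma * np.sqrt(2.0 * np.log(signal.size))
        for j in range(1, len(coeffs)):
            coeffs[j] = soft_threshold(coeffs[j], lam)
    rec = pywt.waverec(coeffs, wavelet, mode="symmetric")
    return rec[: signal.size]
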