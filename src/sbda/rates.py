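"""Breathing-rate estimation and method-agreement statistics.

The rate estimator zero-means the breathing signal, applies a Hann taper,
zero-pads the FFT to a configurable frequency resolution, and reports 60x
the frequency of the strongest in-band spectral peak (breaths per minute).

Two literature baselines are provided for side-by-side comparison on the
same radar matrices:

* autocorrelation + FFT — the subject bin is located by slow-time
  autocorrelation energy at nonzero lags, then the rate comes from the FFT
  of that bin's mean-subtracted series;
* mean subtraction + FFT — the per-bin slow-time mean is subtracted as the
  clutter estimate, the bin is located by slow-time variance, and the FFT
  peak gives the rate.

Neither baseline gates body movement, which is the failure mode the full
pipeline addresses.  Agreement against a reference (ground truth here,
polysomnography in the clinic) is quantified by per-pair percentage error
and Bland–Altman bias with 1.96-SD limits of agreement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import get_window

from .clutter import variance_localize
from .errors import DegenerateSceneError, ValidationError
from .scene import RadarMatrix

__all__ = [
    "BreathingEstimate",
    "AgreementReport",
    "estimate_rate_fft",
    "baseline_autocorr_fft",
    "baseline_meansub_fft",
    "percentage_error",
    "bland_altman",
]

DEFAULT_SEARCH_BAND_HZ = (0.1, 0.8)
DEFAULT_RESOLUTION_HZ = 0.005
MIN_DURATION_S = 30.0


@dataclass(frozen=True)
class BreathingEstimate:
    """A breaths-per-minute estimate with its spectral provenance."""

    rate_bpm: float
    peak_freq_hz: float
    search_band_hz: tuple[float, float]
    method: str
    window_provenance: tuple[int, ...] = ()


@dataclass(frozen=True)
class AgreementReport:
    """Bland–Altman agreement between a candidate method and a reference.

    ``bias`` is the mean candidate-minus-reference difference;
    ``loa_low``/``loa_high`` are bias -/+ 1.96 x sample SD of the
    differences.  ``percentage_errors`` holds 100|c - r|/r per pair.
    """

    candidate: np.ndarray
    reference: np.ndarray
    means: np.ndarray
    differences: np.ndarray
    bias: float
    loa_low: float
    loa_high: float
    percentage_errors: np.ndarray
    mean_percentage_error: float

    def to_frame(self) -> pd.DataFrame:
        """Plot-ready Bland–Altman table (one row per pair)."""
        return pd.DataFrame(
            {
                "candidate_bpm": self.candidate,
                "reference_bpm": self.reference,
                "mean_bpm": self.means,
                "difference_bpm": self.differences,
                "percentage_error": self.percentage_errors,
            }
        )


def estimate_rate_fft(
    signal: np.ndarray,
    fs: float,
    search_band_hz: tuple[float, float] = DEFAULT_SEARCH_BAND_HZ,
    resolution_hz: float = DEFAULT_RESOLUTION_HZ,
    taper: str = "hann",
    method: str = "fft",
    min_duration_s: float = MIN_DURATION_S,
) -> BreathingEstimate:
    """Breathing rate from the strongest in-band FFT peak.

    The signal is zero-meaned, tapered, and zero-padded to at least
    ``resolution_hz`` frequency resolution; ties in peak magnitude resolve
    to the lower frequency.  Signals shorter than ``min_duration_s`` are
    rejected: the spectral line of a breath cannot be resolved reliably on
    shorter records.
    """
    signal = np.asarray(signal, dtype=float)
    if fs <= 0:
        raise ValidationError(f"fs must be positive; got {fs}")
    lo, hi = search_band_hz
    if not 0.0 < lo < hi < fs / 2.0:
        raise ValidationError(
            f"search band {search_band_hz} must satisfy 0 < low < high < fs/2"
        )
    duration = signal.size / fs
    if duration < min_duration_s:
        raise ValidationError(
            f"signal of {duration:.1f} s too short for rate estimation; "
            f"need at least {min_duration_s:g} s"
        )
    x = signal - signal.mean()
    if taper:
        x = x * get_window(taper, x.size)
    n_fft = 1
    target = max(x.size, int(np.ceil(fs / resolution_hz)))
    while n_fft < target:
        n_fft *= 2
    magnitude = np.abs(np.fft.rfft(x, n_fft))
    freqs = np.fft.rfftfreq(n_fft, 1.0 / fs)
    in_band = (freqs >= lo) & (freqs <= hi)
    band_freqs = freqs[in_band]
    band_mag = magnitude[in_band]
    peak = float(band_freqs[int(np.argmax(band_mag))])  # argmax -> lowest index on ties
    return BreathingEstimate(
        rate_bpm=60.0 * peak,
        peak_freq_hz=peak,
        search_band_hz=(float(lo), float(hi)),
        method=method,
    )


def _mean_subtract(matrix: RadarMatrix) -> RadarMatrix:
    residual = matrix.samples - matrix.samples.mean(axis=0, keepdims=True)
    return RadarMatrix(
        samples=residual,
        slow_period_s=matrix.slow_period_s,
        fast_period=matrix.fast_period,
        t0=matrix.t0,
    )


def autocorr_localize(
    residual: RadarMatrix,
    max_lag_s: float = 10.0,
    band_hz: tuple[float, float] = DEFAULT_SEARCH_BAND_HZ,
) -> tuple[int, int, np.ndarray]:
    """Locate the subject bin by slow-time autocorrelation energy at
    nonzero lags.

    Each bin's zero-mean series is band-limited to the respiration search
    band (the localization looks for breathing, not for arbitrary slow
    drifts), its biased autocorrelation r(l) is computed, and the energy
    sum_{l=1..L} r(l)^2 with lag 0 excluded is scored; the bin with maximal
    energy wins.  Returns ``(bin, best_lag, energies)`` where ``best_lag``
    is the argmax lag (>= 1 by construction) of r at the selected bin.
    """
    x = residual.samples
    n = x.shape[0]
    if n < 4:
        raise ValidationError("autocorrelation localization needs >= 4 frames")
    max_lag = min(n - 1, max(1, int(round(max_lag_s / residual.slow_period_s))))
    x0 = x - x.mean(axis=0, keepdims=True)
    n_fft = 1
    while n_fft < 2 * n:
        n_fft *= 2
    spec = np.fft.rfft(x0, n_fft, axis=0)
    freqs = np.fft.rfftfreq(n_fft, residual.slow_period_s)
    spec[(freqs < band_hz[0]) | (freqs > band_hz[1]), :] = 0.0
    acf = np.fft.irfft(spec * np.conj(spec), n_fft, axis=0)[: max_lag + 1] / n
    nonzero = acf[1:]
    energies = np.sum(nonzero**2, axis=0)
    if energies.max() <= 0.0:
        raise DegenerateSceneError("static scene: zero autocorrelation energy in every bin")
    sel = int(np.argmax(energies))
    best_lag = int(np.argmax(nonzero[:, sel])) + 1
    return sel, best_lag, energies


def baseline_autocorr_fft(
    matrix: RadarMatrix,
    search_band_hz: tuple[float, float] = DEFAULT_SEARCH_BAND_HZ,
    resolution_hz: float = DEFAULT_RESOLUTION_HZ,
) -> BreathingEstimate:
    """Autocorrelation-localization + FFT baseline (no movement gating)."""
    residual = _mean_subtract(matrix)
    sel, _, _ = autocorr_localize(residual, band_hz=search_band_hz)
    est = estimate_rate_fft(
        residual.samples[:, sel],
        matrix.slow_rate_hz,
        search_band_hz=search_band_hz,
        resolution_hz=resolution_hz,
        method="autocorr_fft",
    )
    return est


def baseline_meansub_fft(
    matrix: RadarMatrix,
    search_band_hz: tuple[float, float] = DEFAULT_SEARCH_BAND_HZ,
    resolution_hz: float = DEFAULT_RESOLUTION_HZ,
) -> BreathingEstimate:
    """Mean-subtraction clutter removal + variance localization + FFT
    baseline (no movement gating)."""
    residual = _mean_subtract(matrix)
    profile = variance_localize(residual)
    if profile.degenerate:
        raise DegenerateSceneError("static scene: zero slow-time variance in every bin")
    est = estimate_rate_fft(
        residual.samples[:, profile.selected_bin],
        matrix.slow_rate_hz,
        search_band_hz=search_band_hz,
        resolution_hz=resolution_hz,
        method="meansub_fft",
    )
    return est


def percentage_error(candidate_bpm: float, reference_bpm: float) -> float:
    """100 * |candidate - reference| / reference (reference must be > 0)."""
    if not reference_bpm > 0:
        raise ValidationError(f"reference_bpm must be positive; got {reference_bpm}")
    return 100.0 * abs(candidate_bpm - reference_bpm) / reference_bpm


def bland_altman(pairs: Sequence[tuple[float, float]]) -> AgreementReport:
    """Bland–Altman agreement of candidate vs. reference rates.

    Needs >= 2 pairs; the limits of agreement use the sample (ddof=1)
    standard deviation of the differences.
    """
    if len(pairs) < 2:
        raise ValidationError(f"bland_altman needs >= 2 pairs; got {len(pairs)}")
    candidate = np.asarray([p[0] for p in pairs], dtype=float)
    reference = np.asarray([p[1] for p in pairs], dtype=float)
    differences = candidate - reference
    means = 0.5 * (candidate + reference)
    bias = float(differences.mean())
    sd = float(differences.std(ddof=1))
    perc = np.array([percentage_error(c, r) for c, r in zip(candidate, reference)])
    return AgreementReport(
        candidate=candidate,
        reference=reference,
        means=means,
        differences=differences,
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        percentage_errors=perc,
        mean_percentage_error=float(perc.mean()),
    )
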