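"""Periodic-motion gating by sinusoidal curve fitting.

Chest-wall motion is periodic; gross body movement is not.  Each slow-time
window is fitted with a sine series

    y(t) = sum_i a_i * sin(b_i * t + c_i)

and scored with the coefficient of determination

    R^2 = 1 - SS_res / SS_tot.

Windows with R^2 below the gate threshold (default 0.5) are rejected as
movement-contaminated; only the kept windows feed the breathing-signal
extraction.  The fit is a nonlinear least-squares problem, so it is
multi-started from the strongest spectral peaks of the window with the
amplitude/phase of each start solved linearly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import ValidationError

__all__ = [
    "GateConfig",
    "SineFitResult",
    "GateMask",
    "fit_sine_series",
    "r_squared",
    "gate_windows",
    "window_agreement",
]

# frequency range scanned for starting values: generous around human
# respiration (0.05-1.0 Hz covers 3-60 breaths/min)
_SEED_BAND_HZ = (0.05, 1.0)
_N_SEEDS = 3


@dataclass(frozen=True)
class GateConfig:
    """window_s: gate window length (s); n_terms: sine terms in the series;
    r2_threshold: keep windows with R^2 >= this; overlap_fraction in [0, 1)."""

    window_s: float = 30.0
    n_terms: int = 1
    r2_threshold: float = 0.5
    overlap_fraction: float = 0.0

    def validate(self) -> None:
        if not self.window_s > 0:
            raise ValidationError(f"window_s must be positive; got {self.window_s}")
        if self.n_terms < 1:
            raise ValidationError(f"n_terms must be >= 1; got {self.n_terms}")
        if not 0.0 <= self.r2_threshold <= 1.0:
            raise ValidationError(f"r2_threshold must lie in [0, 1]; got {self.r2_threshold}")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValidationError(
                f"overlap_fraction must lie in [0, 1); got {self.overlap_fraction}"
            )


@dataclass(frozen=True)
class SineFitResult:
    """Fitted sine-series parameters for one window.

    ``frequencies_rad`` are angular frequencies (rad/s); amplitudes are
    reported nonnegative with the sign absorbed into the phase.
    """

    amplitudes: np.ndarray
    frequencies_rad: np.ndarray
    phases: np.ndarray
    r_squared: float
    converged: bool

    def predict(self, times: np.ndarray) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        out = np.zeros_like(times)
        for a, b, c in zip(self.amplitudes, self.frequencies_rad, self.phases):
            out += a * np.sin(b * times + c)
        return out


@dataclass(frozen=True)
class GateMask:
    """Per-window keep/reject decisions with the underlying fits and the
    window frame boundaries ``(start, end)`` (end exclusive)."""

    keep: np.ndarray
    fits: tuple[SineFitResult, ...]
    bounds: tuple[tuple[int, int], ...]
    r2_threshold: float

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())

    def kept_concatenated(self, signal: np.ndarray) -> np.ndarray:
        """Concatenate the kept windows of ``signal`` (gaps removed)."""
        segments = [signal[s:e] for (s, e), k in zip(self.bounds, self.keep) if k]
        if not segments:
            return np.empty(0)
        return np.concatenate(segments)


def r_squared(actual: np.ndarray, fitted: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot with SS_tot taken
    about the mean of ``actual``.

    Returns 0.0 for a zero-variance ``actual`` (a constant series carries no
    structure to explain); may be negative for fits worse than the mean.
    """
    actual = np.asarray(actual, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if actual.shape != fitted.shape:
        raise ValidationError(
            f"length mismatch: actual has {actual.shape}, fitted has {fitted.shape}"
        )
    if actual.size < 2:
        raise ValidationError("r_squared needs at least 2 samples")
    ss_res = float(np.sum((actual - fitted) ** 2))
    ss_tot = float(np.sum((actual - actual.mean()) ** 2))
    if ss_tot == 0.0:
        return 0.0
    return 1.0 - ss_res / ss_tot


def _sine_model(t: np.ndarray, *params: float) -> np.ndarray:
    out = np.zeros_like(t)
    for i in range(0, len(params), 3):
        a, b, c = params[i : i + 3]
        out += a * np.sin(b * t + c)
    return out


def _spectral_seeds(window: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Candidate angular frequencies: the strongest in-band FFT peaks."""
    dt = float(np.median(np.diff(times)))
    x = window - window.mean()
    n_fft = max(256, 4 * x.size)
    mag = np.abs(np.fft.rfft(x, n_fft))
    freqs = np.fft.rfftfreq(n_fft, dt)
    band = (freqs >= _SEED_BAND_HZ[0]) & (freqs <= _SEED_BAND_HZ[1])
    if not band.any():
        return np.array([2 * np.pi * 0.25])
    bf, bm = freqs[band], mag[band]
    order = np.argsort(bm)[::-1]
    seeds: list[float] = []
    for idx in order:
        f = bf[idx]
        if all(abs(f - s) > 0.02 for s in seeds):  # skip near-duplicate peaks
            seeds.append(float(f))
        if len(seeds) >= _N_SEEDS:
            break
    return 2 * np.pi * np.asarray(seeds)


def _linear_amp_phase(window: np.ndarray, times: np.ndarray, omega: float) -> tuple[float, float]:
    """Least-squares amplitude/phase of a sine at fixed angular frequency."""
    design = np.column_stack([np.sin(omega * times), np.cos(omega * times)])
    (p, q), *_ = np.linalg.lstsq(design, window, rcond=None)
    return float(np.hypot(p, q)), float(np.arctan2(q, p))


def _canonicalize(params: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Report nonnegative amplitudes and frequencies, wrapping phases."""
    amps = params[0::3].copy()
    freqs = params[1::3].copy()
    phases = params[2::3].copy()
    neg_f = freqs < 0
    # a sin(-b t + c) = -a sin(b t - c)
    freqs[neg_f] *= -1
    phases[neg_f] *= -1
    amps[neg_f] *= -1
    neg_a = amps < 0
    amps[neg_a] *= -1
    phases[neg_a] += np.pi
    phases = np.mod(phases + np.pi, 2 * np.pi) - np.pi
    return amps, freqs, phases


def fit_sine_series(
    window: np.ndarray, times: np.ndarray, n_terms: int = 1
) -> SineFitResult:
    """Fit ``y = sum_i a_i sin(b_i t + c_i)`` to one slow-time window.

    Starting frequencies are drawn from the window's strongest spectral
    peaks; the best converged start (by R^2) wins.  If no start converges
    the best linear-seeded candidate is reported with ``converged=False``.
    """
    window = np.asarray(window, dtype=float)
    times = np.asarray(times, dtype=float)
    if window.shape != times.shape or window.ndim != 1:
        raise ValidationError("window and times must be 1-D arrays of equal length")
    if window.size < 3 * n_terms:
        raise ValidationError(
            f"window of {window.size} samples too short to fit {n_terms} sine terms "
            f"(need >= {3 * n_terms})"
        )
    if not (np.all(np.isfinite(window)) and np.all(np.isfinite(times))):
        raise ValidationError("window and times must be finite")

    if np.ptp(window) == 0.0:
        zeros = np.zeros(n_terms)
        return SineFitResult(
            amplitudes=zeros, frequencies_rad=zeros.copy(), phases=zeros.copy(),
            r_squared=0.0, converged=True,
        )

    seeds = _spectral_seeds(window, times)
    best: tuple[float, np.ndarray] | None = None
    best_fallback: tuple[float, np.ndarray] | None = None
    converged = False
    for start in range(len(seeds)):
        p0: list[float] = []
        for term in range(n_terms):
            omega = seeds[(start + term) % len(seeds)]
            amp, phase = _linear_amp_phase(window, times, omega)
            p0.extend([amp, omega, phase])
        p0_arr = np.asarray(p0)
        fallback_r2 = r_squared(window, _sine_model(times, *p0_arr))
        if best_fallback is None or fallback_r2 > best_fallback[0]:
            best_fallback = (fallback_r2, p0_arr)
        try:
            popt, _ = curve_fit(_sine_model, times, window, p0=p0_arr, maxfev=5000)
        except RuntimeError:
            continue
        r2 = r_squared(window, _sine_model(times, *popt))
        converged = True
        if best is None or r2 > best[0]:
            best = (r2, popt)

    r2, params = best if best is not None else best_fallback
    amps, freqs, phases = _canonicalize(np.asarray(params))
    return SineFitResult(
        amplitudes=amps, frequencies_rad=freqs, phases=phases,
        r_squared=float(r2), converged=converged,
    )


def gate_windows(
    signal: np.ndarray, fs: float, config: GateConfig = GateConfig()
) -> GateMask:
    """Tile ``signal`` into windows, fit each, and keep windows whose fit
    converged with R^2 >= the gate threshold.  A trailing partial window is
    dropped."""
    config.validate()
    signal = np.asarray(signal, dtype=float)
    if fs <= 0:
        raise ValidationError(f"fs must be positive; got {fs}")
    wlen = int(round(config.window_s * fs))
    if signal.size < wlen:
        raise ValidationError(
            f"signal of {signal.size} samples is shorter than one "
            f"{config.window_s:g}-s window ({wlen} samples)"
        )
    step = max(1, int(round(wlen * (1.0 - config.overlap_fraction))))
    times = np.arange(wlen) / fs
    keep: list[bool] = []
    fits: list[SineFitResult] = []
    bounds: list[tuple[int, int]] = []
    for start in range(0, signal.size - wlen + 1, step):
        window = signal[start : start + wlen]
        fit = fit_sine_series(window, times, n_terms=config.n_terms)
        fits.append(fit)
        bounds.append((start, start + wlen))
        keep.append(bool(fit.converged and fit.r_squared >= config.r2_threshold))
    return GateMask(
        keep=np.asarray(keep, dtype=bool),
        fits=tuple(fits),
        bounds=tuple(bounds),
        r2_threshold=config.r2_threshold,
    )


def window_agreement(mask: GateMask, movement_mask: np.ndarray) -> float:
    """Fraction of windows where the gate's decision matches the ground
    truth: a window is truly "movement" when more than half its frames are
    flagged in ``movement_mask``, and agreement means keep == not-movement."""
    movement_mask = np.asarray(movement_mask, dtype=bool)
    hits = 0
    for (start, end), kept in zip(mask.bounds, mask.keep):
        moving = movement_mask[start:end].mean() > 0.5
        hits += int(kept == (not moving))
    return hits / len(mask.bounds)
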