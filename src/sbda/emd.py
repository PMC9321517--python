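"""Empirical mode decomposition, its noise-ensemble variant, and
respiration-band IMF selection.

EMD adaptively splits a signal into intrinsic mode functions (IMFs) by
*sifting*: cubic-spline envelopes are drawn through the local maxima and
minima, their mean is subtracted, and the step repeats until the candidate
satisfies the IMF conditions — (i) the numbers of extrema and zero
crossings are equal or differ by one, and (ii) the envelope mean is
approximately zero.  The extracted IMF is removed and sifting restarts on
the remainder until the residue is monotone.  By construction

    x(t) = sum_i IMF_i(t) + residue(t)

holds exactly.

Plain EMD suffers from mode mixing on intermittent signals: oscillations of
disparate time scales land in one IMF.  Ensemble EMD (EEMD) mitigates this
by decomposing many noise-perturbed copies of the signal and averaging the
k-th IMF across trials; the added white noise populates the whole spectrum
and acts as a uniform reference scale.

The breathing signal is then reconstructed from the IMFs whose spectral
energy concentrates in the respiration band: IMF j is selected when
E_rj / E_j >= delta_r, with E_j the total spectral energy of the IMF and
E_rj its energy inside the band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import NoRespiratoryComponentError, ValidationError

__all__ = [
    "IMFSet",
    "EEMDConfig",
    "EnergySelection",
    "BAND_PRESETS",
    "emd",
    "eemd",
    "energy_ratio",
    "score_imfs",
    "select_and_reconstruct",
    "imf_condition_holds",
]

# the two respiration-band conventions in circulation; "method" is the
# module default, "results" the narrower alternative
BAND_PRESETS: dict[str, tuple[float, float]] = {
    "method": (0.2, 0.8),
    "results": (0.1, 0.35),
}


@dataclass(frozen=True)
class IMFSet:
    """Ordered intrinsic mode functions (index 0 = highest frequency) plus
    the residue; ``source`` records whether plain EMD or the ensemble
    variant produced them."""

    imfs: tuple[np.ndarray, ...]
    residue: np.ndarray
    source: str

    def __len__(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for imf in self.imfs:
            out += imf
        return out


@dataclass(frozen=True)
class SiftStop:
    """Cauchy-type stopping rule: stop a sift when the normalized squared
    change between iterates falls below ``sd_tol`` (and the IMF conditions
    hold), or after ``max_iterations`` sweeps."""

    sd_tol: float = 0.2
    max_iterations: int = 50


@dataclass(frozen=True)
class EEMDConfig:
    """n_trials: ensemble size; noise_sigma_ratio: white-noise sigma as a
    fraction of the input's standard deviation; rng_seed: ensemble seed;
    max_imfs: cap on modes per trial (None = until monotone)."""

    n_trials: int = 100
    noise_sigma_ratio: float = 0.2
    rng_seed: int = 0
    max_imfs: int | None = None
    sift_stop: SiftStop = field(default_factory=SiftStop)

    def validate(self) -> None:
        if self.n_trials < 1:
            raise ValidationError(f"n_trials must be >= 1; got {self.n_trials}")
        if self.noise_sigma_ratio < 0:
            raise ValidationError("noise_sigma_ratio must be >= 0")


@dataclass(frozen=True)
class EnergySelection:
    """Per-IMF spectral energies, respiration-band energies and their
    ratios; ``selected`` holds the (0-based) indices with ratio >= delta_r."""

    energies: np.ndarray
    band_energies: np.ndarray
    ratios: np.ndarray
    band_hz: tuple[float, float]
    delta_r: float
    selected: tuple[int, ...]


# ---------------------------------------------------------------------------
# sifting machinery
# ---------------------------------------------------------------------------


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of interior local maxima and minima; plateaus count once."""
    d = np.sign(np.diff(x))
    nz = d != 0
    if not nz.any():
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    # forward-fill zero signs so plateaus inherit the preceding slope
    idx = np.where(nz, np.arange(d.size), 0)
    np.maximum.accumulate(idx, out=idx)
    filled = d[idx]
    turn = np.diff(filled)
    maxima = np.where(turn < 0)[0] + 1
    minima = np.where(turn > 0)[0] + 1
    return maxima, minima


def _count_zero_crossings(x: np.ndarray) -> int:
    s = np.sign(x)
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(s)))


def imf_condition_holds(imf: np.ndarray) -> bool:
    """Check the extrema/zero-crossing IMF condition (counts equal or
    differing by at most one)."""
    maxima, minima = _local_extrema(imf)
    n_ext = maxima.size + minima.size
    n_zc = _count_zero_crossings(imf)
    return abs(n_ext - n_zc) <= 1


def _envelope(idx: np.ndarray, x: np.ndarray) -> np.ndarray | None:
    """Cubic-spline envelope through the extrema at ``idx``, with the two
    outermost extrema mirrored past each end to tame boundary swings."""
    n = x.size
    if idx.size < 2:
        return None
    k = min(2, idx.size)
    left_t = (-idx[:k][::-1]).astype(float)
    left_v = x[idx[:k]][::-1]
    right_t = (2 * (n - 1) - idx[-k:][::-1]).astype(float)
    right_v = x[idx[-k:]][::-1]
    ts = np.concatenate([left_t, idx.astype(float), right_t])
    vs = np.concatenate([left_v, x[idx], right_v])
    keep = np.concatenate([[True], np.diff(ts) > 0])
    ts, vs = ts[keep], vs[keep]
    if ts.size < 2:
        return None
    return CubicSpline(ts, vs)(np.arange(n))


def _sift_one_imf(x: np.ndarray, stop: SiftStop) -> np.ndarray | None:
    """Extract one IMF from ``x``, or return None when ``x`` has too few
    extrema to sift (i.e. it is the residue)."""
    h = x
    for _ in range(stop.max_iterations):
        maxima, minima = _local_extrema(h)
        if maxima.size < 2 or minima.size < 2:
            return None if h is x else h
        upper = _envelope(maxima, h)
        lower = _envelope(minima, h)
        if upper is None or lower is None:
            return None if h is x else h
        mean_env = 0.5 * (upper + lower)
        h_new = h - mean_env
        denom = float(np.sum(h * h))
        sd = float(np.sum(mean_env * mean_env)) / denom if denom > 0 else 0.0
        h = h_new
        if sd < stop.sd_tol and imf_condition_holds(h):
            break
    return h


def emd(
    signal: np.ndarray,
    max_imfs: int | None = None,
    sift_stop: SiftStop = SiftStop(),
) -> IMFSet:
    """Decompose ``signal`` into intrinsic mode functions by sifting.

    A monotone input yields no IMFs (the residue is the input itself).  The
    identity input = sum(IMFs) + residue holds to floating-point accuracy by
    construction.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1 or signal.size < 8:
        raise ValidationError(
            f"emd expects a 1-D signal of >= 8 samples; got shape {signal.shape}"
        )
    if not np.all(np.isfinite(signal)):
        raise ValidationError("signal must be finite")

    imfs: list[np.ndarray] = []
    residue = signal.copy()
    while max_imfs is None or len(imfs) < max_imfs:
        imf = _sift_one_imf(residue, sift_stop)
        if imf is None:
            break
        imfs.append(imf)
        residue = residue - imf
    return IMFSet(imfs=tuple(imfs), residue=residue, source="emd")


def eemd(signal: np.ndarray, config: EEMDConfig = EEMDConfig()) -> IMFSet:
    """Ensemble EMD: average the k-th IMF over noise-perturbed trials.

    Each trial adds fresh seeded white noise of sigma =
    ``noise_sigma_ratio * std(signal)`` and is decomposed by :func:`emd`.
    Trials can produce different mode counts; mode k is averaged over the
    trials that produced it and dropped when fewer than half did.  The
    residue is defined as input minus the summed averaged IMFs so the
    decomposition remains an exact identity.  Deterministic for a fixed
    seed; with one trial and zero noise the result equals plain EMD.
    """
    config.validate()
    signal = np.asarray(signal, dtype=float)
    rng = np.random.default_rng(config.rng_seed)
    sigma = config.noise_sigma_ratio * float(signal.std())

    per_mode: dict[int, list[np.ndarray]] = {}
    for _ in range(config.n_trials):
        noisy = signal + rng.normal(0.0, sigma, signal.size) if sigma > 0 else signal
        trial = emd(noisy, max_imfs=config.max_imfs, sift_stop=config.sift_stop)
        for k, imf in enumerate(trial.imfs):
            per_mode.setdefault(k, []).append(imf)

    min_count = (config.n_trials + 1) // 2
    averaged: list[np.ndarray] = []
    for k in sorted(per_mode):
        trials_k = per_mode[k]
        if len(trials_k) < min_count:
            break
        averaged.append(np.mean(trials_k, axis=0))

    # subtract sequentially (same operation order as plain sifting) so the
    # degenerate one-trial, zero-noise ensemble is bit-identical to emd()
    residue = signal.copy()
    for imf in averaged:
        residue = residue - imf
    return IMFSet(imfs=tuple(averaged), residue=residue, source="eemd")


# ---------------------------------------------------------------------------
# respiration-band selection
# ---------------------------------------------------------------------------


def _onesided_power(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-sided magnitude-squared spectrum with interior bins doubled (the
    energy of a real signal counts both frequency signs), and its
    frequencies in cycles per sample."""
    spectrum = np.abs(np.fft.rfft(x)) ** 2
    weights = np.full(spectrum.size, 2.0)
    weights[0] = 1.0
    if x.size % 2 == 0:
        weights[-1] = 1.0
    return spectrum * weights, np.fft.rfftfreq(x.size)


def energy_ratio(
    imf: np.ndarray, fs: float, band_hz: tuple[float, float] = BAND_PRESETS["method"]
) -> float:
    """Fraction of the IMF's spectral energy inside ``band_hz``.

    E_j is the total energy of the magnitude-squared one-sided spectrum
    (interior bins doubled to count both frequency signs), E_rj the energy
    over the band (inclusive bounds); a zero-energy IMF has ratio 0 by
    convention.
    """
    if fs <= 0:
        raise ValidationError(f"fs must be positive; got {fs}")
    lo, hi = band_hz
    if not 0.0 < lo < hi <= fs / 2.0:
        raise ValidationError(
            f"band {band_hz} must satisfy 0 < low < high <= fs/2 = {fs / 2.0:g}"
        )
    imf = np.asarray(imf, dtype=float)
    spectrum, cycles = _onesided_power(imf)
    total = float(spectrum.sum())
    if total == 0.0:
        return 0.0
    freqs = cycles * fs
    in_band = (freqs >= lo) & (freqs <= hi)
    return float(spectrum[in_band].sum() / total)


def score_imfs(
    imfset: IMFSet,
    fs: float,
    band_hz: tuple[float, float] | str = "method",
    delta_r: float = 0.5,
) -> EnergySelection:
    """Compute per-IMF band-energy ratios and apply the selection rule
    ratio >= delta_r.  ``band_hz`` may be a preset name or a (low, high)
    pair in Hz."""
    if isinstance(band_hz, str):
        try:
            band_hz = BAND_PRESETS[band_hz]
        except KeyError:
            raise ValidationError(
                f"unknown band preset {band_hz!r}; choose from {sorted(BAND_PRESETS)}"
            ) from None
    if not 0.0 <= delta_r <= 1.0:
        raise ValidationError(f"delta_r must lie in [0, 1]; got {delta_r}")
    energies = []
    band_energies = []
    ratios = []
    for imf in imfset.imfs:
        spectrum, cycles = _onesided_power(np.asarray(imf, dtype=float))
        freqs = cycles * fs
        total = float(spectrum.sum())
        in_band = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
        band_e = float(spectrum[in_band].sum())
        energies.append(total)
        band_energies.append(band_e)
        ratios.append(band_e / total if total > 0 else 0.0)
    ratios_arr = np.asarray(ratios)
    selected = tuple(int(j) for j in np.where(ratios_arr >= delta_r)[0])
    return EnergySelection(
        energies=np.asarray(energies),
        band_energies=np.asarray(band_energies),
        ratios=ratios_arr,
        band_hz=(float(band_hz[0]), float(band_hz[1])),
        delta_r=delta_r,
        selected=selected,
    )


def select_and_reconstruct(
    imfset: IMFSet, fs: float, selection: EnergySelection
) -> np.ndarray:
    """Sum the IMFs whose band-energy ratio passed the threshold into the
    reconstructed breathing signal."""
    if len(imfset) == 0:
        raise ValidationError("imfset is empty; nothing to reconstruct")
    if not selection.selected:
        raise NoRespiratoryComponentError(
            f"no IMF has band-energy ratio >= {selection.delta_r:g} in the "
            f"{selection.band_hz[0]:g}-{selection.band_hz[1]:g} Hz band; widen the "
            "band or lower the threshold explicitly"
        )
    out = np.zeros_like(imfset.imfs[0])
    for j in selection.selected:
        out += imfset.imfs[j]
    return out
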