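"""Synthetic impulse-radio UWB radar scenes with known ground truth.

An IR-UWB recording of a sleeping subject is a slow-time x fast-time
amplitude matrix: each row is one received frame (20 frames/s in the
hardware this emulates), each column a fast-time delay bin, i.e. a range
cell.  A static room contributes a constant ("clutter") amplitude per bin;
the subject's chest modulates the reflection amplitude at their range bin
quasi-sinusoidally at the breathing frequency; gross body movements inject
broadband aperiodic excursions across bins; receiver noise is additive
Gaussian.  The simulator reproduces exactly those four ingredients so that
every downstream stage can be validated against a known breathing rate and
movement mask.

Fast time is treated as unitless bins: the bin-to-metre conversion depends
on the radar's fast-time sampling period, which plays no role in rate
extraction.
"""

from __future__ import annotations

import io
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .errors import ParseError, ValidationError

__all__ = [
    "SceneConfig",
    "RadarMatrix",
    "GroundTruth",
    "simulate_scene",
    "write_matrix",
    "read_matrix",
    "load_scene_config",
]

_BINARY_MAGIC = b"SBDM"
_BINARY_VERSION = 1


@dataclass(frozen=True)
class RadarMatrix:
    """Slow-time x fast-time amplitude samples plus timing metadata.

    ``samples[m, n]`` is the amplitude of fast-time bin ``n`` in slow-time
    frame ``m``.  ``slow_period_s`` is the frame interval Ts (50 ms at
    20 frames/s); ``fast_period`` is kept as unitless metadata.
    """

    samples: np.ndarray
    slow_period_s: float
    fast_period: float = 1.0
    t0: float | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 2 or samples.shape[0] < 1 or samples.shape[1] < 1:
            raise ValidationError(
                f"samples must be a 2-D M x N matrix with M, N >= 1; got shape {samples.shape}"
            )
        if not np.all(np.isfinite(samples)):
            raise ValidationError("samples must be finite")
        if not (np.isfinite(self.slow_period_s) and self.slow_period_s > 0):
            raise ValidationError(f"slow_period_s must be positive; got {self.slow_period_s}")
        object.__setattr__(self, "samples", samples)

    @property
    def n_frames(self) -> int:
        return self.samples.shape[0]

    @property
    def n_bins(self) -> int:
        return self.samples.shape[1]

    @property
    def slow_rate_hz(self) -> float:
        return 1.0 / self.slow_period_s

    @property
    def times_s(self) -> np.ndarray:
        """Slow-time stamps of each frame relative to the recording start."""
        return np.arange(self.n_frames) * self.slow_period_s


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one simulated sleep scene.

    ``movement_epochs`` is a list of ``(start_s, end_s, amplitude)`` body-
    movement intervals; ``clutter_profile`` gives the static amplitude per
    range bin (scalar = flat profile).  ``leak_halfwidth`` controls the
    triangular spatial kernel through which chest motion leaks into
    neighbouring range cells; ``second_harmonic_ratio`` adds a configurable
    second harmonic to the chest displacement to exercise the classic
    harmonic-confusion failure mode of naive FFT rate pickers.
    ``position_shift_sigma`` is the per-bin standard deviation of the
    permanent clutter change left behind by each movement epoch: a body that
    moves settles in a new posture, so the static reflection profile after
    the epoch differs from the one before it.
    """

    duration_s: float = 60.0
    slow_rate_hz: float = 20.0
    n_range_bins: int = 30
    subject_bin: int = 10
    breathing_rate_bpm: float = 15.0
    breathing_amp: float = 1.0
    clutter_profile: Sequence[float] | float = 1.0
    noise_sigma: float = 0.0
    movement_epochs: Sequence[tuple[float, float, float]] = field(default_factory=tuple)
    rng_seed: int = 0
    leak_halfwidth: int = 2
    second_harmonic_ratio: float = 0.0
    position_shift_sigma: float = 1.5

    def validate(self) -> None:
        if not (np.isfinite(self.duration_s) and self.duration_s > 0):
            raise ValidationError(f"duration_s must be positive; got {self.duration_s}")
        if not (np.isfinite(self.slow_rate_hz) and self.slow_rate_hz > 0):
            raise ValidationError(f"slow_rate_hz must be positive; got {self.slow_rate_hz}")
        if not (np.isfinite(self.breathing_rate_bpm) and self.breathing_rate_bpm > 0):
            raise ValidationError(
                f"breathing_rate_bpm must be positive; got {self.breathing_rate_bpm}"
            )
        if self.breathing_rate_bpm / 60.0 >= self.slow_rate_hz / 2.0:
            raise ValidationError(
                f"breathing frequency {self.breathing_rate_bpm / 60.0:g} Hz violates the "
                f"Nyquist limit {self.slow_rate_hz / 2.0:g} Hz of the slow-time rate"
            )
        if self.n_range_bins < 1:
            raise ValidationError("n_range_bins must be >= 1")
        if not 0 <= self.subject_bin < self.n_range_bins:
            raise ValidationError(
                f"subject_bin {self.subject_bin} outside [0, {self.n_range_bins})"
            )
        if not (np.isfinite(self.breathing_amp) and self.breathing_amp >= 0):
            raise ValidationError("breathing_amp must be finite and >= 0")
        if not (np.isfinite(self.noise_sigma) and self.noise_sigma >= 0):
            raise ValidationError("noise_sigma must be finite and >= 0")
        if self.leak_halfwidth < 0:
            raise ValidationError("leak_halfwidth must be >= 0")
        if not (np.isfinite(self.position_shift_sigma) and self.position_shift_sigma >= 0):
            raise ValidationError("position_shift_sigma must be finite and >= 0")
        profile = self._profile_array()
        if not np.all(np.isfinite(profile)):
            raise ValidationError("clutter_profile must be finite")
        for k, (start, end, amp) in enumerate(self.movement_epochs):
            if not (np.isfinite(start) and np.isfinite(end) and np.isfinite(amp)):
                raise ValidationError(f"movement epoch {k} has non-finite values")
            if not (0.0 <= start < end <= self.duration_s):
                raise ValidationError(
                    f"movement epoch {k} ({start:g}, {end:g}) outside [0, {self.duration_s:g}]"
                )

    def _profile_array(self) -> np.ndarray:
        if np.isscalar(self.clutter_profile):
            return np.full(self.n_range_bins, float(self.clutter_profile))
        profile = np.asarray(self.clutter_profile, dtype=float)
        if profile.shape != (self.n_range_bins,):
            raise ValidationError(
                f"clutter_profile length {profile.shape} does not match "
                f"n_range_bins={self.n_range_bins}"
            )
        return profile


@dataclass(frozen=True)
class GroundTruth:
    """Validation channel of the simulator: the quantities the pipeline is
    asked to recover."""

    breathing_rate_bpm: float
    subject_bin: int
    movement_mask: np.ndarray  # bool per slow-time frame


def _movement_artifact(
    rng: np.random.Generator, n: int, amplitude: float, slow_rate_hz: float
) -> np.ndarray:
    """Aperiodic body-movement excursion for one epoch.

    Equal-power blend of (a) a broadband component — mean-removed Gaussian
    random walk (gross postural drift) mixed with white jitter (jerky
    micro-adjustments) — and (b) a quasi-rhythmic limb component whose tempo
    drifts across the epoch (a linear chirp with a random starting frequency
    and a drift of at least 0.15 Hz over the epoch, so it never settles into
    a sinusoid a periodicity gate would accept).  Normalized to ``amplitude``
    standard deviation.  One-second linear ramps at the epoch edges return
    the excursion smoothly to rest, so no step discontinuity is injected at
    the epoch boundaries.
    """
    if n <= 1:
        return np.zeros(n)
    walk = np.cumsum(rng.standard_normal(n))
    walk -= walk.mean()
    wstd = walk.std()
    if wstd > 0:
        walk /= wstd
    jitter = rng.standard_normal(n)
    jstd = jitter.std()
    if jstd > 0:
        jitter /= jstd
    broadband = np.sqrt(0.55) * walk + np.sqrt(0.45) * jitter
    bstd = broadband.std()
    if bstd > 0:
        broadband /= bstd

    t = np.arange(n) / slow_rate_hz
    f_start = rng.uniform(0.15, 0.6)
    drift = rng.choice([-1.0, 1.0]) * rng.uniform(0.15, 0.35)
    phase = 2 * np.pi * (f_start * t + 0.5 * (drift / t[-1]) * t**2)
    limb = np.sin(phase + rng.uniform(0.0, 2 * np.pi))
    lstd = limb.std()
    if lstd > 0:
        limb /= lstd

    artifact = np.sqrt(0.5) * broadband + np.sqrt(0.5) * limb
    ramp = min(int(round(slow_rate_hz)), n // 2)
    if ramp > 0:
        envelope = np.ones(n)
        envelope[:ramp] = np.linspace(0.0, 1.0, ramp)
        envelope[-ramp:] = np.linspace(1.0, 0.0, ramp)
        artifact *= envelope
    astd = artifact.std()
    if astd > 0:
        artifact *= amplitude / astd
    return artifact


def simulate_scene(config: SceneConfig) -> tuple[RadarMatrix, GroundTruth]:
    """Generate one radar matrix and its ground truth.

    The scene model is additive: per-bin static clutter, a sinusoidal
    breathing term (plus optional second harmonic) leaked through a
    triangular kernel around ``subject_bin``, a shared broadband movement
    excursion across all bins during each movement epoch (whole-body motion
    displaces every reflecting surface coherently), and white Gaussian
    noise.  The same configuration and seed give bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)

    n_frames = int(round(config.duration_s * config.slow_rate_hz))
    if n_frames < 1:
        raise ValidationError("scene too short: no slow-time frames")
    ts = 1.0 / config.slow_rate_hz
    t = np.arange(n_frames) * ts

    profile = config._profile_array()
    samples = np.tile(profile, (n_frames, 1))

    f0 = config.breathing_rate_bpm / 60.0
    chest = np.sin(2 * np.pi * f0 * t)
    if config.second_harmonic_ratio:
        chest = chest + config.second_harmonic_ratio * np.sin(4 * np.pi * f0 * t)
    breathing = config.breathing_amp * chest

    w = config.leak_halfwidth
    for offset in range(-w, w + 1):
        b = config.subject_bin + offset
        if 0 <= b < config.n_range_bins:
            weight = 1.0 - abs(offset) / (w + 1.0)
            samples[:, b] += weight * breathing

    movement_mask = np.zeros(n_frames, dtype=bool)
    for start_s, end_s, amp in config.movement_epochs:
        i0 = int(round(start_s * config.slow_rate_hz))
        i1 = min(int(round(end_s * config.slow_rate_hz)), n_frames)
        if i1 <= i0:
            continue
        artifact = _movement_artifact(rng, i1 - i0, amp, config.slow_rate_hz)
        samples[i0:i1, :] += artifact[:, None]
        movement_mask[i0:i1] = True
        if config.position_shift_sigma > 0:
            # the body settles in a new posture: the static profile changes,
            # ramping in across the epoch so no step is left at its edges
            shift = rng.normal(0.0, config.position_shift_sigma, config.n_range_bins)
            ramp01 = np.linspace(0.0, 1.0, i1 - i0)
            samples[i0:i1, :] += ramp01[:, None] * shift[None, :]
            samples[i1:, :] += shift[None, :]

    if config.noise_sigma > 0:
        samples += rng.normal(0.0, config.noise_sigma, samples.shape)

    matrix = RadarMatrix(samples=samples, slow_period_s=ts)
    truth = GroundTruth(
        breathing_rate_bpm=config.breathing_rate_bpm,
        subject_bin=config.subject_bin,
        movement_mask=movement_mask,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# matrix file dialects
#
# text:   '#'-prefixed key=value header lines, then one comma-delimited
#         slow-time frame per row (full float precision).
# binary: little-endian; magic "SBDM", version byte, M and N as uint64,
#         slow_period_s and fast_period as float64, a has-t0 flag byte and
#         t0 float64, then M*N float64 samples in row-major order.
# ---------------------------------------------------------------------------


def write_matrix(matrix: RadarMatrix, path: str | Path, fmt: str | None = None) -> None:
    """Write ``matrix`` to ``path`` in the text (default) or binary dialect.

    ``fmt`` is ``"text"`` or ``"binary"``; when omitted it is inferred from
    the suffix (``.bin`` -> binary, anything else -> text).
    """
    path = Path(path)
    if fmt is None:
        fmt = "binary" if path.suffix == ".bin" else "text"
    if fmt == "text":
        with path.open("w") as fh:
            fh.write("# sbda-radar-matrix v1\n")
            fh.write(f"# slow_period_s={matrix.slow_period_s!r}\n")
            fh.write(f"# fast_period={matrix.fast_period!r}\n")
            if matrix.t0 is not None:
                fh.write(f"# t0={matrix.t0!r}\n")
            for row in matrix.samples:
                fh.write(",".join(f"{v:.17g}" for v in row) + "\n")
    elif fmt == "binary":
        m, n = matrix.samples.shape
        t0 = matrix.t0
        header = struct.pack(
            "<4sBQQddBd",
            _BINARY_MAGIC,
            _BINARY_VERSION,
            m,
            n,
            matrix.slow_period_s,
            matrix.fast_period,
            1 if t0 is not None else 0,
            t0 if t0 is not None else 0.0,
        )
        with path.open("wb") as fh:
            fh.write(header)
            fh.write(np.ascontiguousarray(matrix.samples, dtype="<f8").tobytes())
    else:
        raise ValidationError(f"unknown matrix format {fmt!r}; use 'text' or 'binary'")


def read_matrix(path: str | Path) -> RadarMatrix:
    """Read a matrix written by :func:`write_matrix`; the dialect is sniffed
    from the file's magic bytes."""
    path = Path(path)
    with path.open("rb") as fh:
        magic = fh.read(4)
    if magic == _BINARY_MAGIC:
        return _read_binary(path)
    return _read_text(path)


def _read_binary(path: Path) -> RadarMatrix:
    header_size = struct.calcsize("<4sBQQddBd")
    raw = path.read_bytes()
    if len(raw) < header_size:
        raise ParseError(f"{path}: truncated binary header")
    magic, version, m, n, slow_period_s, fast_period, has_t0, t0 = struct.unpack(
        "<4sBQQddBd", raw[:header_size]
    )
    if version != _BINARY_VERSION:
        raise ParseError(f"{path}: unsupported binary version {version}")
    expected = header_size + 8 * m * n
    if len(raw) != expected:
        raise ParseError(
            f"{path}: payload size mismatch: expected {expected} bytes for a "
            f"{m} x {n} matrix, got {len(raw)}"
        )
    samples = np.frombuffer(raw[header_size:], dtype="<f8").reshape(m, n).copy()
    return RadarMatrix(
        samples=samples,
        slow_period_s=slow_period_s,
        fast_period=fast_period,
        t0=t0 if has_t0 else None,
    )


def _read_text(path: Path) -> RadarMatrix:
    meta: dict[str, float] = {}
    rows: list[np.ndarray] = []
    width: int | None = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    try:
                        meta[key.strip()] = float(value)
                    except ValueError as exc:
                        raise ParseError(
                            f"{path}:{lineno}: non-numeric header value for "
                            f"{key.strip()!r}: {value!r}"
                        ) from exc
                continue
            fields = line.split(",")
            if width is None:
                width = len(fields)
            elif len(fields) != width:
                raise ParseError(
                    f"{path}:{lineno}: ragged row: expected {width} fields, got {len(fields)}"
                )
            try:
                rows.append(np.array([float(v) for v in fields]))
            except ValueError:
                for col, v in enumerate(fields):
                    try:
                        float(v)
                    except ValueError:
                        raise ParseError(
                            f"{path}:{lineno}: non-numeric cell {v!r} in field {col + 1}"
                        ) from None
                raise
    if not rows:
        raise ParseError(f"{path}: no data rows")
    if "slow_period_s" not in meta:
        raise ParseError(f"{path}: header is missing slow_period_s")
    return RadarMatrix(
        samples=np.vstack(rows),
        slow_period_s=meta["slow_period_s"],
        fast_period=meta.get("fast_period", 1.0),
        t0=meta.get("t0"),
    )


def load_scene_config(path: str | Path) -> SceneConfig:
    """Load a :class:`SceneConfig` from a YAML (or flat key: value) file."""
    with Path(path).open() as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ParseError(f"{path}: scene config must be a mapping")
    known = set(SceneConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ParseError(f"{path}: unknown scene config keys {sorted(unknown)}")
    if "movement_epochs" in data and data["movement_epochs"] is not None:
        data["movement_epochs"] = tuple(tuple(e) for e in data["movement_epochs"])
    config = SceneConfig(**data)
    config.validate()
    return config
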