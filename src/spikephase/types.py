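"""Shared domain types for extracellular-signal phase-distortion analysis.

All times are seconds (float64), sample indices are 0-based, and segment
windows are half-open in samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ContinuousSignal",
    "SpikeTrain",
    "WaveformTemplate",
    "MeanWaveform",
    "FilterSpec",
    "FilterRealization",
    "SegmentSet",
    "DetectionScore",
    "RocCurve",
    "ExpansionMode",
    "ValidationError",
    "FormatError",
    "DEFAULT_FS",
]

#: Default sampling rate (Hz): 88 samples spanning a 2 ms waveform window.
DEFAULT_FS = 44000.0


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


class FormatError(IOError):
    """Raised when an on-disk artifact is malformed or inconsistent."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class ContinuousSignal:
    """A sampled single-channel voltage trace."""

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = _as_float_array(self.samples, "samples")
        if self.samples.size < 1:
            raise ValidationError("signal must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("signal samples must be finite")
        if not self.fs > 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")
        self.fs = float(self.fs)
        self.t0 = float(self.t0)

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def time_to_index(self, t: float) -> int:
        """Nearest sample index for time ``t`` (seconds)."""
        return int(round((t - self.t0) * self.fs))


@dataclass
class SpikeTrain:
    """Strictly increasing spike times in seconds over a known duration."""

    times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        self.times = _as_float_array(self.times, "times")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValidationError("spike times must be strictly increasing")
        if self.times.size and (self.times[0] < 0 or self.times[-1] > self.duration):
            raise ValidationError("spike times must lie within [0, duration]")
        if not self.duration > 0:
            raise ValidationError("duration must be positive")
        self.duration = float(self.duration)

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def rate(self) -> float:
        return len(self) / self.duration


@dataclass
class WaveformTemplate:
    """A fixed-length spike shape, peak-normalized to unit absolute amplitude."""

    samples: np.ndarray
    fs: float
    align_index: int
    width_hh: float  # full width at half height of the dominant extremum, ms

    def __post_init__(self) -> None:
        self.samples = _as_float_array(self.samples, "samples")
        if self.samples.size < 3:
            raise ValidationError("template must have at least 3 samples")
        if not (0 <= self.align_index < self.samples.size):
            raise ValidationError("align_index out of bounds")
        peak = np.max(np.abs(self.samples))
        if not np.isclose(peak, 1.0, rtol=0, atol=1e-9):
            raise ValidationError(f"template peak |amplitude| must be 1, got {peak}")
        if not self.fs > 0:
            raise ValidationError("fs must be positive")
        self.fs = float(self.fs)
        self.align_index = int(self.align_index)
        self.width_hh = float(self.width_hh)

    def __len__(self) -> int:
        return int(self.samples.size)


@dataclass
class MeanWaveform:
    """Spike-triggered mean +/- std over a fixed window around the timestamps."""

    mean: np.ndarray
    std: np.ndarray
    n_spikes: int
    fs: float
    window: tuple[float, float] = (0.5, 1.5)  # (pre_ms, post_ms)

    def __post_init__(self) -> None:
        self.mean = _as_float_array(self.mean, "mean")
        self.std = _as_float_array(self.std, "std")
        if self.mean.size != self.std.size:
            raise ValidationError("mean and std must have the same length")
        if self.n_spikes < 1:
            raise ValidationError("n_spikes must be >= 1")
        self.n_spikes = int(self.n_spikes)
        self.fs = float(self.fs)
        self.window = (float(self.window[0]), float(self.window[1]))

    def __len__(self) -> int:
        return int(self.mean.size)


#: phase classes: NLP (causal, nonlinear phase), ZP (bidirectional, zero
#: phase), LP (linear phase, symmetric FIR).
_PHASE_CLASSES = ("NLP", "ZP", "LP")
_FAMILIES = ("butterworth", "fir_hamming")


@dataclass(frozen=True)
class FilterSpec:
    """Declarative band-pass filter description.

    ``order`` counts poles for recursive families (a 4-pole band-pass
    Butterworth has ``order=4``) and taps-minus-one for FIR.
    """

    phase_class: str
    family: str
    order: int
    band: tuple[float, float]
    fs: float

    def __post_init__(self) -> None:
        if self.phase_class not in _PHASE_CLASSES:
            raise ValidationError(f"phase_class must be one of {_PHASE_CLASSES}")
        if self.family not in _FAMILIES:
            raise ValidationError(f"family must be one of {_FAMILIES}")
        low, high = self.band
        if not (0 < low < high < self.fs / 2):
            raise ValidationError(f"band {self.band} must satisfy 0 < low < high < fs/2")
        if self.order < 1:
            raise ValidationError("order must be >= 1")
        if self.phase_class == "ZP" and self.family != "butterworth":
            raise ValidationError("ZP is defined only for recursive families")
        if self.family == "butterworth" and self.order % 2:
            raise ValidationError("butterworth band-pass pole count must be even")
        object.__setattr__(self, "band", (float(low), float(high)))
        object.__setattr__(self, "fs", float(self.fs))
        object.__setattr__(self, "order", int(self.order))


@dataclass
class FilterRealization:
    """Realized coefficients: cascaded second-order sections or FIR taps."""

    spec: FilterSpec
    sos: np.ndarray | None = None
    taps: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.sos is None) == (self.taps is None):
            raise ValidationError("exactly one of sos/taps must be set")
        if self.sos is not None:
            self.sos = np.asarray(self.sos, dtype=np.float64)
            if self.sos.ndim != 2 or self.sos.shape[1] != 6:
                raise ValidationError("sos must have shape (n_sections, 6)")
            if np.any(np.abs(self.poles()) >= 1.0):
                raise ValidationError("recursive realization is unstable")
        else:
            self.taps = np.asarray(self.taps, dtype=np.float64)
            if self.taps.ndim != 1:
                raise ValidationError("taps must be one-dimensional")

    @property
    def is_recursive(self) -> bool:
        return self.sos is not None

    def poles(self) -> np.ndarray:
        if self.sos is None:
            return np.array([])
        roots = [np.roots(section[3:]) for section in self.sos]
        return np.concatenate(roots) if roots else np.array([])


@dataclass
class SegmentSet:
    """Equal-length threshold-crossing snippets with alignment metadata."""

    segments: np.ndarray  # (n_segments, n_samples)
    fs: float
    align_index: int
    window_ms: float
    source_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.segments = np.atleast_2d(np.asarray(self.segments, dtype=np.float64))
        n = self.segments.shape[1]
        if not (0 <= self.align_index < n):
            raise ValidationError("align_index out of bounds")
        expected = round(self.window_ms * self.fs / 1000)
        if expected != n:
            raise ValidationError(
                f"window_ms {self.window_ms} at fs {self.fs} implies {expected} samples, got {n}"
            )
        if self.source_times is not None:
            self.source_times = _as_float_array(self.source_times, "source_times")
            if self.source_times.size != self.segments.shape[0]:
                raise ValidationError("source_times length must match segment count")
        self.fs = float(self.fs)
        self.align_index = int(self.align_index)
        self.window_ms = float(self.window_ms)

    @property
    def n_segments(self) -> int:
        return int(self.segments.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.segments.shape[1])


@dataclass(frozen=True)
class DetectionScore:
    """False-positive (alpha) and false-negative (beta) probabilities."""

    alpha: float
    beta: float
    threshold: float

    def __post_init__(self) -> None:
        if not (0 <= self.alpha <= 1 and 0 <= self.beta <= 1):
            raise ValidationError("alpha and beta must lie in [0, 1]")


@dataclass
class RocCurve:
    """Operating points (P(alpha), P(1-beta)) sorted by P(alpha)."""

    points: np.ndarray  # (n, 2)
    thresholds: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        self.thresholds = np.asarray(self.thresholds, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValidationError("points must have shape (n, 2)")
        if np.any(self.points < -1e-12) or np.any(self.points > 1 + 1e-12):
            raise ValidationError("ROC coordinates must lie in [0, 1]^2")
        if np.any(np.diff(self.points[:, 0]) < 0):
            raise ValidationError("P(alpha) must be nondecreasing along the curve")


_EXPANSION_MODES = ("zeros", "constant", "linear", "mirror")


@dataclass(frozen=True)
class ExpansionMode:
    """Segment boundary expansion: mode plus per-side pad length in ms."""

    mode: str = "linear"
    pad_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in _EXPANSION_MODES:
            raise ValidationError(f"mode must be one of {_EXPANSION_MODES}")
        if self.pad_ms < 0:
            raise ValidationError("pad_ms must be >= 0")
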