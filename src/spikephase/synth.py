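"""Ground-truth signal synthesis.

A homogeneous Poisson spike train with an absolute refractory period is
convolved with a trough-dominant spike template and summed with pink (1/f)
noise scaled to a target SNR (template peak over noise standard deviation).

The template is the analytic time-derivative of a smooth single-trough
action-potential surrogate: a fast, sharp-edged downstroke of controllable
half-height width (an error-function-smoothed rectangular trough) followed
by a slower positive recovery lobe whose area exactly balances the trough,
so the template integrates to ~0 and decays to baseline on both sides.
Sharp trough edges keep broadband spectral content at every width, which is
what makes the waveform susceptible to nonlinear-phase dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .types import ContinuousSignal, SpikeTrain, ValidationError, WaveformTemplate

__all__ = [
    "SimulationConfig",
    "generate_spike_train",
    "make_template",
    "measure_width_hh",
    "generate_pink_noise",
    "assemble_signal",
]

#: Gaussian smoothing of the trough edges (ms); fixed across widths so that
#: wide troughs keep fast transitions, as extracellular waveforms do.
EDGE_TAU_MS = 0.04

_FINE_DT = 5e-7  # fine-grid step (s) used for width calibration


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated recording."""

    rate: float = 10.0
    duration: float = 10.0
    refractory_ms: float = 1.0
    width_hh_ms: float = 0.4
    target_snr: float = 2.7
    fs: float = 44000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValidationError("rate must be >= 0")
        if self.duration <= 0:
            raise ValidationError("duration must be positive")
        if self.refractory_ms <= 0:
            raise ValidationError("refractory_ms must be positive")
        if self.target_snr <= 0:
            raise ValidationError("target_snr must be positive")


def generate_spike_train(
    rate: float,
    duration: float,
    refractory_ms: float = 1.0,
    seed: int | np.random.Generator = 0,
    margin: float = 0.0,
) -> SpikeTrain:
    """Homogeneous Poisson spike times with a dead-time (refractory) period.

    Inter-spike intervals are ``refractory + Exponential(1/rate)``.  Spikes
    within ``margin`` seconds of either end are excluded so a convolution
    window always fits.
    """
    if rate < 0:
        raise ValidationError("rate must be >= 0")
    if duration <= 0:
        raise ValidationError("duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if rate == 0:
        return SpikeTrain(times=np.array([]), duration=duration)
    refractory = refractory_ms / 1000.0
    # mean count under dead-time thinning, padded for sampling fluctuation
    expected = duration * rate / (1.0 + rate * refractory)
    times: list[float] = []
    t = margin
    while True:
        block = rng.exponential(1.0 / rate, size=max(64, int(1.5 * expected) + 16))
        for isi in block:
            t += isi + refractory
            if t >= duration - margin:
                return SpikeTrain(times=np.array(times), duration=duration)
            times.append(t)


def _recovery_params(w: float) -> tuple[float, float, float, float]:
    """(tau, s, d, A) of the trough smoothing and recovery lobe for trough
    nominal width ``w`` (seconds)."""
    tau = EDGE_TAU_MS * 1e-3
    s = 0.3 * w + 0.15e-3
    d = w / 2 + 2.5 * s
    a = w / (s * np.sqrt(2.0 * np.pi))  # recovery area == trough area
    return tau, s, d, a


def _shape(t: np.ndarray, w: float) -> np.ndarray:
    tau, s, d, a = _recovery_params(w)
    trough = -0.5 * (erf((t + w / 2) / (np.sqrt(2) * tau)) - erf((t - w / 2) / (np.sqrt(2) * tau)))
    recovery = a * np.exp(-((t - d) ** 2) / (2 * s**2))
    return trough + recovery


def _support(w: float) -> tuple[float, float]:
    tau, s, d, _ = _recovery_params(w)
    return -(w / 2 + 8 * tau + 1e-3), d + 6 * s


def measure_width_hh(samples: np.ndarray, fs: float) -> float:
    """Full width at half height (ms) of the dominant extremum.

    Crossing times are linearly interpolated between samples, so the result
    has sub-sample resolution.
    """
    y = np.asarray(samples, dtype=np.float64)
    k = int(np.argmax(np.abs(y)))
    y = y * np.sign(y[k])  # dominant extremum positive
    half = y[k] / 2.0
    lo = k
    while lo > 0 and y[lo - 1] >= half:
        lo -= 1
    hi = k
    while hi < y.size - 1 and y[hi + 1] >= half:
        hi += 1
    # interpolate the half-height crossings just outside [lo, hi]
    t_lo = float(lo)
    if lo > 0:
        t_lo = lo - (y[lo] - half) / (y[lo] - y[lo - 1])
    t_hi = float(hi)
    if hi < y.size - 1:
        t_hi = hi + (y[hi] - half) / (y[hi] - y[hi + 1])
    return (t_hi - t_lo) / fs * 1000.0


def _fine_fwhm(w: float) -> float:
    t0, t1 = _support(w)
    t = np.arange(t0, t1, _FINE_DT)
    return measure_width_hh(_shape(t, w), 1.0 / _FINE_DT) / 1000.0


def make_template(width_hh_ms: float, fs: float = 44000.0) -> WaveformTemplate:
    """Build the spike template with the requested half-height width.

    The nominal trough width is calibrated by bisection on a fine grid so
    that the measured full width at half height of the dominant (negative)
    extremum equals ``width_hh_ms``.
    """
    if width_hh_ms <= 0:
        raise ValidationError("width_hh_ms must be positive")
    target = width_hh_ms * 1e-3
    if _fine_fwhm(1e-7) > target:
        raise ValidationError(
            f"width_hh_ms={width_hh_ms} is below the narrowest realizable trough"
        )
    lo, hi = 1e-7, 2 * target
    while _fine_fwhm(hi) < target:
        hi *= 2
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _fine_fwhm(mid) < target:
            lo = mid
        else:
            hi = mid
    w = 0.5 * (lo + hi)
    t0, t1 = _support(w)
    n0, n1 = int(np.floor(t0 * fs)), int(np.ceil(t1 * fs))
    samples = _shape(np.arange(n0, n1 + 1) / fs, w)
    if samples.size < 5:
        raise ValidationError(f"width {width_hh_ms} ms yields < 5 samples at fs={fs}")
    samples = samples / np.max(np.abs(samples))
    return WaveformTemplate(
        samples=samples,
        fs=fs,
        align_index=int(np.argmax(np.abs(samples))),
        width_hh=width_hh_ms,
    )


def generate_pink_noise(
    n_samples: int, fs: float = 44000.0, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Zero-mean unit-variance 1/f noise by spectral shaping.

    A white Gaussian spectrum is multiplied by an f^(-1/2) amplitude mask
    (DC zeroed), inverse-transformed, and standardized.
    """
    if n_samples < 2:
        raise ValidationError("n_samples must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_bins = n_samples // 2 + 1
    spectrum = rng.standard_normal(n_bins) + 1j * rng.standard_normal(n_bins)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    mask = np.zeros_like(freqs)
    mask[1:] = freqs[1:] ** -0.5
    x = np.fft.irfft(spectrum * mask, n_samples)
    x -= x.mean()
    x /= x.std()
    return x


def assemble_signal(
    config: SimulationConfig,
) -> tuple[ContinuousSignal, SpikeTrain, WaveformTemplate]:
    """Simulate ``spikes (*) template + sigma * pink noise``.

    ``sigma = peak|template| / target_snr``, so the signal's SNR (template
    peak over noise standard deviation) equals ``target_snr`` by
    construction.  Each spike time maps to the template's ``align_index``.
    """
    template = make_template(config.width_hh_ms, config.fs)
    n = int(round(config.duration * config.fs))
    if n < len(template):
        raise ValidationError("duration too short to hold one template")
    rng = np.random.default_rng(config.seed)
    margin = len(template) / config.fs
    train = generate_spike_train(
        config.rate, config.duration, config.refractory_ms, rng, margin=margin
    )
    samples = np.zeros(n)
    k = template.align_index
    for t in train.times:
        i = int(round(t * config.fs))
        samples[i - k : i - k + len(template)] += template.samples
    sigma = 1.0 / config.target_snr  # template peak is 1 by normalization
    samples += sigma * generate_pink_noise(n, config.fs, rng)
    return ContinuousSignal(samples=samples, fs=config.fs), train, template
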