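"""Waveform extraction and distortion metrics.

The central quantity is the normalized Euclidean distance between two mean
spike waveforms extracted with *shared* spike timestamps, so that phase
delays register as distortion rather than being re-aligned away.
"""

from __future__ import annotations

import warnings

import numpy as np

from .types import ContinuousSignal, MeanWaveform, SpikeTrain, ValidationError

__all__ = [
    "mean_waveform",
    "normalized_distance",
    "snr_of",
    "estimate_noise_std",
    "dft_reconstruct",
]


def mean_waveform(
    signal: ContinuousSignal,
    train: SpikeTrain,
    window_ms: tuple[float, float] = (0.5, 1.5),
    align: str = "timestamp",
) -> MeanWaveform:
    """Spike-triggered mean and std over a fixed window around each spike.

    ``window_ms = (pre, post)`` spans the snippet relative to the
    timestamps (which are assumed to mark the trough); the default 2 ms
    window holds 88 samples at 44 kHz.  No re-alignment is performed:
    identical timestamps applied to differently filtered versions of the
    same signal make the extracted waveforms directly comparable.
    Out-of-bounds spikes are dropped with a warning.
    """
    if align != "timestamp":
        raise ValidationError(f"unsupported alignment {align!r}")
    if len(train) == 0:
        raise ValidationError("cannot average an empty spike train")
    pre = int(round(window_ms[0] * signal.fs / 1000))
    total = int(round((window_ms[0] + window_ms[1]) * signal.fs / 1000))
    starts = np.round((train.times - signal.t0) * signal.fs).astype(int) - pre
    valid = (starts >= 0) & (starts + total <= signal.n_samples)
    if not np.all(valid):
        warnings.warn(
            f"dropping {int(np.sum(~valid))} spikes whose window exceeds the signal",
            stacklevel=2,
        )
    starts = starts[valid]
    if starts.size == 0:
        raise ValidationError("no spike window lies fully within the signal")
    snippets = signal.samples[starts[:, None] + np.arange(total)[None, :]]
    return MeanWaveform(
        mean=snippets.mean(axis=0),
        std=snippets.std(axis=0),
        n_spikes=starts.size,
        fs=signal.fs,
        window=window_ms,
    )


def _as_samples(w) -> np.ndarray:
    if isinstance(w, MeanWaveform):
        return w.mean
    return np.asarray(w, dtype=np.float64)


def normalized_distance(w_ref, w_test) -> float:
    """``||w_test - w_ref|| / ||w_ref||`` for same-length waveforms.

    Alignment is by shared spike timestamps; no shifting is applied.
    """
    ref = _as_samples(w_ref)
    test = _as_samples(w_test)
    if ref.size != test.size:
        raise ValidationError(f"waveform lengths differ: {ref.size} vs {test.size}")
    norm = np.linalg.norm(ref)
    if norm == 0:
        raise ValidationError("reference waveform has zero norm")
    return float(np.linalg.norm(test - ref) / norm)


def snr_of(waveform, noise_std: float) -> float:
    """``max|waveform| / noise_std``."""
    if noise_std <= 0:
        raise ValidationError("noise_std must be positive")
    return float(np.max(np.abs(_as_samples(waveform))) / noise_std)


def estimate_noise_std(
    signal: ContinuousSignal, train: SpikeTrain, guard_ms: float = 2.0
) -> float:
    """Robust noise standard deviation from spike-free samples.

    Samples within ``+/- guard_ms`` of any spike are excluded and the
    remainder summarized by 1.4826 * MAD (consistent for Gaussian noise).
    """
    keep = np.ones(signal.n_samples, dtype=bool)
    guard = int(round(guard_ms * signal.fs / 1000))
    for t in train.times:
        i = signal.time_to_index(t)
        keep[max(0, i - guard) : i + guard + 1] = False
    rest = signal.samples[keep]
    if rest.size == 0:
        raise ValidationError("no spike-free samples left after guarding")
    return float(1.4826 * np.median(np.abs(rest - np.median(rest))))


def dft_reconstruct(waveform, n_components: int = 8, fs: float | None = None):
    """Reconstruct a waveform from its lowest DFT frequencies.

    The waveform (N samples) is decomposed by DFT and the first
    ``n_components`` nonzero frequencies (bin k at frequency k*fs/N) are
    summed as sinusoids with the DFT amplitudes and phases.  DC is
    excluded: band-passed waveforms carry no offset.  For the default
    88-sample 2 ms window the first eight bins span 0.5-4 kHz.

    Returns the reconstructed waveform (same length, zero mean).
    """
    x = _as_samples(waveform)
    n = x.size
    if not (1 <= n_components <= n // 2):
        raise ValidationError(f"n_components must lie in [1, {n // 2}]")
    spectrum = np.fft.rfft(x)
    t = np.arange(n)
    recon = np.zeros(n)
    for k in range(1, n_components + 1):
        coeff = spectrum[k]
        scale = 1.0 / n if (n % 2 == 0 and k == n // 2) else 2.0 / n
        recon += scale * np.abs(coeff) * np.cos(2 * np.pi * k * t / n + np.angle(coeff))
    return recon
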