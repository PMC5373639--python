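"""Filter design, application, and frequency/phase characterization.

Three phase classes of band-pass filter:

* ``NLP`` -- a causal Butterworth, realized as cascaded second-order
  sections; its nonlinear phase response delays different frequencies by
  different amounts.
* ``ZP`` -- the same Butterworth applied forward and backward, cancelling
  the phase response and squaring the magnitude response.
* ``LP`` -- a symmetric Hamming-window FIR whose phase is exactly linear
  (constant group delay of order/2 samples).
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .types import ContinuousSignal, FilterRealization, FilterSpec, ValidationError

__all__ = [
    "design_filter",
    "apply_causal",
    "apply_zero_phase",
    "apply_filter",
    "phase_response",
    "group_delay",
    "magnitude_response",
]

_DENSE_GRID = 8192  # frequency-grid points to Nyquist for unwrapping


def design_filter(spec: FilterSpec) -> FilterRealization:
    """Realize a FilterSpec as stable SOS cascades or symmetric FIR taps."""
    if spec.family == "butterworth":
        sos = sps.butter(
            spec.order // 2, spec.band, btype="bandpass", fs=spec.fs, output="sos"
        )
        return FilterRealization(spec=spec, sos=sos)
    # Hamming-window FIR band-pass; order N means N+1 symmetric taps
    taps = sps.firwin(
        spec.order + 1, spec.band, pass_zero=False, window="hamming", fs=spec.fs
    )
    return FilterRealization(spec=spec, taps=taps)


def _check_fs(signal: ContinuousSignal, filt: FilterRealization) -> None:
    if not np.isclose(signal.fs, filt.spec.fs):
        raise ValidationError(
            f"signal fs {signal.fs} != filter fs {filt.spec.fs}"
        )


def apply_causal(signal: ContinuousSignal, filt: FilterRealization) -> ContinuousSignal:
    """Single causal pass with zero initial conditions (length preserved)."""
    _check_fs(signal, filt)
    if filt.is_recursive:
        out = sps.sosfilt(filt.sos, signal.samples)
    else:
        out = sps.lfilter(filt.taps, [1.0], signal.samples)
    return ContinuousSignal(samples=out, fs=signal.fs, t0=signal.t0)


def apply_zero_phase(signal: ContinuousSignal, filt: FilterRealization) -> ContinuousSignal:
    """Forward-backward application: zero net phase, |H|^2 net magnitude.

    Edges are handled by odd-symmetric reflection padding (scipy's
    ``sosfiltfilt`` default, 3x the per-section coefficient count).
    """
    _check_fs(signal, filt)
    if not filt.is_recursive:
        raise ValidationError("zero-phase application requires a recursive realization")
    out = sps.sosfiltfilt(filt.sos, signal.samples)
    return ContinuousSignal(samples=out, fs=signal.fs, t0=signal.t0)


def apply_filter(signal: ContinuousSignal, filt: FilterRealization) -> ContinuousSignal:
    """Dispatch on the spec's phase class (NLP/LP causal, ZP bidirectional)."""
    if filt.spec.phase_class == "ZP":
        return apply_zero_phase(signal, filt)
    return apply_causal(signal, filt)


def _dense_response(filt: FilterRealization) -> tuple[np.ndarray, np.ndarray]:
    if filt.is_recursive:
        freqs, h = sps.sosfreqz(filt.sos, worN=_DENSE_GRID, fs=filt.spec.fs)
    else:
        freqs, h = sps.freqz(filt.taps, worN=_DENSE_GRID, fs=filt.spec.fs)
    return freqs, h


def _check_freqs(filt: FilterRealization, freqs: np.ndarray) -> np.ndarray:
    freqs = np.asarray(freqs, dtype=np.float64)
    if np.any(freqs <= 0) or np.any(freqs >= filt.spec.fs / 2):
        raise ValidationError("frequencies must lie in (0, fs/2)")
    return freqs


def phase_response(filt: FilterRealization, freqs) -> np.ndarray:
    """Unwrapped phase (radians) at the requested frequencies.

    The phase of the bidirectional (ZP) class is identically zero.  Causal
    classes are evaluated on a dense grid, unwrapped with standard 2*pi
    jump removal, and linearly interpolated.
    """
    freqs = _check_freqs(filt, freqs)
    if filt.spec.phase_class == "ZP":
        return np.zeros_like(freqs)
    grid, h = _dense_response(filt)
    phase = np.unwrap(np.angle(h))
    return np.interp(freqs, grid, phase)


def group_delay(filt: FilterRealization, freqs) -> np.ndarray:
    """-dphi/domega (in samples), from numeric differentiation of the
    unwrapped dense-grid phase."""
    freqs = _check_freqs(filt, freqs)
    if filt.spec.phase_class == "ZP":
        return np.zeros_like(freqs)
    grid, h = _dense_response(filt)
    phase = np.unwrap(np.angle(h))
    omega = 2 * np.pi * grid / filt.spec.fs  # rad/sample
    delay = -np.gradient(phase, omega)
    return np.interp(freqs, grid, delay)


def magnitude_response(filt: FilterRealization, freqs) -> np.ndarray:
    """|H(f)| for causal classes; |H(f)|^2 for the bidirectional ZP class."""
    freqs = _check_freqs(filt, freqs)
    if filt.is_recursive:
        _, h = sps.sosfreqz(filt.sos, worN=freqs, fs=filt.spec.fs)
    else:
        _, h = sps.freqz(filt.taps, worN=freqs, fs=filt.spec.fs)
    mag = np.abs(h)
    if filt.spec.phase_class == "ZP":
        return mag**2
    return mag
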