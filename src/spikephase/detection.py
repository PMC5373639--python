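"""Threshold-crossing spike detection and ROC evaluation.

The false-negative probability (beta) is the fraction of true spikes
without a matched detection; the false-positive probability (alpha)
normalizes unmatched detections by the number of spike-free time bins, so
both errors are probabilities on comparable scales.
"""

from __future__ import annotations

import numpy as np

from .types import ContinuousSignal, DetectionScore, RocCurve, SpikeTrain, ValidationError

__all__ = [
    "detect_threshold",
    "score_detection",
    "default_thresholds",
    "roc",
    "detection_error",
]


def detect_threshold(
    signal: ContinuousSignal,
    threshold: float,
    polarity: str = "negative",
    dead_time_ms: float = 1.0,
) -> SpikeTrain:
    """Events at first threshold crossings, with dead-time suppression.

    For negative polarity (the default: extracellular troughs), an event
    fires at each sample where the signal first drops below ``threshold``;
    further events are suppressed for ``dead_time_ms``.
    """
    if dead_time_ms < 0:
        raise ValidationError("dead_time_ms must be >= 0")
    if polarity not in ("negative", "positive"):
        raise ValidationError("polarity must be 'negative' or 'positive'")
    x = signal.samples if polarity == "positive" else -signal.samples
    thr = threshold if polarity == "positive" else -threshold
    above = x > thr
    crossings = np.flatnonzero(above & ~np.concatenate([[False], above[:-1]]))
    dead = int(round(dead_time_ms * signal.fs / 1000))
    if dead > 1 and crossings.size:
        kept = [crossings[0]]
        for c in crossings[1:]:
            if c - kept[-1] >= dead:
                kept.append(c)
        crossings = np.asarray(kept)
    times = signal.t0 + crossings / signal.fs
    return SpikeTrain(times=times, duration=signal.duration)


def _greedy_match(detected: np.ndarray, truth: np.ndarray, tol: float) -> tuple[int, int]:
    """Greedy closest-first one-to-one matching within ``tol`` seconds.

    Returns (n_matched_detections, n_matched_truth); the two are equal.
    """
    if detected.size == 0 or truth.size == 0:
        return 0, 0
    right = np.searchsorted(truth, detected)
    candidates = []
    for i, t_det in enumerate(detected):
        for j in (right[i] - 1, right[i]):
            if 0 <= j < truth.size:
                gap = abs(truth[j] - t_det)
                if gap <= tol:
                    candidates.append((gap, i, j))
    candidates.sort()
    used_det = np.zeros(detected.size, dtype=bool)
    used_truth = np.zeros(truth.size, dtype=bool)
    n = 0
    for _, i, j in candidates:
        if not used_det[i] and not used_truth[j]:
            used_det[i] = used_truth[j] = True
            n += 1
    return n, n


def score_detection(
    detected: SpikeTrain,
    truth: SpikeTrain,
    tol_ms: float = 0.5,
    duration: float | None = None,
    bin_ms: float = 1.0,
    threshold: float = np.nan,
) -> DetectionScore:
    """Alpha/beta error probabilities of a detection against ground truth.

    Detections are matched one-to-one to true spikes (closest first,
    within ``+/- tol_ms``).  ``beta`` is the unmatched-truth fraction;
    ``alpha`` divides unmatched detections by the number of ``bin_ms``
    bins containing no true spike (clipped to 1).
    """
    if tol_ms <= 0 or bin_ms <= 0:
        raise ValidationError("tol_ms and bin_ms must be positive")
    duration = truth.duration if duration is None else duration
    if duration <= 0:
        raise ValidationError("duration must be positive")
    if len(truth) == 0:
        raise ValidationError("truth train is empty")
    n_matched, _ = _greedy_match(detected.times, truth.times, tol_ms / 1000.0)
    beta = 1.0 - n_matched / len(truth)
    bin_s = bin_ms / 1000.0
    n_bins = int(np.floor(duration / bin_s))
    occupied = np.unique(np.floor(truth.times / bin_s).astype(int))
    n_opportunities = n_bins - occupied.size
    if n_opportunities <= 0:
        raise ValidationError("no spike-free bins to normalize alpha")
    alpha = min(1.0, (len(detected) - n_matched) / n_opportunities)
    return DetectionScore(alpha=alpha, beta=beta, threshold=threshold)


def default_thresholds(
    signal: ContinuousSignal, noise_std: float, n: int = 40, polarity: str = "negative"
) -> np.ndarray:
    """Grid of ``n`` thresholds from 0.5 * noise_std to 1.2x max excursion."""
    if polarity == "negative":
        excursion = abs(float(np.min(signal.samples)))
        return -np.linspace(0.5 * noise_std, 1.2 * excursion, n)
    excursion = abs(float(np.max(signal.samples)))
    return np.linspace(0.5 * noise_std, 1.2 * excursion, n)


def roc(
    signal: ContinuousSignal,
    truth: SpikeTrain,
    thresholds,
    tol_ms: float = 0.5,
    bin_ms: float = 1.0,
    polarity: str = "negative",
    dead_time_ms: float = 0.0,
) -> RocCurve:
    """One (alpha, 1-beta) point per threshold, plus (0,0)/(1,1) anchors.

    The threshold sweep runs without dead-time suppression by default:
    with a dead time, a noise crossing shortly before a spike suppresses
    the spike's own crossing while itself falling outside the matching
    tolerance (which is centered on the spike time, not the crossing),
    so beta rises again at permissive thresholds and the operating points
    are no longer monotone in the threshold.
    """
    thresholds = np.asarray(thresholds, dtype=np.float64)
    if thresholds.size < 2:
        raise ValidationError("need at least 2 thresholds")
    pts = [(0.0, 0.0, np.nan), (1.0, 1.0, np.nan)]
    for thr in thresholds:
        detected = detect_threshold(signal, thr, polarity=polarity, dead_time_ms=dead_time_ms)
        s = score_detection(detected, truth, tol_ms, signal.duration, bin_ms, threshold=thr)
        pts.append((s.alpha, 1.0 - s.beta, thr))
    pts.sort(key=lambda p: (p[0], p[1]))
    arr = np.asarray(pts)
    return RocCurve(points=arr[:, :2], thresholds=arr[:, 2])


def detection_error(curve: RocCurve) -> float:
    """1 - AUC (trapezoidal) of the ROC curve."""
    if curve.points.shape[0] < 2:
        raise ValidationError("need at least 2 ROC points")
    auc = float(np.trapezoid(curve.points[:, 1], curve.points[:, 0]))
    return 1.0 - auc
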