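"""Readers and writers for signals, events, segments, and filter configs.

Formats are deliberately language-neutral: raw little-endian float32 binary
with a JSON sidecar for continuous signals, CSV for events and segments,
YAML/JSON for filter and simulation configs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import (
    ContinuousSignal,
    FilterSpec,
    FormatError,
    SegmentSet,
    SpikeTrain,
    ValidationError,
)

__all__ = [
    "save_signal",
    "load_signal",
    "save_events",
    "load_events",
    "save_segments",
    "load_segments",
    "load_filter_spec",
    "save_filter_spec",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def save_signal(signal: ContinuousSignal, path: str | Path) -> None:
    """Write raw little-endian float32 samples plus a JSON sidecar."""
    path = Path(path)
    samples = signal.samples.astype("<f4")
    path.write_bytes(samples.tobytes())
    sidecar = {
        "fs_hz": signal.fs,
        "n_samples": signal.n_samples,
        "t0_s": signal.t0,
        "dtype": "float32-le",
        "units": "uV",
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2) + "\n")


def load_signal(path: str | Path) -> ContinuousSignal:
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}")
    try:
        meta = json.loads(sidecar_path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed sidecar {sidecar_path}: {exc}") from exc
    for key in ("fs_hz", "n_samples"):
        if key not in meta:
            raise FormatError(f"sidecar {sidecar_path} missing key {key!r}")
    raw = path.read_bytes()
    if len(raw) != 4 * int(meta["n_samples"]):
        raise FormatError(
            f"{path}: file holds {len(raw) // 4} float32 samples, "
            f"sidecar declares {meta['n_samples']}"
        )
    samples = np.frombuffer(raw, dtype="<f4").astype(np.float64)
    if not np.all(np.isfinite(samples)):
        raise ValidationError(f"{path}: non-finite samples")
    return ContinuousSignal(samples=samples, fs=float(meta["fs_hz"]), t0=float(meta.get("t0_s", 0.0)))


def save_events(train: SpikeTrain, path: str | Path) -> None:
    """Events CSV with a single full-precision ``time_s`` column."""
    df = pd.DataFrame({"time_s": train.times})
    df.to_csv(path, index=False, float_format="%.17g")
    # duration kept in a sidecar so the round trip is lossless
    meta = {"duration_s": train.duration}
    _sidecar_path(Path(path)).write_text(json.dumps(meta) + "\n")


def load_events(path: str | Path, duration: float | None = None) -> SpikeTrain:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if "time_s" not in df.columns:
        raise FormatError(f"{path}: expected a 'time_s' column, got {list(df.columns)}")
    times = df["time_s"].to_numpy(dtype=np.float64)
    if times.size and np.any(times < 0):
        raise ValidationError(f"{path}: negative spike times")
    if times.size and np.any(np.diff(times) <= 0):
        raise ValidationError(f"{path}: spike times not strictly increasing")
    if duration is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            duration = float(json.loads(sidecar.read_text())["duration_s"])
        else:
            duration = float(times[-1]) if times.size else 1.0
    return SpikeTrain(times=times, duration=duration)


def save_segments(segset: SegmentSet, path: str | Path) -> None:
    """Segments CSV (one row per snippet) with a JSON metadata sidecar."""
    path = Path(path)
    pd.DataFrame(segset.segments).to_csv(path, index=False, header=False, float_format="%.17g")
    meta = {
        "fs_hz": segset.fs,
        "align_index": segset.align_index,
        "window_ms": segset.window_ms,
    }
    if segset.source_times is not None:
        meta["source_times_s"] = segset.source_times.tolist()
    _sidecar_path(path).write_text(json.dumps(meta) + "\n")


def load_segments(path: str | Path) -> SegmentSet:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    segments = pd.read_csv(path, header=None, float_precision="round_trip").to_numpy(
        dtype=np.float64
    )
    source_times = meta.get("source_times_s")
    return SegmentSet(
        segments=segments,
        fs=float(meta["fs_hz"]),
        align_index=int(meta["align_index"]),
        window_ms=float(meta["window_ms"]),
        source_times=None if source_times is None else np.asarray(source_times),
    )


def save_filter_spec(spec: FilterSpec, path: str | Path) -> None:
    payload = {
        "phase_class": spec.phase_class,
        "family": spec.family,
        "order": spec.order,
        "band": list(spec.band),
        "fs": spec.fs,
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_filter_spec(path: str | Path) -> FilterSpec:
    path = Path(path)
    try:
        payload = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise FormatError(f"malformed config {path}: {exc}") from exc
    if not isinstance(payload, dict):
        raise FormatError(f"{path}: expected a mapping")
    try:
        return FilterSpec(
            phase_class=payload["phase_class"],
            family=payload["family"],
            order=int(payload["order"]),
            band=tuple(payload["band"]),
            fs=float(payload["fs"]),
        )
    except KeyError as exc:
        raise FormatError(f"{path}: missing key {exc}") from exc
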