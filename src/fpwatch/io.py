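"""Readers and writers for the package's signal and event formats.

Signals use a documented lossless native layout: a raw float32 little-endian
matrix (``<base>.dat``, C-order, channels x samples, microvolts) next to a
JSON sidecar (``<base>.json``) carrying sample rate, array geometry, channel
labels and the live-channel mask. Event trains are plain CSV with commented
header metadata; times are stored in seconds at microsecond precision
(sub-microsecond digits are meaningless at 2 kHz sampling).
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from .containers import ArrayGeometry, EventTrain, GroundTruth, HDSEMGRecording

__all__ = [
    "HDSEMGRecording",
    "EventTrain",
    "read_recording",
    "write_recording",
    "read_event_train",
    "write_event_train",
    "write_ground_truth",
    "read_ground_truth",
]

log = logging.getLogger("fpwatch.io")

_REC_FORMAT = "fpwatch-recording-v1"
_EVT_FORMAT = "fpwatch-events-v1"
_TIME_DECIMALS = 6      # 1 microsecond


def _rec_paths(path: str | Path) -> tuple[Path, Path]:
    p = Path(path)
    if p.suffix in (".json", ".dat"):
        p = p.with_suffix("")
    return p.with_suffix(".dat"), p.with_suffix(".json")


def write_recording(rec: HDSEMGRecording, path: str | Path) -> Path:
    """Write the native binary + JSON-sidecar layout; returns the sidecar path."""
    dat, sidecar = _rec_paths(path)
    data = np.ascontiguousarray(rec.signal, dtype="<f4")
    data.tofile(dat)
    meta = {
        "format": _REC_FORMAT,
        "dtype": "float32",
        "byte_order": "little",
        "units": "uV",
        "name": rec.name,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "sample_rate_hz": rec.sample_rate_hz,
        "live_mask": rec.live_mask.astype(int).tolist(),
        "geometry": rec.geometry.to_dict(),
        "signal_file": dat.name,
    }
    sidecar.write_text(json.dumps(meta, indent=1))
    return sidecar


def read_recording(path: str | Path) -> HDSEMGRecording:
    """Read a native-layout recording; bit-exact round trip with write_recording."""
    dat, sidecar = _rec_paths(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing geometry sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    if meta.get("format") != _REC_FORMAT:
        raise ValueError(f"{sidecar} is not a {_REC_FORMAT} sidecar")
    geometry = ArrayGeometry.from_dict(meta["geometry"])
    n_ch, n_s = int(meta["n_channels"]), int(meta["n_samples"])
    if geometry.n_channels != n_ch:
        raise ValueError(
            f"sidecar lists {n_ch} channels but geometry has {geometry.n_channels}")
    dat_file = sidecar.parent / meta.get("signal_file", dat.name)
    raw = np.fromfile(dat_file, dtype="<f4")
    if raw.size != n_ch * n_s:
        raise ValueError(
            f"{dat_file} holds {raw.size} samples, expected {n_ch}x{n_s}")
    rec = HDSEMGRecording(
        signal=raw.reshape(n_ch, n_s),
        sample_rate_hz=float(meta["sample_rate_hz"]),
        geometry=geometry,
        live_mask=np.asarray(meta["live_mask"], dtype=bool),
        name=meta.get("name", ""),
    )
    log.info("read %s: %d channels (%d live), %.1f s @ %g Hz",
             dat_file, rec.n_channels, int(rec.live_mask.sum()),
             rec.duration_s, rec.sample_rate_hz)
    return rec


def _write_times_csv(path: Path, header: dict, times: np.ndarray,
                     source_ids: np.ndarray | None) -> None:
    lines = [f"# {k}: {v}" for k, v in header.items()]
    if source_ids is None:
        lines.append("time_s")
        lines += [f"{t:.{_TIME_DECIMALS}f}" for t in times]
    else:
        lines.append("time_s,source_id")
        lines += [f"{t:.{_TIME_DECIMALS}f},{s}" for t, s in zip(times, source_ids)]
    path.write_text("\n".join(lines) + "\n")


def _read_times_csv(path: str | Path) -> tuple[dict, np.ndarray, np.ndarray | None]:
    p = Path(path)
    header: dict[str, str] = {}
    times: list[float] = []
    ids: list[int] = []
    columns: list[str] | None = None
    for line in p.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                k, v = body.split(":", 1)
                header[k.strip()] = v.strip()
            continue
        if columns is None:
            columns = [c.strip() for c in line.split(",")]
            if "time_s" not in columns:
                raise ValueError(f"{p}: missing required column time_s")
            continue
        fields = line.split(",")
        times.append(float(fields[columns.index("time_s")]))
        if "source_id" in columns:
            ids.append(int(fields[columns.index("source_id")]))
    t = np.asarray(times, dtype=float)
    if t.size and (np.any(t < 0) or np.any(np.diff(t) <= 0)):
        raise ValueError(f"{p}: times must be non-negative and strictly increasing")
    return header, t, (np.asarray(ids, dtype=int) if ids else None)


def write_event_train(train: EventTrain, path: str | Path) -> Path:
    """Write a detected/analysed FP train as CSV with commented metadata."""
    p = Path(path)
    _write_times_csv(p, {
        "format": _EVT_FORMAT,
        "muscle_id": train.muscle_id,
        "recording_duration_s": f"{train.recording_duration_s:.{_TIME_DECIMALS}f}",
    }, np.round(train.times, _TIME_DECIMALS), None)
    return p


def read_event_train(path: str | Path) -> EventTrain:
    """Read an event-train CSV; rejects unsorted or negative times."""
    header, times, _ = _read_times_csv(path)
    if "recording_duration_s" not in header:
        raise ValueError(f"{path}: header comment recording_duration_s is required")
    train = EventTrain(
        muscle_id=header.get("muscle_id", Path(path).stem),
        times=times,
        recording_duration_s=float(header["recording_duration_s"]),
    )
    log.info("read %s: N=%d events over %.1f s (%.2f/min)",
             path, train.n, train.recording_duration_s, train.rate_per_min)
    return train


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    """Ground-truth CSV with time_s and source_id columns."""
    p = Path(path)
    _write_times_csv(p, {
        "format": _EVT_FORMAT,
        "recording_duration_s": f"{truth.duration_s:.{_TIME_DECIMALS}f}",
    }, np.round(truth.event_times, _TIME_DECIMALS), truth.source_ids)
    return p


def read_ground_truth(path: str | Path) -> GroundTruth:
    header, times, ids = _read_times_csv(path)
    if "recording_duration_s" not in header:
        raise ValueError(f"{path}: header comment recording_duration_s is required")
    if ids is None:
        ids = np.zeros(times.size, dtype=int)
    return GroundTruth(event_times=times, source_ids=ids,
                       duration_s=float(header["recording_duration_s"]))
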