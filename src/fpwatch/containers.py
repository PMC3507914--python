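"""Core in-memory containers shared across the pipeline.

All times are seconds (float, 0 at the first sample), amplitudes are
microvolts, and array coordinates are millimetres.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ArrayGeometry", "GroundTruth", "EventTrain", "HDSEMGRecording"]


@dataclass(eq=False)
class ArrayGeometry:
    """Electrode-array layout: channel positions on the skin plane.

    Two stock layouts mirror the hardware used in FP surveillance studies:
    an 8x8 flexible grid with 4 mm inter-electrode distance (intrinsic hand
    muscles) and a 20-channel linear bar with 5 mm pitch (biceps brachii).
    """

    layout: str                      # "grid" | "linear"
    pitch_mm: float
    positions_mm: np.ndarray         # (n_channels, 2) float, x/y in mm
    labels: tuple[str, ...]
    grid_shape: tuple[int, int] | None = None   # (rows, cols) for layout=="grid"

    def __post_init__(self) -> None:
        if self.layout not in ("grid", "linear"):
            raise ValueError(f"unknown layout {self.layout!r}")
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        if self.positions_mm.ndim != 2 or self.positions_mm.shape[1] != 2:
            raise ValueError("positions_mm must be an (n_channels, 2) array")
        n = self.positions_mm.shape[0]
        if len(self.labels) != n:
            raise ValueError(f"{len(self.labels)} labels for {n} positions")
        if self.layout == "grid":
            if self.grid_shape is None or self.grid_shape[0] * self.grid_shape[1] != n:
                raise ValueError("grid layout requires grid_shape with rows*cols == n_channels")
        # positions must be pairwise distinct
        uniq = np.unique(self.positions_mm, axis=0)
        if uniq.shape[0] != n:
            raise ValueError("channel positions must be pairwise distinct")
        if self.pitch_mm <= 0:
            raise ValueError("pitch_mm must be positive")

    @property
    def n_channels(self) -> int:
        return self.positions_mm.shape[0]

    @classmethod
    def grid(cls, rows: int = 8, cols: int = 8, pitch_mm: float = 4.0) -> "ArrayGeometry":
        """8x8 flexible grid by default (4 mm IED)."""
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        pos = np.column_stack([cc.ravel() * pitch_mm, rr.ravel() * pitch_mm]).astype(float)
        labels = tuple(f"G-r{r + 1}c{c + 1}" for r in range(rows) for c in range(cols))
        return cls("grid", pitch_mm, pos, labels, grid_shape=(rows, cols))

    @classmethod
    def linear(cls, n_channels: int = 20, pitch_mm: float = 5.0) -> "ArrayGeometry":
        """20-channel linear bar array by default (5 mm pitch)."""
        pos = np.column_stack([np.arange(n_channels) * pitch_mm,
                               np.zeros(n_channels)]).astype(float)
        labels = tuple(f"L-{i + 1:02d}" for i in range(n_channels))
        return cls("linear", pitch_mm, pos, labels)

    @property
    def centroid_mm(self) -> np.ndarray:
        return self.positions_mm.mean(axis=0)

    def to_dict(self) -> dict:
        return {
            "layout": self.layout,
            "pitch_mm": self.pitch_mm,
            "positions_mm": self.positions_mm.tolist(),
            "labels": list(self.labels),
            "grid_shape": list(self.grid_shape) if self.grid_shape else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArrayGeometry":
        return cls(
            layout=d["layout"],
            pitch_mm=float(d["pitch_mm"]),
            positions_mm=np.asarray(d["positions_mm"], dtype=float),
            labels=tuple(d["labels"]),
            grid_shape=tuple(d["grid_shape"]) if d.get("grid_shape") else None,
        )


def _check_times(times: np.ndarray, duration_s: float, what: str) -> None:
    if times.size:
        if times[0] < 0 or times[-1] > duration_s:
            raise ValueError(f"{what} must lie within [0, {duration_s}] s")
        if np.any(np.diff(times) <= 0):
            raise ValueError(f"{what} must be strictly increasing")


@dataclass(eq=False)
class GroundTruth:
    """Simulated FP occurrence times t(1) < t(2) < ... < t(N) with source labels."""

    event_times: np.ndarray          # seconds, strictly increasing
    source_ids: np.ndarray           # int label per event (simulated motor unit)
    duration_s: float

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        self.source_ids = np.asarray(self.source_ids, dtype=int)
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.event_times.shape != self.source_ids.shape:
            raise ValueError("event_times and source_ids must have equal length")
        _check_times(self.event_times, self.duration_s, "event_times")

    @property
    def n_events(self) -> int:
        return int(self.event_times.size)

    def to_event_train(self, muscle_id: str = "truth") -> "EventTrain":
        return EventTrain(muscle_id=muscle_id, times=self.event_times.copy(),
                          recording_duration_s=self.duration_s)


@dataclass(eq=False)
class EventTrain:
    """One muscle's FP occurrence times plus the recording duration."""

    muscle_id: str
    times: np.ndarray                # seconds, strictly increasing
    recording_duration_s: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.recording_duration_s <= 0:
            raise ValueError("recording_duration_s must be positive")
        _check_times(self.times, self.recording_duration_s, "times")

    @property
    def n(self) -> int:
        return int(self.times.size)

    @property
    def rate_per_min(self) -> float:
        return self.n / self.recording_duration_s * 60.0


@dataclass(eq=False)
class HDSEMGRecording:
    """Multi-channel surface-EMG signal matrix with array geometry and channel mask."""

    signal: np.ndarray               # (n_channels, n_samples), microvolts
    sample_rate_hz: float
    geometry: ArrayGeometry
    live_mask: np.ndarray            # bool per channel; False == disconnected
    name: str = ""

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal))
        self.live_mask = np.asarray(self.live_mask, dtype=bool)
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.signal.shape[0] != self.geometry.n_channels:
            raise ValueError(
                f"signal has {self.signal.shape[0]} channels but geometry has "
                f"{self.geometry.n_channels}")
        if self.live_mask.shape != (self.signal.shape[0],):
            raise ValueError("live_mask must have one entry per channel")
        if not self.live_mask.any():
            raise ValueError("no live channels")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz
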