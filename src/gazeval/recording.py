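"""Vendor-neutral recording data model and interchange I/O.

A recording directory holds ``gaze.csv`` (timestamp_ms, frame_idx,
gaze_x_px, gaze_y_px — empty cells mean a missing sample, never zero),
``markers.csv`` (frame_idx, marker_id, x1..y4 corner pixels in
top-left/top-right/bottom-right/bottom-left order), ``episodes.csv``
(start_ms, end_ms, label) and optionally ``calibration.json``.
Native exports of specific eye trackers are converted to this layout
upstream; this module never parses vendor formats.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .camera import CameraCalibration

__all__ = [
    "GazeSample",
    "MarkerObservation",
    "EpisodeAnnotation",
    "Recording",
    "RecordingError",
    "read_recording",
    "write_recording",
    "slice_episode",
    "data_loss",
]


class RecordingError(ValueError):
    """Malformed recording content (unsorted timestamps, overlapping
    episodes, bad corner counts); the message carries row context."""


@dataclass(frozen=True)
class GazeSample:
    timestamp: float  # ms
    frame_idx: int
    gaze_px: tuple[float, float] | None  # None = missing sample

    @property
    def missing(self) -> bool:
        return self.gaze_px is None


@dataclass(frozen=True)
class MarkerObservation:
    frame_idx: int
    marker_id: int
    corners: np.ndarray  # (4, 2) px, TL TR BR BL in the marker frame

    def __post_init__(self) -> None:
        c = np.asarray(self.corners, dtype=float)
        if c.shape != (4, 2):
            raise RecordingError(
                f"marker {self.marker_id} frame {self.frame_idx}: "
                f"need 4 corners, got shape {c.shape}"
            )
        object.__setattr__(self, "corners", c)


@dataclass(frozen=True)
class EpisodeAnnotation:
    start: float  # ms, inclusive
    end: float  # ms, exclusive
    label: str = "validation"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise RecordingError(
                f"episode '{self.label}': start {self.start} must be < end {self.end}"
            )


@dataclass
class Recording:
    """Timestamped gaze in scene-video pixels plus per-frame fiducial
    marker corner observations and validation-episode annotations."""

    gaze: list[GazeSample] = field(default_factory=list)
    markers: list[MarkerObservation] = field(default_factory=list)
    episodes: list[EpisodeAnnotation] = field(default_factory=list)
    calibration: CameraCalibration | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ts = np.array([s.timestamp for s in self.gaze])
        if len(ts) > 1 and not np.all(np.diff(ts) > 0):
            bad = int(np.argmax(np.diff(ts) <= 0)) + 1
            raise RecordingError(
                f"gaze row {bad}: timestamps must be strictly increasing"
            )
        eps = sorted(self.episodes, key=lambda e: e.start)
        for a, b in zip(eps, eps[1:]):
            if b.start < a.end:
                raise RecordingError(
                    f"episodes '{a.label}' and '{b.label}' overlap "
                    f"([{a.start}, {a.end}) vs [{b.start}, {b.end}))"
                )

    @property
    def sampling_rate(self) -> float:
        """Median sampling rate in Hz, derived from gaze timestamps."""
        ts = np.array([s.timestamp for s in self.gaze])
        if len(ts) < 2:
            return float("nan")
        return float(1000.0 / np.median(np.diff(ts)))

    # array views used by the mapping stage
    def gaze_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(timestamps (N,), frame_idx (N,), gaze_px (N,2) with NaN)."""
        n = len(self.gaze)
        ts = np.empty(n)
        fi = np.empty(n, dtype=int)
        px = np.full((n, 2), np.nan)
        for i, s in enumerate(self.gaze):
            ts[i] = s.timestamp
            fi[i] = s.frame_idx
            if s.gaze_px is not None:
                px[i] = s.gaze_px
        return ts, fi, px


def write_recording(rec: Recording, dir_path: str | Path) -> None:
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    ts, fi, px = rec.gaze_arrays()
    pd.DataFrame(
        {
            "timestamp_ms": ts,
            "frame_idx": fi,
            "gaze_x_px": px[:, 0],
            "gaze_y_px": px[:, 1],
        }
    ).to_csv(d / "gaze.csv", index=False)
    rows = []
    for m in rec.markers:
        row = {"frame_idx": m.frame_idx, "marker_id": m.marker_id}
        for k, (x, y) in enumerate(m.corners, start=1):
            row[f"x{k}"], row[f"y{k}"] = x, y
        rows.append(row)
    cols = ["frame_idx", "marker_id"] + [f"{a}{k}" for k in range(1, 5) for a in "xy"]
    pd.DataFrame(rows, columns=cols).to_csv(d / "markers.csv", index=False)
    pd.DataFrame(
        [{"start_ms": e.start, "end_ms": e.end, "label": e.label} for e in rec.episodes],
        columns=["start_ms", "end_ms", "label"],
    ).to_csv(d / "episodes.csv", index=False)
    if rec.calibration is not None:
        rec.calibration.to_json(d / "calibration.json")
    if rec.meta:
        (d / "meta.json").write_text(json.dumps(rec.meta, indent=1))


def read_recording(dir_path: str | Path) -> Recording:
    d = Path(dir_path)
    gf = pd.read_csv(d / "gaze.csv")
    gaze = []
    for _, r in gf.iterrows():
        x, y = r["gaze_x_px"], r["gaze_y_px"]
        missing = pd.isna(x) or pd.isna(y)
        gaze.append(
            GazeSample(
                timestamp=float(r["timestamp_ms"]),
                frame_idx=int(r["frame_idx"]),
                gaze_px=None if missing else (float(x), float(y)),
            )
        )
    markers = []
    mpath = d / "markers.csv"
    if mpath.exists():
        mf = pd.read_csv(mpath)
        for _, r in mf.iterrows():
            corners = np.array(
                [[r[f"x{k}"], r[f"y{k}"]] for k in range(1, 5)], dtype=float
            )
            markers.append(
                MarkerObservation(
                    frame_idx=int(r["frame_idx"]),
                    marker_id=int(r["marker_id"]),
                    corners=corners,
                )
            )
    episodes = []
    epath = d / "episodes.csv"
    if epath.exists():
        ef = pd.read_csv(epath)
        episodes = [
            EpisodeAnnotation(
                start=float(r["start_ms"]), end=float(r["end_ms"]), label=str(r["label"])
            )
            for _, r in ef.iterrows()
        ]
    calib = None
    cpath = d / "calibration.json"
    if cpath.exists():
        calib = CameraCalibration.from_json(cpath)
    meta = {}
    metapath = d / "meta.json"
    if metapath.exists():
        meta = json.loads(metapath.read_text())
    return Recording(
        gaze=gaze, markers=markers, episodes=episodes, calibration=calib, meta=meta
    )


def slice_episode(rec: Recording, ep: EpisodeAnnotation) -> Recording:
    """Restrict a recording to the half-open interval [start, end).

    Marker observations are kept for the frames the remaining gaze
    samples reference, so downstream per-episode results are
    independent of other episodes.  An episode outside the recorded
    span yields an (explicitly) empty recording.
    """
    gaze = [s for s in rec.gaze if ep.start <= s.timestamp < ep.end]
    frames = {s.frame_idx for s in gaze}
    markers = [m for m in rec.markers if m.frame_idx in frames]
    return Recording(
        gaze=gaze,
        markers=markers,
        episodes=[ep],
        calibration=rec.calibration,
        meta=dict(rec.meta),
    )


def data_loss(rec: Recording, ep: EpisodeAnnotation) -> float:
    """Percentage of gaze samples within the episode with no valid
    coordinates.  NaN when the episode contains no samples."""
    inside = [s for s in rec.gaze if ep.start <= s.timestamp < ep.end]
    if not inside:
        return float("nan")
    missing = sum(s.missing for s in inside)
    return 100.0 * missing / len(inside)
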