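"""Per-frame poster geometry and scene-pixel to poster-plane gaze mapping.

Two viewing-position modes are supported.  In ``fixed_distance`` mode
the eye is assumed to sit exactly in front of the poster centre at a
configured perpendicular distance, with the poster perpendicular to the
line of sight.  In ``pose_estimated`` mode the scene-camera pose
relative to the poster is recovered from the fiducial-marker array for
every frame (requires a camera calibration) and the eye is equated with
the scene-camera optical centre; an eye-to-camera offset can be
supplied when known, default zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal

import numpy as np

from .camera import (
    CameraCalibration,
    GeometryError,
    Homography,
    PlanarPose,
    estimate_homography,
    pose_from_homography,
    undistort_points,
)
from .poster import PosterSpec, marker_corners
from .recording import Recording

__all__ = [
    "FrameGeometry",
    "PosterGazeSample",
    "PosterGazeSeries",
    "frame_geometries",
    "fill_missing_geometry",
    "map_gaze",
]

Mode = Literal["fixed_distance", "pose_estimated"]


@dataclass
class FrameGeometry:
    """Homography (and pose, when calibrated) for one video frame."""

    frame_idx: int
    timestamp: float  # ms, median gaze timestamp of the frame
    homography: Homography | None = None
    pose: PlanarPose | None = None
    n_markers_used: int = 0
    reason: str = ""  # why geometry is missing, "" when present
    filled: bool = False  # True when copied from a neighbouring frame

    @property
    def valid(self) -> bool:
        return self.homography is not None


def frame_geometries(rec: Recording, poster: PosterSpec) -> list[FrameGeometry]:
    """Estimate per-frame homography (and pose when calibrated) from all
    detected markers with known ids, pooled into one correspondence set.

    Frames with no usable detections yield missing geometry with a
    reason, never a silent gap.  Marker ids absent from the poster
    specification are ignored.
    """
    ts, fi, _ = rec.gaze_arrays()
    frame_times: dict[int, float] = {}
    for f in np.unique(fi):
        frame_times[int(f)] = float(np.median(ts[fi == f]))

    by_frame: dict[int, list] = {}
    for m in rec.markers:
        by_frame.setdefault(m.frame_idx, []).append(m)

    geoms = []
    for f in sorted(frame_times):
        g = FrameGeometry(frame_idx=f, timestamp=frame_times[f])
        obs = by_frame.get(f, [])
        src, dst = [], []
        n_used = 0
        for o in obs:
            spec = poster.marker_by_id(o.marker_id)
            if spec is None:
                continue
            src.append(marker_corners(spec))
            dst.append(np.asarray(o.corners, dtype=float))
            n_used += 1
        if n_used == 0:
            g.reason = "no-markers"
            geoms.append(g)
            continue
        src_mm = np.vstack(src)
        dst_px = np.vstack(dst)
        if rec.calibration is not None:
            norm, conv = undistort_points(dst_px, rec.calibration)
            if not conv.all():
                g.reason = "undistort-failed"
                geoms.append(g)
                continue
            K = rec.calibration.matrix
            dst_ideal = norm @ np.diag([K[0, 0], K[1, 1]]) + np.array(
                [K[0, 2], K[1, 2]]
            )
        else:
            dst_ideal = dst_px
        try:
            g.homography = estimate_homography(src_mm, dst_ideal)
        except GeometryError as exc:
            g.reason = f"homography-failed: {exc}"
            geoms.append(g)
            continue
        g.n_markers_used = n_used
        if rec.calibration is not None:
            try:
                g.pose = pose_from_homography(g.homography, rec.calibration)
            except GeometryError:
                g.pose = None
        geoms.append(g)
    return geoms


def fill_missing_geometry(
    geoms: list[FrameGeometry], max_gap_ms: float = 100.0
) -> list[FrameGeometry]:
    """Fill marker-dropout gaps by nearest-in-time geometry.

    A maximal run of frames with missing geometry is filled from its
    nearest valid neighbour only when the enclosing time gap (last
    valid frame before to first valid frame after) does not exceed
    ``max_gap_ms``; longer dropouts stay missing.  Matrix entries are
    copied, never interpolated, because element-wise interpolation of a
    homography is not projectively sound.
    """
    out = [
        FrameGeometry(
            frame_idx=g.frame_idx,
            timestamp=g.timestamp,
            homography=g.homography,
            pose=g.pose,
            n_markers_used=g.n_markers_used,
            reason=g.reason,
            filled=g.filled,
        )
        for g in geoms
    ]
    valid_idx = [i for i, g in enumerate(out) if g.valid]
    if not valid_idx:
        return out
    i = 0
    n = len(out)
    while i < n:
        if out[i].valid:
            i += 1
            continue
        j = i
        while j < n and not out[j].valid:
            j += 1
        before = out[i - 1] if i > 0 and out[i - 1].valid else None
        after = out[j] if j < n else None
        gap_edges = [g.timestamp for g in (before, after) if g is not None]
        if before is not None and after is not None:
            gap = after.timestamp - before.timestamp
        elif gap_edges:
            # run at the series edge: measure to the single neighbour
            run_ts = [out[k].timestamp for k in range(i, j)]
            gap = max(abs(t - gap_edges[0]) for t in run_ts)
        else:
            gap = np.inf
        if gap <= max_gap_ms:
            for k in range(i, j):
                src = min(
                    (g for g in (before, after) if g is not None),
                    key=lambda g: abs(g.timestamp - out[k].timestamp),
                )
                out[k].homography = src.homography
                out[k].pose = src.pose
                out[k].n_markers_used = src.n_markers_used
                out[k].reason = ""
                out[k].filled = True
        i = j
    return out


@dataclass(frozen=True)
class PosterGazeSample:
    """One gaze sample expressed on the poster plane."""

    timestamp: float
    poster_xy: tuple[float, float] | None
    eye_pos: tuple[float, float, float] | None
    gaze_px: tuple[float, float] | None
    valid: bool
    reason: str  # "ok" / "gaze-missing" / "no-markers" / ...


@dataclass
class PosterGazeSeries:
    """Array-backed series of poster-plane gaze samples.

    ``poster_xy`` rows are NaN where invalid; ``eye_pos`` carries the
    per-sample eye position in the poster frame (estimated pose or the
    assumed fixed position).  ``interpolated`` marks samples filled in
    later by gap interpolation, not originally measured.
    """

    timestamps: np.ndarray  # (N,)
    poster_xy: np.ndarray  # (N, 2), NaN = missing
    eye_pos: np.ndarray  # (N, 3), NaN = missing
    gaze_px: np.ndarray  # (N, 2) raw scene pixels, NaN = missing
    valid: np.ndarray  # (N,) bool
    reason: np.ndarray  # (N,) str
    mode: Mode
    assumed_eye: np.ndarray  # (3,), the mode-1 eye position
    interpolated: np.ndarray = field(default=None)  # type: ignore[assignment]
    calibration: CameraCalibration | None = None

    def __post_init__(self) -> None:
        if self.interpolated is None:
            self.interpolated = np.zeros(len(self.timestamps), dtype=bool)

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def sample_interval_ms(self) -> float:
        if len(self.timestamps) < 2:
            return float("nan")
        return float(np.median(np.diff(self.timestamps)))

    def samples(self) -> Iterator[PosterGazeSample]:
        for i in range(len(self)):
            yield PosterGazeSample(
                timestamp=float(self.timestamps[i]),
                poster_xy=None
                if np.isnan(self.poster_xy[i]).any()
                else tuple(self.poster_xy[i]),
                eye_pos=None
                if np.isnan(self.eye_pos[i]).any()
                else tuple(self.eye_pos[i]),
                gaze_px=None
                if np.isnan(self.gaze_px[i]).any()
                else tuple(self.gaze_px[i]),
                valid=bool(self.valid[i]),
                reason=str(self.reason[i]),
            )

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "timestamp_ms": self.timestamps,
                "poster_x_mm": self.poster_xy[:, 0],
                "poster_y_mm": self.poster_xy[:, 1],
                "eye_x_mm": self.eye_pos[:, 0],
                "eye_y_mm": self.eye_pos[:, 1],
                "eye_z_mm": self.eye_pos[:, 2],
                "valid": self.valid,
                "reason": self.reason,
            }
        )


def map_gaze(
    rec: Recording,
    geoms: list[FrameGeometry],
    poster: PosterSpec,
    mode: Mode = "pose_estimated",
    assumed_distance: float | None = None,
    eye_camera_offset: np.ndarray | None = None,
) -> PosterGazeSeries:
    """Transform every gaze sample to poster-plane millimetres.

    When a calibration is present the gaze pixel is undistorted to the
    ideal pinhole image before the frame homography is applied (in both
    modes, so the two modes yield identical poster positions and differ
    only in the eye position).  Without a calibration the homography was
    estimated against raw pixels and distortion is absorbed as a local
    approximation error.

    ``eye_camera_offset`` (poster-frame mm, added to the recovered
    camera position) corrects for the eye sitting below/behind the scene
    camera when that offset has been measured; by default the eye is
    equated with the optical centre.
    """
    if mode not in ("fixed_distance", "pose_estimated"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "pose_estimated" and rec.calibration is None:
        raise ValueError("pose_estimated mode requires a camera calibration")
    if assumed_distance is None:
        assumed_distance = poster.assumed_distance
    assumed_eye = np.array([0.0, 0.0, -float(assumed_distance)])
    offset = (
        np.zeros(3) if eye_camera_offset is None else np.asarray(eye_camera_offset, float)
    )

    by_frame = {g.frame_idx: g for g in geoms}
    ts, fi, px = rec.gaze_arrays()
    n = len(ts)
    xy = np.full((n, 2), np.nan)
    eye = np.full((n, 3), np.nan)
    valid = np.zeros(n, dtype=bool)
    reason = np.array(["ok"] * n, dtype=object)

    for i in range(n):
        g = by_frame.get(int(fi[i]))
        if g is None or not g.valid:
            reason[i] = "no-markers"
            continue
        if np.isnan(px[i]).any():
            reason[i] = "gaze-missing"
            continue
        pt = px[i]
        if rec.calibration is not None:
            normed, conv = undistort_points(pt, rec.calibration)
            if not conv:
                reason[i] = "undistort-failed"
                continue
            K = rec.calibration.matrix
            pt = np.array(
                [K[0, 0] * normed[0] + K[0, 2], K[1, 1] * normed[1] + K[1, 2]]
            )
        xy[i] = g.homography.unmap_points(pt)
        if mode == "pose_estimated":
            if g.pose is None:
                xy[i] = np.nan
                reason[i] = "no-pose"
                continue
            eye[i] = g.pose.camera_position_poster + offset
        else:
            eye[i] = assumed_eye
        valid[i] = True

    return PosterGazeSeries(
        timestamps=ts,
        poster_xy=xy,
        eye_pos=eye,
        gaze_px=px,
        valid=valid,
        reason=reason.astype(str),
        mode=mode,
        assumed_eye=assumed_eye,
        calibration=rec.calibration,
    )
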