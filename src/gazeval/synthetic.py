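"""Synthetic wearable eye-tracker recordings with known ground truth.

The generator emulates the validation procedure: a participant stands
in front of the poster and fixates each target in reading order for a
fixed dwell, while the scene camera observes the fiducial markers.
Gaze inaccuracy is injected as a constant Fick-angle offset, precision
noise as white Gaussian angular noise, and data loss as per-sample
Bernoulli dropout.  Noise is applied in angular space, not on the
poster plane, so recovered noise magnitudes are independent of viewing
distance — matching the angular definition of the quality measures.

Saccades are instantaneous single-sample transitions; real saccade
kinematics, blinks and marker occlusion are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .camera import (
    CameraCalibration,
    direction_to_fick,
    fick_to_direction,
    project_points,
)
from .poster import PosterSpec, default_poster, marker_corners
from .recording import (
    EpisodeAnnotation,
    GazeSample,
    MarkerObservation,
    Recording,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "default_calibration",
    "trajectory_static",
    "trajectory_sway",
    "simulate_recording",
]

Trajectory = Callable[[float], tuple[np.ndarray, np.ndarray]]


def default_calibration() -> CameraCalibration:
    """A plausible scene-camera calibration (1080p, ~88 deg horizontal
    field of view, no distortion)."""
    return CameraCalibration(fx=1000.0, fy=1000.0, cx=960.0, cy=540.0)


def _look_at(pos: np.ndarray, aim: np.ndarray) -> np.ndarray:
    """Camera-from-poster rotation for a camera at ``pos`` whose optical
    axis points at ``aim``, with the image y-axis along poster +y
    (down).  Rows of R are the camera axes in the poster frame."""
    z = aim - pos
    z = z / np.linalg.norm(z)
    x = np.cross([0.0, 1.0, 0.0], z)
    nx = np.linalg.norm(x)
    if nx < 1e-12:
        x = np.array([1.0, 0.0, 0.0])
    else:
        x = x / nx
    y = np.cross(z, x)
    return np.vstack([x, y, z])


def trajectory_static(pos, aim=(0.0, 0.0, 0.0)) -> Trajectory:
    """Constant eye pose aimed at the poster centre (or ``aim``)."""
    p = np.asarray(pos, dtype=float)
    R = _look_at(p, np.asarray(aim, dtype=float))

    def traj(t_ms: float) -> tuple[np.ndarray, np.ndarray]:
        return p, R

    return traj


def trajectory_sway(
    amplitude_mm: float,
    period_ms: float,
    base_pos=(0.0, 0.0, -600.0),
    axis: str = "z",
) -> Trajectory:
    """Sinusoidal postural sway along ``axis`` ('z' or 'x'), re-aimed at
    the poster centre every sample.  Zero amplitude equals static."""
    if amplitude_mm < 0:
        raise ValueError("amplitude_mm must be >= 0")
    base = np.asarray(base_pos, dtype=float)
    k = {"x": 0, "y": 1, "z": 2}[axis]

    def traj(t_ms: float) -> tuple[np.ndarray, np.ndarray]:
        p = base.copy()
        p[k] += amplitude_mm * np.sin(2.0 * np.pi * t_ms / period_ms)
        return p, _look_at(p, np.zeros(3))

    return traj


@dataclass
class SimulationConfig:
    """Study conditions for a simulated validation.

    Defaults follow the suggested procedure: nine targets fixated in
    reading order for one second each at 50 Hz from 600 mm, with a
    still head.
    """

    poster: PosterSpec = field(default_factory=default_poster)
    calib: CameraCalibration = field(default_factory=default_calibration)
    eye_trajectory: Trajectory | None = None  # default: static at (0,0,-600)
    dwell_ms: float = 1000.0
    order: list[int] | None = None  # target ids; default reading order
    offset_deg: tuple[float, float] = (0.0, 0.0)  # (azimuth, elevation)
    noise_sigma_deg: float = 0.0
    loss_prob: float = 0.0
    corner_noise_px: float = 0.0
    rate_hz: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if self.dwell_ms <= 0:
            raise ValueError("dwell_ms must be positive")
        if not 0.0 <= self.loss_prob <= 1.0:
            raise ValueError("loss_prob must be in [0, 1]")
        if self.noise_sigma_deg < 0 or self.corner_noise_px < 0:
            raise ValueError("noise magnitudes must be >= 0")


@dataclass
class GroundTruth:
    """Per-sample truth aligned 1:1 with the emitted gaze samples."""

    target_id: np.ndarray  # (N,) int
    true_direction: np.ndarray  # (N, 3) unit, poster frame
    eye_position: np.ndarray  # (N, 3) mm, poster frame
    offset_deg: tuple[float, float]
    noise_sigma_deg: float
    loss_prob: float

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "target_id": self.target_id,
                "dir_x": self.true_direction[:, 0],
                "dir_y": self.true_direction[:, 1],
                "dir_z": self.true_direction[:, 2],
                "eye_x_mm": self.eye_position[:, 0],
                "eye_y_mm": self.eye_position[:, 1],
                "eye_z_mm": self.eye_position[:, 2],
            }
        )


def simulate_recording(cfg: SimulationConfig) -> tuple[Recording, GroundTruth]:
    """Generate a complete synthetic recording plus its ground truth.

    For every sample the true gaze direction is eye-to-target; the
    reported direction adds the constant offset and white Gaussian
    noise in Fick angles; the reported poster point is the intersection
    of the reported ray with the poster plane; the gaze pixel is the
    scene-camera projection of that point (including distortion).
    Marker corners are projected per frame with optional pixel jitter.
    Samples go missing with probability ``loss_prob`` (the marker
    observations of those frames are kept, as a real video would be).
    One validation episode spans the whole scanpath.  Deterministic
    under a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    traj = cfg.eye_trajectory or trajectory_static((0.0, 0.0, -cfg.poster.assumed_distance))
    order = cfg.order if cfg.order is not None else cfg.poster.reading_order()
    dt = 1000.0 / cfg.rate_hz
    per_dwell = int(round(cfg.dwell_ms / dt))
    n = per_dwell * len(order)

    corner_mm = {
        m.id: np.column_stack([marker_corners(m), np.zeros(4)])
        for m in cfg.poster.markers
    }

    gaze: list[GazeSample] = []
    markers: list[MarkerObservation] = []
    tid_arr = np.empty(n, dtype=int)
    dir_arr = np.empty((n, 3))
    eye_arr = np.empty((n, 3))

    for k in range(n):
        t_ms = k * dt
        tid = order[k // per_dwell]
        target = cfg.poster.target_by_id(tid)
        pos, R = traj(t_ms)
        if pos[2] >= 0:
            raise ValueError("eye trajectory crossed the poster plane")
        tgt3 = np.array([target.x, target.y, 0.0])
        d_true = tgt3 - pos
        d_true = d_true / np.linalg.norm(d_true)

        az, el = direction_to_fick(d_true)
        az += cfg.offset_deg[0] + rng.normal(0.0, cfg.noise_sigma_deg)
        el += cfg.offset_deg[1] + rng.normal(0.0, cfg.noise_sigma_deg)
        d_rep = fick_to_direction(az, el)

        tid_arr[k] = tid
        dir_arr[k] = d_true
        eye_arr[k] = pos

        # reported gaze ray meets the poster plane z = 0
        s = -pos[2] / d_rep[2]
        point = pos + s * d_rep
        p_cam = R @ (point - pos)
        px = project_points(p_cam, cfg.calib)

        lost = rng.random() < cfg.loss_prob
        gaze.append(
            GazeSample(
                timestamp=t_ms,
                frame_idx=k,
                gaze_px=None if lost else (float(px[0]), float(px[1])),
            )
        )

        for mid, cmm in corner_mm.items():
            cam_corners = (cmm - pos) @ R.T
            cpx = project_points(cam_corners, cfg.calib)
            if cfg.corner_noise_px > 0:
                cpx = cpx + rng.normal(0.0, cfg.corner_noise_px, size=cpx.shape)
            markers.append(
                MarkerObservation(frame_idx=k, marker_id=mid, corners=cpx)
            )

    rec = Recording(
        gaze=gaze,
        markers=markers,
        episodes=[EpisodeAnnotation(start=0.0, end=n * dt, label="validation")],
        calibration=cfg.calib,
        meta={"synthetic": True, "seed": cfg.seed},
    )
    truth = GroundTruth(
        target_id=tid_arr,
        true_direction=dir_arr,
        eye_position=eye_arr,
        offset_deg=cfg.offset_deg,
        noise_sigma_deg=cfg.noise_sigma_deg,
        loss_prob=cfg.loss_prob,
    )
    return rec, truth
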