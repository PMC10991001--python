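"""Pinhole camera model, planar homography and angular utilities.

All image coordinates are pixels with the origin at the top-left of the
scene frame, x rightward, y downward.  Poster-plane coordinates are
millimetres on z = 0 with the viewer at z < 0 (x right, y down, z into
the poster), so a fronto-parallel scene camera and the poster frame are
co-oriented.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "CameraCalibration",
    "Homography",
    "PlanarPose",
    "project_points",
    "distort_normalized",
    "undistort_points",
    "estimate_homography",
    "pose_from_homography",
    "angle_between",
    "direction_to_fick",
    "fick_to_direction",
]


class GeometryError(ValueError):
    """Raised for degenerate geometric input (behind-camera points,
    underdetermined homographies, singular decompositions)."""


@dataclass
class CameraCalibration:
    """Pinhole intrinsics with Brown–Conrady distortion.

    Parameters
    ----------
    fx, fy : float
        Focal lengths in pixels.
    cx, cy : float
        Principal point in pixels.
    dist : array-like of 5 floats
        Distortion coefficients ``(k1, k2, p1, p2, k3)``.
    width, height : int
        Sensor resolution in pixels.
    """

    fx: float
    fy: float
    cx: float
    cy: float
    dist: np.ndarray = field(default_factory=lambda: np.zeros(5))
    width: int = 1920
    height: int = 1080

    def __post_init__(self) -> None:
        self.dist = np.asarray(self.dist, dtype=float).reshape(5)
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("resolution must be positive")

    @property
    def matrix(self) -> np.ndarray:
        """3x3 intrinsic matrix K."""
        return np.array(
            [[self.fx, 0.0, self.cx], [0.0, self.fy, self.cy], [0.0, 0.0, 1.0]]
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "fx": self.fx,
            "fy": self.fy,
            "cx": self.cx,
            "cy": self.cy,
            "dist": list(map(float, self.dist)),
            "width": self.width,
            "height": self.height,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CameraCalibration":
        d = json.loads(Path(path).read_text())
        return cls(
            fx=float(d["fx"]),
            fy=float(d["fy"]),
            cx=float(d["cx"]),
            cy=float(d["cy"]),
            dist=np.asarray(d.get("dist", np.zeros(5)), dtype=float),
            width=int(d.get("width", 1920)),
            height=int(d.get("height", 1080)),
        )


def distort_normalized(xy: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Apply Brown–Conrady distortion to ideal normalized coordinates."""
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    k1, k2, p1, p2, k3 = dist
    x, y = xy[:, 0], xy[:, 1]
    r2 = x * x + y * y
    radial = 1.0 + k1 * r2 + k2 * r2**2 + k3 * r2**3
    xd = x * radial + 2.0 * p1 * x * y + p2 * (r2 + 2.0 * x * x)
    yd = y * radial + p1 * (r2 + 2.0 * y * y) + 2.0 * p2 * x * y
    return np.column_stack([xd, yd])


def project_points(p_camera: np.ndarray, calib: CameraCalibration) -> np.ndarray:
    """Project camera-frame 3D points (mm) to distorted pixel coordinates.

    Raises :class:`GeometryError` if any point lies at or behind the
    optical centre (z <= 0).
    """
    p = np.atleast_2d(np.asarray(p_camera, dtype=float))
    single = np.asarray(p_camera).ndim == 1
    if np.any(p[:, 2] <= 0):
        raise GeometryError("point behind camera (z <= 0)")
    norm = p[:, :2] / p[:, 2:3]
    dn = distort_normalized(norm, calib.dist)
    px = np.column_stack(
        [calib.fx * dn[:, 0] + calib.cx, calib.fy * dn[:, 1] + calib.cy]
    )
    return px[0] if single else px


def undistort_points(
    px: np.ndarray,
    calib: CameraCalibration,
    max_iter: int = 50,
    tol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Invert the distortion model for pixel coordinates.

    Returns ``(normalized_xy, converged)`` where ``normalized_xy`` are
    ideal (undistorted) normalized image coordinates and ``converged``
    flags samples for which the fixed-point iteration reached ``tol``
    within ``max_iter`` iterations.  Non-converged samples should be
    treated as invalid by callers.
    """
    p = np.atleast_2d(np.asarray(px, dtype=float))
    single = np.asarray(px).ndim == 1
    xd = (p[:, 0] - calib.cx) / calib.fx
    yd = (p[:, 1] - calib.cy) / calib.fy
    k1, k2, p1, p2, k3 = calib.dist
    x, y = xd.copy(), yd.copy()
    converged = np.zeros(len(p), dtype=bool)
    for _ in range(max_iter):
        r2 = x * x + y * y
        radial = 1.0 + k1 * r2 + k2 * r2**2 + k3 * r2**3
        dx_t = 2.0 * p1 * x * y + p2 * (r2 + 2.0 * x * x)
        dy_t = p1 * (r2 + 2.0 * y * y) + 2.0 * p2 * x * y
        x_new = (xd - dx_t) / radial
        y_new = (yd - dy_t) / radial
        step = np.hypot(x_new - x, y_new - y)
        x, y = x_new, y_new
        converged = step < tol
        if converged.all():
            break
    out = np.column_stack([x, y])
    return (out[0], converged[0]) if single else (out, converged)


@dataclass
class Homography:
    """3x3 projective map from poster-plane mm (homogeneous) to image px.

    Normalized so the bottom-right element is 1 when nonzero.
    ``residual_px`` is the RMS reprojection residual of the
    correspondences it was estimated from (0 for constructed maps).
    """

    matrix: np.ndarray
    residual_px: float = 0.0

    def __post_init__(self) -> None:
        H = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        if abs(np.linalg.det(H)) < 1e-15:
            raise GeometryError("homography matrix is singular")
        if abs(H[2, 2]) > 1e-12:
            H = H / H[2, 2]
        self.matrix = H

    def map_points(self, pts: np.ndarray) -> np.ndarray:
        """Map poster mm points (N,2) to image pixel points (N,2)."""
        return _apply_h(self.matrix, pts)

    def unmap_points(self, pts: np.ndarray) -> np.ndarray:
        """Map image pixel points (N,2) back to poster mm points (N,2)."""
        return _apply_h(np.linalg.inv(self.matrix), pts)


def _apply_h(H: np.ndarray, pts: np.ndarray) -> np.ndarray:
    p = np.atleast_2d(np.asarray(pts, dtype=float))
    single = np.asarray(pts).ndim == 1
    hom = np.column_stack([p, np.ones(len(p))]) @ H.T
    out = hom[:, :2] / hom[:, 2:3]
    return out[0] if single else out


def _normalizing_similarity(pts: np.ndarray) -> np.ndarray:
    """Hartley similarity: centroid to origin, mean distance sqrt(2)."""
    c = pts.mean(axis=0)
    d = np.mean(np.linalg.norm(pts - c, axis=1))
    s = np.sqrt(2.0) / d if d > 1e-12 else 1.0
    return np.array([[s, 0.0, -s * c[0]], [0.0, s, -s * c[1]], [0.0, 0.0, 1.0]])


def estimate_homography(src_mm: np.ndarray, dst_px: np.ndarray) -> Homography:
    """Estimate the poster-to-image homography by the normalized DLT.

    Parameters
    ----------
    src_mm : (N, 2) array
        Points on the poster plane, millimetres.
    dst_px : (N, 2) array
        Corresponding image points, pixels.  One detected fiducial
        marker contributes its four corners, the minimum configuration.

    Raises
    ------
    GeometryError
        Fewer than 4 correspondences, or a degenerate (collinear)
        configuration.
    """
    src = np.atleast_2d(np.asarray(src_mm, dtype=float))
    dst = np.atleast_2d(np.asarray(dst_px, dtype=float))
    if src.shape != dst.shape or src.shape[0] < 4:
        raise GeometryError(
            f"need >= 4 correspondences, got {src.shape[0]}"
        )
    Ts, Td = _normalizing_similarity(src), _normalizing_similarity(dst)
    sn = _apply_h(Ts, src)
    dn = _apply_h(Td, dst)
    n = len(sn)
    A = np.zeros((2 * n, 9))
    x, y = sn[:, 0], sn[:, 1]
    u, v = dn[:, 0], dn[:, 1]
    A[0::2, 3:6] = -np.column_stack([x, y, np.ones(n)])
    A[0::2, 6:9] = np.column_stack([v * x, v * y, v])
    A[1::2, 0:3] = np.column_stack([x, y, np.ones(n)])
    A[1::2, 6:9] = -np.column_stack([u * x, u * y, u])
    _, s, Vt = np.linalg.svd(A)
    # rank < 8 means the configuration does not pin down a homography
    if s[7] < 1e-9 * s[0]:
        raise GeometryError("degenerate correspondence configuration")
    Hn = Vt[-1].reshape(3, 3)
    H = np.linalg.inv(Td) @ Hn @ Ts
    reproj = _apply_h(H, src)
    residual = float(np.sqrt(np.mean(np.sum((reproj - dst) ** 2, axis=1))))
    return Homography(H, residual_px=residual)


@dataclass
class PlanarPose:
    """Rigid pose of the scene camera relative to the poster plane.

    ``rotation`` and ``translation`` map poster-frame points to the
    camera frame, ``p_cam = R p_poster + t``.  ``camera_position_poster``
    is the optical centre expressed in the poster frame (``-R.T t``).
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    @property
    def camera_position_poster(self) -> np.ndarray:
        return -self.rotation.T @ self.translation

    @property
    def perpendicular_distance(self) -> float:
        return float(abs(self.camera_position_poster[2]))

    @property
    def euclidean_distance_to_origin(self) -> float:
        return float(np.linalg.norm(self.camera_position_poster))


def pose_from_homography(h: Homography, calib: CameraCalibration) -> PlanarPose:
    """Recover the planar pose from a calibrated homography.

    Decomposes ``K^-1 H`` into ``[r1 r2 t]`` up to scale, fixes the
    scale by the unit-norm constraint on the rotation columns and
    projects onto the nearest orthonormal matrix (SVD).  The sign is
    chosen so the poster lies in front of the camera (t_z > 0).
    """
    B = np.linalg.solve(calib.matrix, h.matrix)
    n1, n2 = np.linalg.norm(B[:, 0]), np.linalg.norm(B[:, 1])
    if n1 < 1e-12 or n2 < 1e-12:
        raise GeometryError("singular K^-1 H; pose recovery failed")
    lam = 2.0 / (n1 + n2)
    if B[2, 2] * lam < 0:
        lam = -lam
    r1, r2, t = lam * B[:, 0], lam * B[:, 1], lam * B[:, 2]
    R_approx = np.column_stack([r1, r2, np.cross(r1, r2)])
    U, _, Vt = np.linalg.svd(R_approx)
    R = U @ np.diag([1.0, 1.0, np.linalg.det(U @ Vt)]) @ Vt
    return PlanarPose(rotation=R, translation=t)


def angle_between(v1: np.ndarray, v2: np.ndarray) -> float:
    """Angle in degrees between two 3-vectors, in [0, 180]."""
    a = np.asarray(v1, dtype=float)
    b = np.asarray(v2, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise GeometryError("angle_between requires nonzero vectors")
    c = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def direction_to_fick(d: np.ndarray) -> np.ndarray:
    """Fick angles (azimuth, elevation) in degrees of 3D directions.

    Azimuth is positive rightward (+x), elevation positive upward
    (-y, since y points down); directions must point toward the poster
    (positive z).  Accepts a single vector or an (N, 3) array.
    """
    v = np.atleast_2d(np.asarray(d, dtype=float))
    single = np.asarray(d).ndim == 1
    if np.any(np.linalg.norm(v, axis=1) == 0):
        raise GeometryError("zero direction vector")
    az = np.degrees(np.arctan2(v[:, 0], v[:, 2]))
    el = np.degrees(np.arctan2(-v[:, 1], np.hypot(v[:, 0], v[:, 2])))
    out = np.column_stack([az, el])
    return out[0] if single else out


def fick_to_direction(az_deg: np.ndarray, el_deg: np.ndarray) -> np.ndarray:
    """Unit direction(s) from Fick azimuth/elevation in degrees."""
    az = np.radians(np.asarray(az_deg, dtype=float))
    el = np.radians(np.asarray(el_deg, dtype=float))
    x = np.cos(el) * np.sin(az)
    y = -np.sin(el)
    z = np.cos(el) * np.cos(az)
    return np.stack([x, y, z], axis=-1)
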