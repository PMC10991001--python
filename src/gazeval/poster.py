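"""Planar validation-surface geometry: fixation targets and fiducial markers.

The poster frame has its origin at the centre of the fixation-target
grid, x rightward, y downward, z into the poster plane; the viewer
stands at negative z.  All coordinates are millimetres.
"""

from __future__ import annotations

import json
import math
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .camera import angle_between

__all__ = [
    "TargetSpec",
    "MarkerSpec",
    "PosterSpec",
    "PosterError",
    "PrintScaleReport",
    "default_poster",
    "angular_span",
    "check_print_scale",
    "marker_corners",
    "load_poster",
    "save_poster",
]

DEFAULT_ASSUMED_DISTANCE_MM = 600.0
DEFAULT_MARKER_SIZE_MM = 41.9
DEFAULT_MARKER_SPAN_MM = 356.0
#: Angular extent of the target grid at the default assumed distance.
DEFAULT_SPAN_DEG = (20.0, 17.5)


class PosterError(ValueError):
    """Invalid poster geometry; the message names the offending field."""


@dataclass(frozen=True)
class TargetSpec:
    """A fixation target on the poster plane.

    The first (top-left) target of the default poster is red so
    participants can find the start of the reading-order scanpath;
    the others are blue.
    """

    id: int
    x: float
    y: float
    appearance: str = "blue"  # {"red", "blue"}

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass(frozen=True)
class MarkerSpec:
    """A square fiducial marker of known size and dictionary index."""

    id: int
    center_x: float
    center_y: float
    size: float
    rotation: float = 0.0  # degrees, in-plane


def marker_corners(marker: MarkerSpec) -> np.ndarray:
    """Corner positions (mm) in the order top-left, top-right,
    bottom-right, bottom-left of the marker's own frame."""
    h = marker.size / 2.0
    local = np.array([[-h, -h], [h, -h], [h, h], [-h, h]])
    th = math.radians(marker.rotation)
    R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    return local @ R.T + np.array([marker.center_x, marker.center_y])


@dataclass
class PosterSpec:
    """Targets plus markers on one plane (z = 0 by construction)."""

    targets: list[TargetSpec]
    markers: list[MarkerSpec]
    assumed_distance: float = DEFAULT_ASSUMED_DISTANCE_MM
    paper_size: tuple[float, float] = (594.0, 420.0)  # A2 landscape, mm

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.targets:
            raise PosterError("targets: at least one target required")
        if not self.markers:
            raise PosterError("markers: at least one marker required")
        if self.assumed_distance <= 0:
            raise PosterError("assumed_distance: must be positive")
        tids = [t.id for t in self.targets]
        if len(set(tids)) != len(tids):
            dup = sorted({i for i in tids if tids.count(i) > 1})
            raise PosterError(f"targets.id: duplicate id(s) {dup}")
        mids = [m.id for m in self.markers]
        if len(set(mids)) != len(mids):
            dup = sorted({i for i in mids if mids.count(i) > 1})
            raise PosterError(f"markers.id: duplicate id(s) {dup}")
        for m in self.markers:
            if m.size <= 0:
                raise PosterError(f"markers.size: marker {m.id} has size {m.size}")
        for m in self.markers:
            for t in self.targets:
                if _point_in_marker(t.position, m):
                    raise PosterError(
                        f"markers: marker {m.id} overlaps target {t.id}"
                    )

    def target_by_id(self, tid: int) -> TargetSpec:
        for t in self.targets:
            if t.id == tid:
                return t
        raise KeyError(tid)

    def marker_by_id(self, mid: int) -> MarkerSpec | None:
        for m in self.markers:
            if m.id == mid:
                return m
        return None

    @property
    def target_ids(self) -> list[int]:
        return [t.id for t in self.targets]

    def reading_order(self) -> list[int]:
        """Target ids sorted top-to-bottom then left-to-right."""
        return [t.id for t in sorted(self.targets, key=lambda t: (t.y, t.x))]

    def marker_span_mm(self) -> float:
        """Horizontal extent from the left edge of the left-most marker
        column to the right edge of the right-most column (the printed
        print-scale check measurement)."""
        xs = np.concatenate([marker_corners(m)[:, 0] for m in self.markers])
        return float(xs.max() - xs.min())


def _point_in_marker(p: np.ndarray, m: MarkerSpec) -> bool:
    th = math.radians(m.rotation)
    R = np.array([[math.cos(th), math.sin(th)], [-math.sin(th), math.cos(th)]])
    lx, ly = R @ (p - np.array([m.center_x, m.center_y]))
    h = m.size / 2.0
    return abs(lx) < h and abs(ly) < h


def default_poster() -> PosterSpec:
    """The default validation poster.

    Nine targets on a 3x3 grid spanning 20 deg x 17.5 deg at a 600 mm
    perpendicular viewing distance (outer columns at +-600 tan 10 deg,
    outer rows at +-600 tan 8.75 deg); sixteen 41.9 mm fiducial markers
    in a 4x4 frame around the grid whose horizontal extent, left edge
    of the left-most column to right edge of the right-most, is
    356.0 mm — the quantity measured when checking print scale.
    """
    d = DEFAULT_ASSUMED_DISTANCE_MM
    tx = d * math.tan(math.radians(DEFAULT_SPAN_DEG[0] / 2.0))
    ty = d * math.tan(math.radians(DEFAULT_SPAN_DEG[1] / 2.0))
    targets = []
    tid = 1
    for row, y in enumerate((-ty, 0.0, ty)):
        for x in (-tx, 0.0, tx):
            targets.append(
                TargetSpec(
                    id=tid,
                    x=x,
                    y=y,
                    appearance="red" if tid == 1 else "blue",
                )
            )
            tid += 1
    size = DEFAULT_MARKER_SIZE_MM
    # outer marker-column centres so outer edges are 356.0 mm apart
    outer = (DEFAULT_MARKER_SPAN_MM - size) / 2.0
    centers = np.linspace(-outer, outer, 4)
    markers = []
    mid = 0
    for cy in centers:
        for cx in centers:
            markers.append(MarkerSpec(id=mid, center_x=cx, center_y=cy, size=size))
            mid += 1
    return PosterSpec(targets=targets, markers=markers, assumed_distance=d)


def angular_span(poster: PosterSpec, eye: np.ndarray) -> tuple[float, float]:
    """Horizontal and vertical angular extent of the target grid, in
    degrees, seen from ``eye`` (poster-frame mm, off the plane).

    Horizontal: angle between the directions from the eye to the
    left-most and right-most targets of the row nearest eye height;
    vertical analogously over the column nearest the eye's x.
    """
    eye = np.asarray(eye, dtype=float).reshape(3)
    if eye[2] == 0:
        raise PosterError("eye: must lie off the poster plane")

    def span(group_axis: int, span_axis: int) -> float:
        coords = np.array([[t.x, t.y] for t in poster.targets])
        groups = np.unique(np.round(coords[:, group_axis], 6))
        g = groups[np.argmin(np.abs(groups - eye[group_axis]))]
        members = coords[np.isclose(coords[:, group_axis], g)]
        if len(members) < 2:
            return 0.0
        lo = members[np.argmin(members[:, span_axis])]
        hi = members[np.argmax(members[:, span_axis])]
        if np.allclose(lo, hi):
            return 0.0
        return angle_between(
            np.append(lo, 0.0) - eye, np.append(hi, 0.0) - eye
        )

    return span(group_axis=1, span_axis=0), span(group_axis=0, span_axis=1)


@dataclass(frozen=True)
class PrintScaleReport:
    passed: bool
    scale: float
    nominal_mm: float
    measured_mm: float
    tolerance: float


def check_print_scale(
    measured_span_mm: float, poster: PosterSpec, tolerance: float = 0.01
) -> PrintScaleReport:
    """Compare a measured marker span against the poster's nominal span.

    Printers are often not calibrated, so the marker-column span should
    be measured on the printed sheet; a scale factor outside
    ``1 +- tolerance`` fails the check.
    """
    if measured_span_mm <= 0:
        raise PosterError("measured_span_mm: must be positive")
    nominal = poster.marker_span_mm()
    scale = measured_span_mm / nominal
    return PrintScaleReport(
        passed=abs(scale - 1.0) <= tolerance,
        scale=scale,
        nominal_mm=nominal,
        measured_mm=measured_span_mm,
        tolerance=tolerance,
    )


# ---------------------------------------------------------------------------
# persistence (TOML by default; JSON by extension)

def _poster_dict(poster: PosterSpec) -> dict:
    return {
        "assumed_distance_mm": poster.assumed_distance,
        "paper_size_mm": list(poster.paper_size),
        "targets": [
            {"id": t.id, "x": t.x, "y": t.y, "appearance": t.appearance}
            for t in poster.targets
        ],
        "markers": [
            {
                "id": m.id,
                "x": m.center_x,
                "y": m.center_y,
                "size": m.size,
                "rotation": m.rotation,
            }
            for m in poster.markers
        ],
    }


def _poster_from_dict(d: dict) -> PosterSpec:
    try:
        targets = [
            TargetSpec(
                id=int(t["id"]),
                x=float(t["x"]),
                y=float(t["y"]),
                appearance=str(t.get("appearance", "blue")),
            )
            for t in d["targets"]
        ]
        markers = [
            MarkerSpec(
                id=int(m["id"]),
                center_x=float(m["x"]),
                center_y=float(m["y"]),
                size=float(m["size"]),
                rotation=float(m.get("rotation", 0.0)),
            )
            for m in d["markers"]
        ]
    except (KeyError, TypeError, ValueError) as exc:
        raise PosterError(f"malformed poster file: {exc}") from exc
    ps = d.get("paper_size_mm", (594.0, 420.0))
    return PosterSpec(
        targets=targets,
        markers=markers,
        assumed_distance=float(d.get("assumed_distance_mm", DEFAULT_ASSUMED_DISTANCE_MM)),
        paper_size=(float(ps[0]), float(ps[1])),
    )


def _toml_scalar(v) -> str:
    if isinstance(v, (bool, np.bool_)):
        return "true" if v else "false"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_scalar(x) for x in v) + "]"
    raise TypeError(type(v))


def save_poster(poster: PosterSpec, path: str | Path) -> None:
    """Write a poster configuration (.toml or .json by extension)."""
    path = Path(path)
    d = _poster_dict(poster)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(d, indent=1))
        return
    lines = [
        f"assumed_distance_mm = {_toml_scalar(d['assumed_distance_mm'])}",
        f"paper_size_mm = {_toml_scalar(d['paper_size_mm'])}",
        "",
    ]
    for t in d["targets"]:
        lines.append("[[targets]]")
        lines.extend(f"{k} = {_toml_scalar(v)}" for k, v in t.items())
        lines.append("")
    for m in d["markers"]:
        lines.append("[[markers]]")
        lines.extend(f"{k} = {_toml_scalar(v)}" for k, v in m.items())
        lines.append("")
    path.write_text("\n".join(lines))


def load_poster(path: str | Path) -> PosterSpec:
    """Read a poster configuration; validates geometry on load."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        d = json.loads(path.read_text())
    else:
        with open(path, "rb") as f:
            try:
                d = tomllib.load(f)
            except tomllib.TOMLDecodeError as exc:
                raise PosterError(f"malformed poster file: {exc}") from exc
    return _poster_from_dict(d)
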