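"""Data-quality measures: accuracy, precision, data loss, gaze range.

Accuracy for a fixation target is the angle between the direction from
the eye to the gaze point and the direction from the eye to the target.
Precision is computed from the per-sample angular offsets to the
target, decomposed into Fick azimuth/elevation: RMS-S2S is the root
mean square of successive sample-to-sample angular displacements and
STD the dispersion of the offsets around their mean.  Data loss is the
percentage of invalid gaze samples over the validation episode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .camera import CameraCalibration, angle_between, direction_to_fick, undistort_points
from .fixations import ClassifierParams, Fixation, classify_fixations
from .mapping import (
    PosterGazeSeries,
    fill_missing_geometry,
    frame_geometries,
    map_gaze,
)
from .poster import PosterSpec
from .recording import EpisodeAnnotation, Recording, data_loss, slice_episode

__all__ = [
    "TargetMatch",
    "DataQualityResult",
    "EpisodeSummary",
    "match_targets",
    "accuracy",
    "fixation_eye_position",
    "precision",
    "gaze_range",
    "fixed_distance_error_ratio",
    "process_episode",
    "process_recording",
    "summarize",
]

#: A fixation must be at least this long (ms) to be matched to a target.
MIN_MATCH_DURATION_MS = 50.0


@dataclass(frozen=True)
class TargetMatch:
    target_id: int
    fixation: Fixation | None
    distance_mm: float  # poster-plane centroid-target distance, NaN if unmatched

    @property
    def matched(self) -> bool:
        return self.fixation is not None


def match_targets(
    fixations: list[Fixation],
    poster: PosterSpec,
    min_dur_ms: float = MIN_MATCH_DURATION_MS,
) -> list[TargetMatch]:
    """Assign each target its nearest sufficiently long fixation.

    All (target, fixation) pairs with fixation duration >= min_dur_ms
    are sorted by poster-plane centroid-target distance and assigned
    greedily, skipping targets and fixations already used, so the
    matching is injective and each target gets the nearest fixation
    still available.  Unmatched targets are reported as such.
    """
    eligible = [f for f in fixations if f.duration >= min_dur_ms]
    pairs = []
    for t in poster.targets:
        for k, f in enumerate(eligible):
            d = float(np.hypot(f.centroid_xy[0] - t.x, f.centroid_xy[1] - t.y))
            pairs.append((d, t.id, k))
    pairs.sort()
    used_t: set[int] = set()
    used_f: set[int] = set()
    assigned: dict[int, tuple[Fixation, float]] = {}
    for d, tid, k in pairs:
        if tid in used_t or k in used_f:
            continue
        assigned[tid] = (eligible[k], d)
        used_t.add(tid)
        used_f.add(k)
    return [
        TargetMatch(
            target_id=t.id,
            fixation=assigned.get(t.id, (None, float("nan")))[0],
            distance_mm=assigned.get(t.id, (None, float("nan")))[1],
        )
        for t in poster.targets
    ]


def accuracy(
    centroid_xy: np.ndarray, target_xy: np.ndarray, eye_pos: np.ndarray
) -> float:
    """Angular error (deg) between gaze point and target seen from the eye."""
    c = np.append(np.asarray(centroid_xy, float), 0.0)
    t = np.append(np.asarray(target_xy, float), 0.0)
    e = np.asarray(eye_pos, float)
    return angle_between(c - e, t - e)


def fixation_eye_position(series: PosterGazeSeries, f: Fixation) -> np.ndarray:
    """Eye position attributed to a fixation: component-wise median of
    the member samples' eye positions (robust to pose jitter)."""
    sl = slice(f.member_indices[0], f.member_indices[1] + 1)
    eyes = series.eye_pos[sl][series.valid[sl] & ~series.interpolated[sl]]
    if len(eyes) == 0:
        eyes = series.eye_pos[sl][series.valid[sl]]
    return np.median(eyes, axis=0)


def _member_offsets(
    series: PosterGazeSeries, f: Fixation, target_xy: np.ndarray
) -> np.ndarray:
    """Per-sample (azimuth, elevation) offsets, deg, of the member gaze
    positions relative to the target, each using that sample's eye."""
    sl = slice(f.member_indices[0], f.member_indices[1] + 1)
    keep = series.valid[sl] & ~series.interpolated[sl]
    xy = series.poster_xy[sl][keep]
    eyes = series.eye_pos[sl][keep]
    pts = np.column_stack([xy, np.zeros(len(xy))])
    tgt = np.append(np.asarray(target_xy, float), 0.0)
    fick_g = direction_to_fick(pts - eyes)
    fick_t = direction_to_fick(tgt[None, :] - eyes)
    return fick_g - fick_t


def precision(
    series: PosterGazeSeries, f: Fixation, target_xy: np.ndarray
) -> tuple[float, float]:
    """(RMS-S2S, STD) in degrees over the fixation's member samples.

    RMS-S2S = sqrt(mean over successive sample pairs of daz^2 + del^2);
    STD = sqrt(var(az) + var(el)) with population (1/n) variances.
    Returns (nan, nan) with fewer than 2 member samples.
    """
    off = _member_offsets(series, f, target_xy)
    if len(off) < 2:
        return float("nan"), float("nan")
    d = np.diff(off, axis=0)
    rms = float(np.sqrt(np.mean(np.sum(d * d, axis=1))))
    std = float(np.sqrt(off[:, 0].var() + off[:, 1].var()))
    return rms, std


def gaze_range(
    series: PosterGazeSeries,
    matches: list[TargetMatch],
    calib: CameraCalibration | None = None,
) -> tuple[float, float]:
    """(horizontal, vertical) gaze range in degrees in the scene-camera
    frame: most positive minus most negative mean gaze direction across
    matched fixations.

    The mean gaze direction of a fixation is the Fick decomposition of
    the undistorted mean gaze pixel back-projected through the camera
    intrinsics.  A still-headed viewer sweeps the full angular extent of
    the target grid; a viewer who re-aims their head at every target
    keeps the gaze pixel constant and shows a range near zero.
    Returns (nan, nan) with fewer than 2 matched fixations or without a
    calibration.
    """
    calib = calib if calib is not None else series.calibration
    if calib is None:
        return float("nan"), float("nan")
    dirs = []
    for m in matches:
        if not m.matched:
            continue
        f = m.fixation
        sl = slice(f.member_indices[0], f.member_indices[1] + 1)
        px = series.gaze_px[sl]
        keep = ~np.isnan(px).any(axis=1)
        if not keep.any():
            continue
        mean_px = px[keep].mean(axis=0)
        normed, conv = undistort_points(mean_px, calib)
        if not conv:
            continue
        dirs.append(direction_to_fick(np.array([normed[0], normed[1], 1.0])))
    if len(dirs) < 2:
        return float("nan"), float("nan")
    fick = np.array(dirs)
    return (
        float(fick[:, 0].max() - fick[:, 0].min()),
        float(fick[:, 1].max() - fick[:, 1].min()),
    )


@dataclass
class DataQualityResult:
    """Per-target data-quality measures for one validation episode."""

    target_id: int
    accuracy_deg: float = float("nan")
    rms_s2s_deg: float = float("nan")
    std_deg: float = float("nan")
    n_samples: int = 0
    viewing_distance_mm: float = float("nan")
    eye_pos_mm: tuple[float, float, float] | None = None
    mode: str = ""
    matched: bool = False


@dataclass
class EpisodeSummary:
    """All measures for one recording episode."""

    results: list[DataQualityResult]
    data_loss_percent: float
    gaze_range_deg: tuple[float, float]
    mode: str
    episode: EpisodeAnnotation | None = None
    recording_name: str = ""

    def mean_over_targets(self) -> dict[str, float]:
        """Arithmetic means over matched targets only."""
        m = [r for r in self.results if r.matched]
        if not m:
            return {
                "accuracy_deg": float("nan"),
                "rms_s2s_deg": float("nan"),
                "std_deg": float("nan"),
                "viewing_distance_mm": float("nan"),
                "n_matched": 0,
            }
        def nmean(vals: list[float]) -> float:
            vals = [v for v in vals if np.isfinite(v)]
            return float(np.mean(vals)) if vals else float("nan")

        return {
            "accuracy_deg": nmean([r.accuracy_deg for r in m]),
            "rms_s2s_deg": nmean([r.rms_s2s_deg for r in m]),
            "std_deg": nmean([r.std_deg for r in m]),
            "viewing_distance_mm": nmean([r.viewing_distance_mm for r in m]),
            "n_matched": len(m),
        }


def fixed_distance_error_ratio(
    result_fixed: DataQualityResult, result_pose: DataQualityResult
) -> dict[str, float | None]:
    """Percentage error introduced by assuming a fixed viewing position:
    fixed-distance measure divided by pose-estimated measure, x100, for
    accuracy and both precision measures.  None where the pose-mode
    denominator is zero or missing."""

    def ratio(a: float, b: float) -> float | None:
        if not np.isfinite(a) or not np.isfinite(b) or b == 0:
            return None
        return 100.0 * a / b

    return {
        "accuracy_pct": ratio(result_fixed.accuracy_deg, result_pose.accuracy_deg),
        "rms_s2s_pct": ratio(result_fixed.rms_s2s_deg, result_pose.rms_s2s_deg),
        "std_pct": ratio(result_fixed.std_deg, result_pose.std_deg),
    }


def process_episode(
    rec: Recording,
    episode: EpisodeAnnotation,
    poster: PosterSpec,
    mode: str = "pose_estimated",
    assumed_distance: float | None = None,
    params: ClassifierParams = ClassifierParams(),
    fill_gap_ms: float = 100.0,
) -> EpisodeSummary:
    """Run the full pipeline on one validation episode.

    Slices the episode, estimates per-frame geometry, maps gaze to the
    poster, classifies fixations, matches them to targets and computes
    the per-target measures plus episode-level data loss and gaze range.
    """
    ep_rec = slice_episode(rec, episode)
    loss = data_loss(rec, episode)
    if not ep_rec.gaze:
        return EpisodeSummary(
            results=[DataQualityResult(target_id=t.id, mode=mode) for t in poster.targets],
            data_loss_percent=loss,
            gaze_range_deg=(float("nan"), float("nan")),
            mode=mode,
            episode=episode,
        )
    geoms = frame_geometries(ep_rec, poster)
    if fill_gap_ms > 0:
        geoms = fill_missing_geometry(geoms, fill_gap_ms)
    series = map_gaze(
        ep_rec, geoms, poster, mode=mode, assumed_distance=assumed_distance
    )
    fixations = classify_fixations(series, params)
    matches = match_targets(fixations, poster)
    results = []
    for m in matches:
        r = DataQualityResult(target_id=m.target_id, mode=mode)
        if m.matched:
            t = poster.target_by_id(m.target_id)
            eye = fixation_eye_position(series, m.fixation)
            r.matched = True
            r.eye_pos_mm = (float(eye[0]), float(eye[1]), float(eye[2]))
            r.viewing_distance_mm = float(
                np.linalg.norm(np.array([t.x, t.y, 0.0]) - eye)
            )
            r.accuracy_deg = accuracy(m.fixation.centroid_xy, (t.x, t.y), eye)
            r.rms_s2s_deg, r.std_deg = precision(series, m.fixation, (t.x, t.y))
            sl = slice(m.fixation.member_indices[0], m.fixation.member_indices[1] + 1)
            r.n_samples = int(
                np.count_nonzero(series.valid[sl] & ~series.interpolated[sl])
            )
        results.append(r)
    grange = gaze_range(series, matches)
    return EpisodeSummary(
        results=results,
        data_loss_percent=loss,
        gaze_range_deg=grange,
        mode=mode,
        episode=episode,
    )


def process_recording(
    rec: Recording,
    poster: PosterSpec,
    mode: str = "pose_estimated",
    assumed_distance: float | None = None,
    params: ClassifierParams = ClassifierParams(),
    recording_name: str = "",
) -> list[EpisodeSummary]:
    """Process every annotated validation episode of a recording."""
    out = []
    for ep in rec.episodes:
        s = process_episode(
            rec, ep, poster, mode=mode, assumed_distance=assumed_distance, params=params
        )
        s.recording_name = recording_name
        out.append(s)
    return out


def summarize(
    summaries: list[EpisodeSummary], average_over_targets: bool = False
) -> pd.DataFrame:
    """Tabulate episode summaries.

    One row per recording x episode x target, or one row per recording
    x episode (target_id "mean") when averaging; unmatched targets are
    excluded from averages and reported in ``n_unmatched``.
    """
    rows = []
    for s in summaries:
        base = {
            "recording": s.recording_name,
            "episode": s.episode.label if s.episode else "",
            "episode_start_ms": s.episode.start if s.episode else float("nan"),
            "mode": s.mode,
            "data_loss_percent": s.data_loss_percent,
            "gaze_range_h_deg": s.gaze_range_deg[0],
            "gaze_range_v_deg": s.gaze_range_deg[1],
        }
        if average_over_targets:
            mean = s.mean_over_targets()
            rows.append(
                base
                | {
                    "target_id": "mean",
                    "accuracy_deg": mean["accuracy_deg"],
                    "rms_s2s_deg": mean["rms_s2s_deg"],
                    "std_deg": mean["std_deg"],
                    "viewing_distance_mm": mean["viewing_distance_mm"],
                    "n_samples": sum(r.n_samples for r in s.results),
                    "n_unmatched": sum(not r.matched for r in s.results),
                }
            )
        else:
            for r in s.results:
                rows.append(
                    base
                    | {
                        "target_id": r.target_id,
                        "accuracy_deg": r.accuracy_deg,
                        "rms_s2s_deg": r.rms_s2s_deg,
                        "std_deg": r.std_deg,
                        "viewing_distance_mm": r.viewing_distance_mm,
                        "n_samples": r.n_samples,
                        "n_unmatched": int(not r.matched),
                    }
                )
    return pd.DataFrame(rows)
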