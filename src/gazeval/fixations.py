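"""Fixation classification on the poster-plane gaze series.

The classifier follows the two-means clustering idea behind I2MC: a
window slides over the 2-D gaze positions, each window is split into
two clusters, and samples at cluster transitions accumulate weight.
Samples whose accumulated weight stays below an adaptive cutoff form
fixation candidates, which are then merged across short gaps and
filtered by duration.  It is a self-contained variant, not a
line-for-line port of any existing implementation, and the classifier
entry point is pluggable so a different segmentation can be swapped in.

No multi-rate downsampling cascade is used: wearable eye trackers run
at 50-120 Hz, where a single time scale suffices.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

from .camera import angle_between
from .mapping import PosterGazeSeries

__all__ = [
    "ClassifierParams",
    "Fixation",
    "interpolate_gaps",
    "clustering_weights",
    "classify_fixations",
]


@dataclass(frozen=True)
class ClassifierParams:
    """Tunables of the two-means fixation classifier.

    window_ms
        Sliding-window length for the two-means step; should cover a
        handful of samples at the series rate (default 200 ms = 10
        samples at 50 Hz).
    max_interp_gap_ms
        Longest invalid run bridged by linear interpolation before
        clustering (default 100 ms, roughly a blink onset).
    weight_cutoff_lambda
        Candidate cutoff is mean(weight) + lambda * SD(weight).
    merge_max_gap_ms, merge_max_dist_deg
        Successive candidates closer than both limits (time gap and
        angular centroid separation seen from the eye) are merged.
    min_fix_dur_ms
        Candidates shorter than this are discarded.
    """

    window_ms: float = 200.0
    max_interp_gap_ms: float = 100.0
    weight_cutoff_lambda: float = 2.0
    merge_max_gap_ms: float = 30.0
    merge_max_dist_deg: float = 0.7
    min_fix_dur_ms: float = 40.0

    def __post_init__(self) -> None:
        for name in (
            "window_ms",
            "max_interp_gap_ms",
            "weight_cutoff_lambda",
            "merge_max_gap_ms",
            "merge_max_dist_deg",
            "min_fix_dur_ms",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class Fixation:
    start: float  # ms
    end: float  # ms
    centroid_xy: tuple[float, float]  # mm, mean of valid member samples
    member_indices: tuple[int, int]  # [first, last] sample index, inclusive

    @property
    def duration(self) -> float:
        return self.end - self.start


def interpolate_gaps(
    series: PosterGazeSeries, max_gap_ms: float = 100.0
) -> PosterGazeSeries:
    """Linearly interpolate poster positions across short invalid runs.

    Runs of invalid samples spanning at most ``max_gap_ms`` between two
    valid neighbours are filled by linear interpolation in time of both
    the poster position and the eye position; filled samples are
    flagged ``interpolated``.  Longer runs are untouched.
    """
    ts = series.timestamps
    xy = series.poster_xy.copy()
    eye = series.eye_pos.copy()
    valid = series.valid.copy()
    interp = series.interpolated.copy()
    n = len(ts)
    i = 0
    while i < n:
        if valid[i]:
            i += 1
            continue
        j = i
        while j < n and not valid[j]:
            j += 1
        if i > 0 and j < n:
            gap = ts[j] - ts[i - 1]
            if gap <= max_gap_ms:
                for k in range(i, j):
                    w = (ts[k] - ts[i - 1]) / gap
                    xy[k] = (1 - w) * xy[i - 1] + w * xy[j]
                    eye[k] = (1 - w) * eye[i - 1] + w * eye[j]
                    valid[k] = True
                    interp[k] = True
        i = j
    return PosterGazeSeries(
        timestamps=ts,
        poster_xy=xy,
        eye_pos=eye,
        gaze_px=series.gaze_px,
        valid=valid,
        reason=series.reason,
        mode=series.mode,
        assumed_eye=series.assumed_eye,
        interpolated=interp,
        calibration=series.calibration,
    )


def _two_means_labels(xy: np.ndarray, max_iter: int = 100) -> np.ndarray:
    """Lloyd's algorithm with k=2, initialized by splitting the window
    at its temporal midpoint.  Ties assign to cluster 0, so a window of
    identical positions yields a single label and no transitions."""
    n = len(xy)
    labels = np.zeros(n, dtype=int)
    labels[n // 2 :] = 1
    for _ in range(max_iter):
        m0 = xy[labels == 0].mean(axis=0) if (labels == 0).any() else xy.mean(axis=0)
        m1 = xy[labels == 1].mean(axis=0) if (labels == 1).any() else xy.mean(axis=0)
        d0 = np.sum((xy - m0) ** 2, axis=1)
        d1 = np.sum((xy - m1) ** 2, axis=1)
        new = (d1 < d0).astype(int)
        if np.array_equal(new, labels):
            break
        labels = new
    return labels


def clustering_weights(
    series: PosterGazeSeries, params: ClassifierParams = ClassifierParams()
) -> np.ndarray:
    """Per-sample transition weight from sliding-window two-means.

    Every window of ``window_ms`` (step one sample) whose samples are
    all valid is clustered into two; the samples on either side of each
    label transition receive an increment of 1 divided by the number of
    transitions in that window, so a window that splits cleanly at a
    saccade contributes full weight to the saccade pair while a window
    whose labels flicker on noise spreads the same total weight thinly.
    The weight is the accumulated count divided by the number of
    windows that covered the sample.  Windows with fewer than 4
    samples, or containing an invalid sample, are skipped.
    """
    ts = series.timestamps
    n = len(ts)
    counts = np.zeros(n)
    coverage = np.zeros(n)
    if n == 0:
        return counts
    dt = series.sample_interval_ms
    w = max(4, int(round(params.window_ms / dt))) if np.isfinite(dt) else n
    for start in range(0, n - w + 1):
        sl = slice(start, start + w)
        if not series.valid[sl].all():
            continue
        labels = _two_means_labels(series.poster_xy[sl])
        coverage[sl] += 1
        trans = np.nonzero(np.diff(labels) != 0)[0]
        if len(trans):
            w_inc = 1.0 / len(trans)
            for t in trans:
                counts[start + t] += w_inc
                counts[start + t + 1] += w_inc
    weights = np.zeros(n)
    covered = coverage > 0
    weights[covered] = counts[covered] / coverage[covered]
    return weights


def classify_fixations(
    series: PosterGazeSeries,
    params: ClassifierParams = ClassifierParams(),
    weight_fn: Callable[[PosterGazeSeries, ClassifierParams], np.ndarray]
    | None = None,
) -> list[Fixation]:
    """Segment a poster-gaze series into fixations.

    Steps: interpolate short gaps; compute per-sample transition
    weights (``weight_fn`` defaults to :func:`clustering_weights`);
    threshold at mean + lambda*SD; take maximal runs of valid
    sub-threshold samples as candidates; merge candidates separated by
    at most ``merge_max_gap_ms`` and ``merge_max_dist_deg`` (angular
    separation of centroids seen from the eye); drop candidates shorter
    than ``min_fix_dur_ms``.

    Centroids are the arithmetic mean of the *measured* (non-
    interpolated) member positions.  A fixation's end is the last
    member timestamp plus one sample interval, so an uninterrupted
    1 s dwell at 50 Hz has duration 1000 ms, not 980.
    """
    interp = interpolate_gaps(series, params.max_interp_gap_ms)
    n = len(interp)
    if n == 0 or not interp.valid.any():
        return []
    weight_fn = weight_fn or clustering_weights
    weights = weight_fn(interp, params)
    usable = interp.valid
    mu = weights[usable].mean()
    sd = weights[usable].std()
    cutoff = mu + params.weight_cutoff_lambda * sd
    keep = usable & (weights <= cutoff)

    dt = interp.sample_interval_ms
    if not np.isfinite(dt):
        dt = 0.0
    candidates: list[Fixation] = []
    i = 0
    while i < n:
        if not keep[i]:
            i += 1
            continue
        j = i
        while j < n and keep[j]:
            j += 1
        candidates.append(_make_fixation(interp, i, j - 1, dt))
        i = j

    merged = _merge_candidates(interp, candidates, params, dt)
    return [f for f in merged if f.duration >= params.min_fix_dur_ms]


def _make_fixation(
    series: PosterGazeSeries, first: int, last: int, dt: float
) -> Fixation:
    sl = slice(first, last + 1)
    measured = series.valid[sl] & ~series.interpolated[sl]
    member = measured if measured.any() else series.valid[sl]
    centroid = series.poster_xy[sl][member].mean(axis=0)
    return Fixation(
        start=float(series.timestamps[first]),
        end=float(series.timestamps[last] + dt),
        centroid_xy=(float(centroid[0]), float(centroid[1])),
        member_indices=(first, last),
    )


def _fixation_eye(series: PosterGazeSeries, f: Fixation) -> np.ndarray:
    sl = slice(f.member_indices[0], f.member_indices[1] + 1)
    eyes = series.eye_pos[sl][series.valid[sl]]
    return np.median(eyes, axis=0)


def _merge_candidates(
    series: PosterGazeSeries,
    candidates: list[Fixation],
    params: ClassifierParams,
    dt: float,
) -> list[Fixation]:
    if not candidates:
        return []
    out = [candidates[0]]
    for f in candidates[1:]:
        prev = out[-1]
        gap = f.start - prev.end
        eye = np.median(
            [_fixation_eye(series, prev), _fixation_eye(series, f)], axis=0
        )
        sep = angle_between(
            np.append(prev.centroid_xy, 0.0) - eye, np.append(f.centroid_xy, 0.0) - eye
        )
        if gap <= params.merge_max_gap_ms and sep <= params.merge_max_dist_deg:
            out[-1] = _make_fixation(
                series, prev.member_indices[0], f.member_indices[1], dt
            )
        else:
            out.append(f)
    return out
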