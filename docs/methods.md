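# Methods

## Coordinate conventions

Poster frame: origin at the centre of the fixation-target grid, x
rightward, y downward, z into the poster plane; all poster coordinates
in millimetres, the viewer at z < 0. Scene-image frame: pixels, origin
top-left, x right, y down. These conventions make the poster and a
fronto-parallel scene camera co-oriented, so the camera-from-poster
rotation of a viewer facing the poster is the identity. Angular
directions use Fick decomposition: azimuth = atan2(x, z) (positive
rightward), elevation = atan2(−y, √(x² + z²)) (positive upward).
Timestamps are milliseconds; episodes are half-open intervals
[start, end).

## Default poster

Nine targets on a 3×3 grid whose outer columns sit at ±600·tan 10° =
±105.80 mm and outer rows at ±600·tan 8.75° = ±92.35 mm, so the grid
subtends 20° × 17.5° at the default assumed perpendicular viewing
distance of 600 mm. The top-left target is red (the scanpath start);
the rest are blue. Sixteen fiducial markers (ids 0–15, side 41.9 mm)
form a 4×4 frame with equal column spacing chosen so the horizontal
extent from the left edge of the left-most column to the right edge of
the right-most column is 356.0 mm — the quantity a user measures to
check print scale (tolerance ±1% by default). The marker count and
arrangement are a design choice of this package; the geometry is fully
configurable through a TOML/JSON poster file and validated on load
(unique ids, positive sizes, no marker/target overlap).

## Camera model and planar geometry

A standard pinhole model with Brown–Conrady distortion (k1, k2, p1,
p2, k3). Undistortion inverts the model by fixed-point iteration (50
iterations, 1e−12 tolerance); non-converged points are flagged invalid
rather than used. Homographies between poster millimetres and image
pixels are estimated by the normalized (Hartley) DLT over the pooled
corners of all detected markers in a frame — one marker (4 corners) is
the minimum; pooling all markers gives a far stabler estimate than
averaging per-marker homographies. Degenerate configurations are
detected from the singular-value spectrum of the design matrix.

Planar pose is recovered by decomposing K⁻¹H into [r1 r2 t], fixing
scale with the unit-norm constraint on the rotation columns (mean of
the two norms), choosing the sign that puts the poster in front of the
camera, and projecting onto the nearest orthonormal matrix via SVD. An
iterative PnP refinement is unnecessary at the corner-noise levels of
interest here; on noiseless data the round trip is exact to well below
0.1 mm / 0.01° (verified over randomized poses in the tests).

When a calibration is available, gaze pixels and marker corners are
undistorted to the ideal pinhole image before the homography is
estimated/applied, in both viewing-position modes — so mode choice
affects only the eye position, never the mapped poster position.
Without a calibration (fixed-distance mode only), the homography is
estimated against raw pixels and distortion is absorbed as a local
approximation error.

The eye is equated with the scene-camera optical centre; a fixed
eye-to-camera offset vector can be supplied when it has been measured
(default zero). "Viewing distance" reported per target is the Euclidean
distance from the eye to that target; the perpendicular distance is
available from the pose for distance-dependence analyses.

## Gaze mapping

Per-frame geometry is estimated from that frame's detections; frames
with no usable markers yield missing geometry with a reason code.
Dropout gaps are bridged by copying the nearest-in-time geometry, but
only when the whole gap spans ≤ 100 ms (configurable): homography
entries are never interpolated, because element-wise interpolation of
a projective map is not sound. Each valid gaze sample is undistorted
and pushed through its frame's inverse homography; its eye position is
the frame's recovered camera position (pose mode) or (0, 0, −assumed
distance) (fixed mode). The eye position attributed to a whole fixation
is the component-wise median over its member samples, robust to pose
jitter; per-sample eye positions are used for the per-sample angular
offsets entering precision.

## Fixation classification

A two-means-clustering classifier operating on the poster-plane
positions. A window of 200 ms slides one sample at a time; each fully
valid window is split into two clusters (Lloyd's algorithm, initialized
by the temporal midpoint split). The two samples flanking each label
transition receive an increment of 1/(number of transitions in the
window): a window that splits cleanly at a saccade contributes its full
weight to the saccade pair, while a window whose labels flicker on
noise spreads the same weight thinly. A sample's weight is its
accumulated count divided by the number of windows covering it.
Candidate fixations are maximal runs of valid samples with weight ≤
mean + λ·SD (λ = 2); ≤ rather than < so that a perfectly stationary
series (all weights 0, SD 0) is one fixation rather than none.
Candidates separated by ≤ 30 ms and ≤ 0.7° (angular centroid
separation seen from the eye) are merged; candidates shorter than
40 ms are dropped. Gaps ≤ 100 ms are linearly interpolated before
clustering; interpolated samples are flagged and excluded from
centroids and precision. A fixation's end is its last member timestamp
plus one sample interval, so an n-sample dwell at rate r has duration
n/r. No multi-rate downsampling cascade is used: wearable trackers run
at 50–120 Hz, where a single time scale suffices. The weight function
is pluggable, so a dispersion-based or ported classifier can be swapped
in unchanged downstream.

## Target matching and measures

Fixations of at least 50 ms are eligible for matching. All (target,
eligible fixation) pairs are sorted by poster-plane centroid–target
distance and assigned greedily, skipping used targets and fixations;
this realises "nearest fixation, each fixation used at most once" with
a deterministic resolution when targets compete for a fixation.
Unmatched targets are reported, never imputed. Accuracy, RMS-S2S and
STD are computed as in the README; STD uses population (1/n) variances
and RMS-S2S averages over the n−1 successive differences. The
fixed-distance error ratio is (fixed-mode measure)/(pose-mode measure)
× 100 for accuracy and each precision measure, with a flagged missing
value when the denominator is zero. The gaze-range statistic takes,
per matched fixation, the Fick angles of the undistorted mean gaze
pixel back-projected through the intrinsics, and reports max − min of
azimuth and elevation across fixations; it needs ≥ 2 matched fixations
and a calibration. Data loss is computed over the full episode, not
over matched fixations.

## Synthetic recordings

The simulator emulates the suggested validation procedure: nine
targets fixated in reading order for 1 s each at 50 Hz from a still
position 600 mm in front of the poster centre, scene camera aimed at
the centre (defaults; all configurable). Per sample, the true gaze
direction is eye→target; a constant (azimuth, elevation) offset models
inaccuracy and white Gaussian noise models imprecision, both added in
Fick angles so that the recovered magnitudes are independent of viewing
distance; the perturbed ray is intersected with the poster plane and
projected through the camera (with distortion) to produce the gaze
pixel. Marker corners are projected per frame with optional Gaussian
pixel jitter; samples are dropped with a Bernoulli loss probability
(marker observations kept, as in a real video). Saccades are
instantaneous single-sample transitions. An eye trajectory is a
callable t → (position, orientation); provided trajectories are static
and sinusoidal sway re-aimed at the poster centre. Everything is
deterministic under a fixed seed.

What the simulator does not emulate — saccade kinematics, blinks and
eyelid occlusion, marker occlusion and motion blur, pupil-size-dependent
gaze shifts, rolling shutter — bounds what passing tests show: they
demonstrate that the pipeline recovers known offset/noise/loss under
clean viewing conditions, not that any particular real tracker meets a
quality level.

## Problem sizes and numerical choices

Tests and the acceptance script use the nine-target, 1 s-dwell, 50 Hz
procedure (450 samples, 16 markers → 64 correspondences per frame),
with 20 seeded replicates for stochastic recovery checks; these sizes
match the procedure the tool is built for, and the statistics are
already stable there. Homography exactness is asserted at 1e−6 px and
pose at 0.1 mm on noiseless input; accuracy-offset recovery at 0.05°
(an azimuth offset δ at an off-axis target with elevation e subtends
≈ δ·cos e, ≤ 0.03° below δ on this poster); precision recovery at 15%
of the closed-form expectations E[RMS-S2S] = 2σ, E[STD] = σ√2. Ties in
the two-means assignment go to the first cluster, making the
classifier deterministic on degenerate (constant) windows.

## Known limitations

- No vendor importers: recordings must be converted to the interchange
  CSV layout first, and marker detection on the scene video is assumed
  to have happened upstream.
- Fixed-distance mode inherits its stated assumptions; errors grow in
  proportion to the mismatch between assumed and physical distance.
- The classifier is a variant, not a port, of the published two-means
  method; parameter defaults follow its spirit, not a specific release.
- Planar targets only; no correction for corneal refraction or for the
  eye-camera offset unless supplied.
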