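import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gazeval.camera import (
    CameraCalibration,
    GeometryError,
    Homography,
    angle_between,
    direction_to_fick,
    estimate_homography,
    fick_to_direction,
    pose_from_homography,
    project_points,
    undistort_points,
)


@pytest.fixture
def pinhole():
    return CameraCalibration(fx=1000.0, fy=1000.0, cx=960.0, cy=540.0)


class TestProjection:
    def test_optical_axis_hits_principal_point(self, pinhole):
        assert project_points([0.0, 0.0, 600.0], pinhole) == pytest.approx([960, 540])

    def test_lateral_offset(self, pinhole):
        assert project_points([60.0, 0.0, 600.0], pinhole) == pytest.approx([1060, 540])

    def test_behind_camera_rejected(self, pinhole):
        with pytest.raises(GeometryError):
            project_points([0.0, 0.0, -10.0], pinhole)


class TestUndistort:
    def test_identity_distortion(self, pinhole):
        xy, conv = undistort_points([1060.0, 540.0], pinhole)
        assert conv
        assert xy == pytest.approx([0.1, 0.0])

    def test_principal_point_maps_to_origin_any_coeffs(self):
        c = CameraCalibration(fx=900, fy=950, cx=640, cy=360,
                              dist=[-0.3, 0.12, 0.001, -0.002, 0.05])
        xy, conv = undistort_points([640.0, 360.0], c)
        assert conv
        assert xy == pytest.approx([0.0, 0.0], abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        x=st.floats(-800, 800),
        y=st.floats(-450, 450),
        k1=st.floats(-0.3, 0.3),
    )
    def test_distort_undistort_round_trip(self, x, y, k1):
        """distort(undistort(p)) returns the pixel within 1e-6 px for
        in-frame points and |k1| <= 0.3."""
        c = CameraCalibration(fx=1000, fy=1000, cx=960, cy=540,
                              dist=[k1, 0.02, 0.001, -0.001, 0.0])
        px = np.array([960.0 + x, 540.0 + y])
        norm, conv = undistort_points(px, c)
        if not conv:  # extreme distortion corner cases are flagged, not wrong
            return
        back = project_points(np.array([norm[0], norm[1], 1.0]) * 600.0, c)
        assert back == pytest.approx(px, abs=1e-6)


def random_homography(rng):
    H = np.eye(3) + rng.uniform(-0.5, 0.5, (3, 3)) * np.array(
        [[0.5, 0.5, 200], [0.5, 0.5, 200], [1e-4, 1e-4, 0.5]]
    )
    return H if abs(np.linalg.det(H)) > 1e-3 else np.eye(3)


class TestHomography:
    def test_recovers_scale_and_shift(self):
        H0 = np.array([[2.0, 0, 500], [0, 2.0, 500], [0, 0, 1.0]])
        src = np.array([[0, 0], [100, 0], [100, 100], [0, 100.0]])
        dst = (np.column_stack([src, np.ones(4)]) @ H0.T)[:, :2]
        h = estimate_homography(src, dst)
        assert h.map_points([10.0, 20.0]) == pytest.approx([520, 540], abs=1e-9)

    def test_identity_correspondences(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1.0]])
        h = estimate_homography(pts, pts)
        assert h.map_points([0.3, 0.7]) == pytest.approx([0.3, 0.7], abs=1e-9)

    def test_three_points_underdetermined(self):
        pts = np.array([[0, 0], [1, 0], [0, 1.0]])
        with pytest.raises(GeometryError):
            estimate_homography(pts, pts)

    def test_collinear_points_degenerate(self):
        src = np.column_stack([np.arange(5.0), np.arange(5.0)])
        with pytest.raises(GeometryError):
            estimate_homography(src, src * 2.0)

    def test_exact_on_noiseless_random_maps(self):
        """Held-out points map within 1e-6 px for arbitrary invertible H."""
        rng = np.random.default_rng(7)
        grid = np.array([[x, y] for x in (-150, -50, 50, 150) for y in (-150, 0, 150.0)])
        held_out = rng.uniform(-140, 140, (20, 2))
        for _ in range(25):
            H0 = random_homography(rng)
            dst = (np.column_stack([grid, np.ones(len(grid))]) @ H0.T)
            dst = dst[:, :2] / dst[:, 2:3]
            h = estimate_homography(grid, dst)
            exp = (np.column_stack([held_out, np.ones(20)]) @ H0.T)
            exp = exp[:, :2] / exp[:, 2:3]
            assert h.map_points(held_out) == pytest.approx(exp, abs=1e-6)
            assert h.residual_px < 1e-6

    def test_residual_grows_with_corner_noise(self):
        rng = np.random.default_rng(1)
        grid = np.array([[x, y] for x in (-150, -50, 50, 150) for y in (-150, 0, 150.0)])
        clean = estimate_homography(grid, grid * 3.0).residual_px
        noisy = estimate_homography(grid, grid * 3.0 + rng.normal(0, 2, grid.shape))
        assert noisy.residual_px > clean

    def test_singular_matrix_rejected(self):
        with pytest.raises(GeometryError):
            Homography(np.zeros((3, 3)))


def make_pose(rng, yaw_pitch_limit=45.0):
    """Random camera pose looking at the poster from z < 0."""
    yaw, pitch = np.radians(rng.uniform(-yaw_pitch_limit, yaw_pitch_limit, 2))
    roll = np.radians(rng.uniform(-20, 20))
    cy_, sy = np.cos(yaw), np.sin(yaw)
    cp, sp = np.cos(pitch), np.sin(pitch)
    cr, sr = np.cos(roll), np.sin(roll)
    Ry = np.array([[cy_, 0, sy], [0, 1, 0], [-sy, 0, cy_]])
    Rx = np.array([[1, 0, 0], [0, cp, -sp], [0, sp, cp]])
    Rz = np.array([[cr, -sr, 0], [sr, cr, 0], [0, 0, 1]])
    R = Rz @ Rx @ Ry
    pos = np.array([rng.uniform(-150, 150), rng.uniform(-150, 150),
                    -rng.uniform(400, 900)])
    t = -R @ pos
    return R, t, pos


def forward_homography(R, t, calib):
    return Homography(calib.matrix @ np.column_stack([R[:, 0], R[:, 1], t]))


class TestPlanarPose:
    def test_fronto_parallel(self, pinhole):
        R, t = np.eye(3), np.array([0.0, 0.0, 600.0])
        pose = pose_from_homography(forward_homography(R, t, pinhole), pinhole)
        assert pose.camera_position_poster == pytest.approx([0, 0, -600], abs=1e-9)
        assert pose.perpendicular_distance == pytest.approx(600.0)

    def test_translated_camera_distances(self, pinhole):
        pos = np.array([100.0, 0.0, -600.0])
        pose = pose_from_homography(
            forward_homography(np.eye(3), -pos, pinhole), pinhole)
        assert pose.perpendicular_distance == pytest.approx(600.0)
        assert pose.euclidean_distance_to_origin == pytest.approx(608.28, abs=0.01)

    def test_yawed_poster_rotation_recovered(self, pinhole):
        yaw = np.radians(30.0)
        R = np.array([[np.cos(yaw), 0, np.sin(yaw)], [0, 1, 0],
                      [-np.sin(yaw), 0, np.cos(yaw)]])
        pos = np.array([0.0, 0.0, -600.0])
        pose = pose_from_homography(forward_homography(R, -R @ pos, pinhole), pinhole)
        assert angle_between(pose.rotation[:, 2], R[:, 2]) < 0.01

    def test_randomized_round_trip(self, pinhole):
        """Pose decomposition inverts forward construction: rotation
        within 0.01 deg, camera position within 0.1 mm, over randomized
        poses with |yaw|, |pitch| <= 45 deg."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            R, t, pos = make_pose(rng)
            pose = pose_from_homography(forward_homography(R, t, pinhole), pinhole)
            assert pose.camera_position_poster == pytest.approx(pos, abs=0.1)
            cos_err = (np.trace(pose.rotation @ R.T) - 1.0) / 2.0
            assert np.degrees(np.arccos(np.clip(cos_err, -1, 1))) < 0.01


class TestAngles:
    def test_identical_vectors_zero(self):
        assert angle_between([1, 2, 3], [1, 2, 3]) == pytest.approx(0.0)

    def test_known_angle(self):
        assert angle_between([0, 0, 1], [np.tan(np.radians(10)), 0, 1]) == (
            pytest.approx(10.0))

    def test_opposite_vectors(self):
        assert angle_between([0, 0, 1], [0, 0, -1]) == pytest.approx(180.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(GeometryError):
            angle_between([0, 0, 0], [1, 0, 0])

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        v=st.tuples(*[st.floats(-5, 5) for _ in range(3)]),
        w=st.tuples(*[st.floats(-5, 5) for _ in range(3)]),
        s=st.floats(0.01, 100),
    )
    def test_symmetric_and_scale_invariant(self, v, w, s):
        v, w = np.asarray(v), np.asarray(w)
        if np.linalg.norm(v) < 1e-3 or np.linalg.norm(w) < 1e-3:
            return
        assert angle_between(v, w) == pytest.approx(angle_between(w, v), abs=1e-5)
        assert angle_between(s * v, w) == pytest.approx(angle_between(v, w), abs=1e-5)

    @pytest.mark.parametrize(
        "d,expected",
        [
            ((0, 0, 1), (0, 0)),
            ((1, 0, 1), (45, 0)),
            ((0, -1, 1), (0, 45)),  # y points down, so -y is upward
        ],
    )
    def test_fick_decomposition(self, d, expected):
        assert direction_to_fick(np.array(d, dtype=float)) == pytest.approx(expected)

    def test_fick_round_trip(self):
        rng = np.random.default_rng(0)
        az = rng.uniform(-80, 80, 50)
        el = rng.uniform(-80, 80, 50)
        d = fick_to_direction(az, el)
        back = direction_to_fick(d)
        assert back[:, 0] == pytest.approx(az, abs=1e-9)
        assert back[:, 1] == pytest.approx(el, abs=1e-9)


def test_calibration_json_round_trip(tmp_path):
    c = CameraCalibration(fx=1100, fy=1050, cx=955.5, cy=545.5,
                          dist=[-0.1, 0.01, 0.001, 0.0, 0.002],
                          width=1920, height=1080)
    c.to_json(tmp_path / "c.json")
    d = CameraCalibration.from_json(tmp_path / "c.json")
    assert (d.fx, d.fy, d.cx, d.cy) == (c.fx, c.fy, c.cx, c.cy)
    assert d.dist == pytest.approx(c.dist)
    assert (d.width, d.height) == (c.width, c.height)
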