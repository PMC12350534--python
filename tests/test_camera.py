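import numpy as np
import pytest

from depthreg import camera as cam
from depthreg import simulator as sim
from depthreg.camera import (
    CameraIntrinsics,
    Checkerboard,
    CornerObservation,
    estimate_board_pose,
    estimate_homography,
    project,
    project_points,
    reprojection_error_px,
    zhang_calibrate,
)
from depthreg.exceptions import (
    ConfigError,
    DegenerateConfigurationError,
    IllConditionedError,
    ProjectionDomainError,
)
from depthreg.geometry import RigidTransform, rotation_geodesic_deg


class TestTypes:
    def test_intrinsics_validation(self):
        with pytest.raises(ConfigError):
            CameraIntrinsics(fx=-1, fy=800, cx=640, cy=360, width=1280, height=720)
        with pytest.raises(ConfigError):
            CameraIntrinsics(fx=800, fy=800, cx=2000, cy=360, width=1280, height=720)

    def test_board_orientation_disambiguation(self):
        with pytest.raises(ConfigError):
            Checkerboard(inner_rows=7, inner_cols=7, square_mm=25)
        b = Checkerboard(inner_rows=7, inner_cols=10, square_mm=25)
        pts = b.corner_points
        assert pts.shape == (70, 3)
        assert np.all(pts[:, 2] == 0)
        # row-major from the origin
        assert np.allclose(pts[0], [0, 0, 0])
        assert np.allclose(pts[1], [25, 0, 0])


class TestProjection:
    def test_on_axis_point_hits_principal_point(self, intr):
        uv = project_points(intr, np.array([[0.0, 0.0, 1000.0]]))
        assert np.allclose(uv[0], [intr.cx, intr.cy])

    def test_focal_length_linearity(self, intr):
        from dataclasses import replace

        p = np.array([[30.0, -20.0, 500.0]])
        uv1 = project_points(intr, p)
        uv2 = project_points(replace(intr, fx=2 * intr.fx), p)
        assert np.isclose(uv2[0, 0] - intr.cx, 2 * (uv1[0, 0] - intr.cx))
        assert np.isclose(uv2[0, 1], uv1[0, 1])

    def test_radial_distortion_matches_scalar_formula(self):
        intr = CameraIntrinsics(
            fx=800, fy=800, cx=640, cy=360, width=1280, height=720, k1=-0.1
        )
        # normalized radius 0.5 -> radial factor (1 + k1 * 0.25)
        p = np.array([[0.3, 0.4, 1.0]])
        uv = project_points(intr, p)
        factor = 1.0 + (-0.1) * 0.25
        assert np.allclose(uv[0, 0], 640 + 800 * 0.3 * factor)
        assert np.allclose(uv[0, 1], 360 + 800 * 0.4 * factor)

    def test_point_behind_camera_raises(self, intr):
        with pytest.raises(ProjectionDomainError):
            project_points(intr, np.array([[0.0, 0.0, -10.0]]))

    def test_reprojection_error_zero_on_exact_observation(self, intr, board):
        pose = sim._centered_board_pose(board, (1, 0, 0), 15.0, 450.0)
        obs = project(intr, pose, board)
        mean, std = reprojection_error_px(intr, pose, board, obs)
        assert mean < 1e-12 and std < 1e-12

    def test_reprojection_error_uniform_shift(self, intr, board):
        pose = sim._centered_board_pose(board, (1, 0, 0), 15.0, 450.0)
        obs = project(intr, pose, board)
        shifted = CornerObservation(obs.image_points + [1.0, 0.0])
        mean, std = reprojection_error_px(intr, pose, board, shifted)
        assert np.isclose(mean, 1.0) and std < 1e-12

    def test_reprojection_error_matches_per_corner_loop(self, intr, board):
        rng = np.random.default_rng(0)
        pose = sim._centered_board_pose(board, (0, 1, 0), 20.0, 500.0)
        obs = CornerObservation(
            project(intr, pose, board).image_points + rng.normal(size=(board.n_corners, 2))
        )
        mean, std = reprojection_error_px(intr, pose, board, obs)
        pred = project(intr, pose, board).image_points
        dists = [float(np.hypot(*(pred[i] - obs.image_points[i]))) for i in range(board.n_corners)]
        assert np.isclose(mean, np.mean(dists))
        assert np.isclose(std, np.std(dists))


class TestHomography:
    def test_recovers_known_homography(self):
        rng = np.random.default_rng(1)
        h_true = np.array([[1.2, 0.1, 30.0], [-0.05, 0.9, -20.0], [1e-4, -2e-4, 1.0]])
        xy = rng.uniform(0, 200, size=(20, 2))
        xyh = np.column_stack([xy, np.ones(len(xy))]) @ h_true.T
        uv = xyh[:, :2] / xyh[:, 2:]
        h = estimate_homography(xy, uv)
        assert np.allclose(h, h_true, atol=1e-8)

    def test_identity_on_unit_square(self):
        sq = np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]])
        h = estimate_homography(sq, sq)
        assert np.allclose(h, np.eye(3), atol=1e-9)

    def test_minimal_four_point_case_exact(self):
        rng = np.random.default_rng(2)
        h_true = np.array([[0.8, 0.0, 5.0], [0.1, 1.1, -3.0], [0.0, 1e-4, 1.0]])
        xy = np.array([[0.0, 0], [100, 0], [100, 80], [0, 80]])
        xyh = np.column_stack([xy, np.ones(4)]) @ h_true.T
        uv = xyh[:, :2] / xyh[:, 2:]
        h = estimate_homography(xy, uv)
        back = np.column_stack([xy, np.ones(4)]) @ h.T
        assert np.allclose(back[:, :2] / back[:, 2:], uv, atol=1e-9)

    def test_degenerate_configuration_raises(self):
        line = np.column_stack([np.arange(5.0), np.arange(5.0)])
        with pytest.raises(DegenerateConfigurationError):
            estimate_homography(line, line)


class TestZhangCalibration:
    def test_noise_free_recovery(self, intr, board):
        obs, _ = sim.simulate_intrinsics_views(intr, board, corner_noise_px=0.0, seed=1)
        est, poses = zhang_calibrate(obs, board, width=intr.width, height=intr.height)
        assert abs(est.fx - intr.fx) < 0.1
        assert abs(est.fy - intr.fy) < 0.1
        assert abs(est.cx - intr.cx) < 0.5
        assert len(poses) == 8

    def test_distorted_camera_recovery(self, board):
        from dataclasses import replace

        intr = replace(
            sim.default_intrinsics(), k1=-0.15, k2=0.05, p1=1e-3, p2=-5e-4
        )
        obs, _ = sim.simulate_intrinsics_views(intr, board, corner_noise_px=0.0, seed=2)
        est, poses = zhang_calibrate(obs, board, width=intr.width, height=intr.height)
        errs = [reprojection_error_px(est, p, board, o)[0] for p, o in zip(poses, obs)]
        assert np.mean(errs) < 0.05
        assert abs(est.k1 - intr.k1) < 0.01

    def test_noise_floor_tracks_injected_noise(self, intr, board):
        obs, _ = sim.simulate_intrinsics_views(intr, board, corner_noise_px=0.2, seed=3)
        est, poses = zhang_calibrate(obs, board, width=intr.width, height=intr.height)
        errs = [reprojection_error_px(est, p, board, o)[0] for p, o in zip(poses, obs)]
        # mean Euclidean residual of an isotropic 0.2 px Gaussian is
        # 0.2 * sqrt(pi/2) ~ 0.25 px; allow +-30% around the injected sigma
        assert 0.14 < np.mean(errs) < 0.26

    def test_too_few_views_raises(self, intr, board):
        obs, _ = sim.simulate_intrinsics_views(intr, board, seed=4)
        with pytest.raises(IllConditionedError):
            zhang_calibrate(obs[:2], board, width=intr.width, height=intr.height)


class TestBoardPose:
    def test_round_trip_noise_free(self, intr, board):
        pose = sim._centered_board_pose(board, (1, 0.4, 0), 25.0, 480.0, (30, -20), roll_deg=40)
        obs = project(intr, pose, board)
        est = estimate_board_pose(intr, board, obs)
        assert np.linalg.norm(est.translation - pose.translation) < 1e-4
        assert rotation_geodesic_deg(est, pose) < 1e-5

    def test_frontoparallel_board_on_axis(self, intr, board):
        pose = sim._centered_board_pose(board, (1, 0, 0), 0.0, 400.0)
        est = estimate_board_pose(intr, board, project(intr, pose, board))
        assert abs(est.translation[2] - pose.translation[2]) < 1e-6
        assert rotation_geodesic_deg(est, pose) < 1e-6

    def test_distorted_round_trip(self, board):
        from dataclasses import replace

        intr = replace(sim.default_intrinsics(), k1=-0.12, k2=0.03, p1=5e-4)
        pose = sim._centered_board_pose(board, (0, 1, 0), 20.0, 450.0)
        est = estimate_board_pose(intr, board, project(intr, pose, board))
        assert np.linalg.norm(est.translation - pose.translation) < 1e-3

    def test_noise_envelope(self, intr, board):
        """0.5 px corner noise at ~400-500 mm keeps translation error well
        below 5 mm."""
        rng = np.random.default_rng(5)
        worst = 0.0
        for _ in range(50):
            pose = sim._centered_board_pose(
                board,
                rng.normal(size=3),
                rng.uniform(10, 35),
                rng.uniform(380, 520),
                rng.uniform(-40, 40, 2),
            )
            obs = project(intr, pose, board)
            noisy = CornerObservation(
                obs.image_points + rng.normal(scale=0.5, size=obs.image_points.shape)
            )
            est = estimate_board_pose(intr, board, noisy)
            worst = max(worst, float(np.linalg.norm(est.translation - pose.translation)))
        assert worst < 5.0


class TestFileFormats:
    def test_intrinsics_yaml_round_trip(self, tmp_path):
        intr = CameraIntrinsics(
            fx=812.5, fy=798.25, cx=640.125, cy=359.5, width=1280, height=720,
            k1=-0.11, k2=0.021, k3=-1e-3, p1=2e-4, p2=-3e-4,
        )
        cam.write_intrinsics(tmp_path / "i.yaml", intr)
        assert cam.read_intrinsics(tmp_path / "i.yaml") == intr

    def test_intrinsics_unknown_key_rejected(self, tmp_path):
        (tmp_path / "bad.yaml").write_text(
            "fx: 800\nfy: 800\ncx: 640\ncy: 360\nk1: 0\nk2: 0\nk3: 0\np1: 0\np2: 0\n"
            "width: 1280\nheight: 720\nbogus: 1\n"
        )
        with pytest.raises(ConfigError):
            cam.read_intrinsics(tmp_path / "bad.yaml")

    def test_corners_csv_round_trip(self, tmp_path, intr, board):
        obs, _ = sim.simulate_intrinsics_views(intr, board, corner_noise_px=0.1, seed=6)
        cam.write_corners_csv(tmp_path / "c.csv", obs)
        back = cam.read_corners_csv(tmp_path / "c.csv")
        assert len(back) == len(obs)
        for o1, o2 in zip(obs, back):
            assert o1.capture_id == o2.capture_id
            assert np.array_equal(o1.image_points, o2.image_points)
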