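"""Triangulation, rigid registration and error metrics."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hybridnav.carm import GantryPose
from hybridnav.errors import ConfigurationError, DegenerateGeometryError
from hybridnav.registration import (
    TRIPLET_ANGLES,
    ErrorReport,
    RigidTransform,
    SnapshotTriplet,
    apply_transform,
    error_report,
    rigid_register,
    triangulate,
    triangulate_rays,
    triplets_from_csv,
    triplets_to_csv,
)
from hybridnav.synthetic import triplet_for_point


class TestTriangulate:
    def test_noiseless_round_trip(self, parallel_model, rng):
        for _ in range(50):
            point = rng.uniform(-80.0, 80.0, size=3)
            triplet = triplet_for_point(parallel_model, point, quantize=False)
            rec = triangulate(triplet, parallel_model)
            assert np.linalg.norm(rec - point) < 1e-6

    def test_row_mean_gives_y_in_parallel_mode(self, parallel_model):
        point = np.array([12.0, -7.5, 30.0])
        triplet = triplet_for_point(parallel_model, point, quantize=False)
        rec = triangulate(triplet, parallel_model)
        rows = np.array([triplet.detections[a][1] for a in TRIPLET_ANGLES])
        y_oracle = np.mean(
            (rows - parallel_model.principal_point_px[1]) / parallel_model.px_per_mm
        )
        assert rec[1] == pytest.approx(y_oracle, abs=1e-9)

    def test_quantized_detections_stay_within_three_sigma(self, parallel_model, rng):
        # px_per_mm=2 -> quantization sigma = 1/(2*sqrt(12)) ~ 0.144 mm/axis
        sigma = 1.0 / (parallel_model.px_per_mm * np.sqrt(12.0))
        errors = []
        for _ in range(1000):
            point = rng.uniform(-60.0, 60.0, size=3)
            triplet = triplet_for_point(parallel_model, point, quantize=True)
            errors.append(np.linalg.norm(triangulate(triplet, parallel_model) - point))
        # depth is amplified by the narrow 30-degree aperture (~3.9x), so
        # the mean 3D error stays below 3 sigma_z = 3 * sigma/sin(15 deg) only
        # loosely; the spec bound is mean error < 3 * quantization sigma in z
        sigma_z = sigma / np.sin(np.deg2rad(15.0))
        assert np.mean(errors) < 3.0 * sigma_z

    def test_duplicated_view_matches_two_ray_closest_point(self, parallel_model):
        point = np.array([25.0, 10.0, -15.0])
        pose_a, pose_b = GantryPose(75.0), GantryPose(90.0)
        ray_a = parallel_model.pixel_ray(parallel_model.project(point, pose_a), pose_a)
        ray_b = parallel_model.pixel_ray(parallel_model.project(point, pose_b), pose_b)
        # duplicating one ray must not move the least-squares solution
        rec = triangulate_rays([ray_a, ray_a, ray_b])
        oracle = triangulate_rays([ray_a, ray_b])
        np.testing.assert_allclose(rec, oracle, atol=1e-9)

    def test_residual_optimality_against_random_candidates(self, parallel_model, rng):
        point = rng.uniform(-50.0, 50.0, size=3)
        triplet = triplet_for_point(parallel_model, point, quantize=True)
        rays = [
            parallel_model.pixel_ray(px, GantryPose(a))
            for a, px in triplet.detections.items()
        ]
        rec = triangulate(triplet, parallel_model)

        def residual(p):
            return sum(r.distance_to(p) ** 2 for r in rays)

        best = residual(rec)
        candidates = rec + rng.normal(0.0, 5.0, size=(10_000, 3))
        assert all(residual(c) >= best - 1e-9 for c in candidates)

    def test_parallel_rays_are_degenerate(self, parallel_model):
        pose = GantryPose(90.0)
        rays = [
            parallel_model.pixel_ray([100.0 + i, 90.0], pose) for i in range(3)
        ]
        with pytest.raises(DegenerateGeometryError):
            triangulate_rays(rays)

    def test_triplet_requires_all_angles(self):
        with pytest.raises(ConfigurationError):
            SnapshotTriplet(detections={75.0: (0.0, 0.0), 90.0: (1.0, 1.0)})


class TestRigidRegister:
    def test_identity_for_identical_point_sets(self, rng):
        pts = rng.uniform(-50.0, 50.0, size=(10, 3))
        T = rigid_register(pts, pts)
        np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(T.translation, 0.0, atol=1e-9)

    def test_recovers_known_transform(self, rng):
        pts = rng.uniform(-50.0, 50.0, size=(12, 3))
        R = Rotation.from_euler("xyz", [10.0, -25.0, 40.0], degrees=True).as_matrix()
        t = np.array([4.0, -2.0, 11.0])
        T = rigid_register(pts, pts @ R.T + t)
        np.testing.assert_allclose(T.rotation, R, atol=1e-9)
        np.testing.assert_allclose(T.translation, t, atol=1e-9)

    def test_agrees_with_scipy_align_vectors(self, rng):
        # independent cross-check on noisy correspondences
        src = rng.uniform(-50.0, 50.0, size=(20, 3))
        R = Rotation.from_euler("zyx", [33.0, 12.0, -8.0], degrees=True)
        dst = R.apply(src) + np.array([1.0, 2.0, 3.0]) + rng.normal(0, 0.5, (20, 3))
        T = rigid_register(src, dst)
        R_sp, _ = Rotation.align_vectors(
            dst - dst.mean(axis=0), src - src.mean(axis=0)
        )
        np.testing.assert_allclose(T.rotation, R_sp.as_matrix(), atol=1e-6)

    def test_reflected_target_still_yields_proper_rotation(self, rng):
        src = rng.uniform(-50.0, 50.0, size=(15, 3))
        mirrored = src * np.array([1.0, 1.0, -1.0])
        T = rigid_register(src, mirrored)
        assert np.linalg.det(T.rotation) == pytest.approx(1.0, abs=1e-9)
        # constrained optimum must not beat any proper rotation oracle draw
        best = np.sum((T.apply(src) - mirrored) ** 2)
        rng2 = np.random.default_rng(7)
        for _ in range(200):
            Rr = Rotation.random(random_state=rng2).as_matrix()
            tr = mirrored.mean(axis=0) - Rr @ src.mean(axis=0)
            assert np.sum((src @ Rr.T + tr - mirrored) ** 2) >= best - 1e-6

    def test_rotation_equivariance(self, rng):
        src = rng.uniform(-50.0, 50.0, size=(10, 3))
        dst = rng.uniform(-50.0, 50.0, size=(10, 3))
        Q = Rotation.from_euler("xyz", [15.0, 75.0, -30.0], degrees=True).as_matrix()
        base = rigid_register(src, dst)
        rotated = rigid_register(src, dst @ Q.T)
        np.testing.assert_allclose(rotated.rotation, Q @ base.rotation, atol=1e-9)

    def test_collinear_points_degenerate(self):
        line = np.outer(np.arange(5.0), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(DegenerateGeometryError):
            rigid_register(line, line + 1.0)

    def test_too_few_points_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            rigid_register(np.zeros((2, 3)), np.ones((2, 3)))


class TestApplyTransform:
    def test_identity_and_inverse(self, rng):
        pts = rng.uniform(-10.0, 10.0, size=(7, 3))
        T = RigidTransform(
            rotation=Rotation.from_euler("xyz", [5.0, 10.0, 15.0], degrees=True).as_matrix(),
            translation=np.array([1.0, -2.0, 3.0]),
        )
        np.testing.assert_allclose(
            apply_transform(RigidTransform.identity(), pts), pts, atol=1e-12
        )
        np.testing.assert_allclose(
            apply_transform(T.inverse(), apply_transform(T, pts)), pts, atol=1e-12
        )

    def test_is_isometry(self, rng):
        pts = rng.uniform(-10.0, 10.0, size=(20, 3))
        T = RigidTransform(
            rotation=Rotation.random(random_state=np.random.default_rng(3)).as_matrix(),
            translation=np.array([8.0, 0.5, -4.0]),
        )
        out = apply_transform(T, pts)
        d_in = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        d_out = np.linalg.norm(out[:, None] - out[None, :], axis=2)
        np.testing.assert_allclose(d_in, d_out, atol=1e-12)

    def test_yaml_round_trip(self, tmp_path):
        T = RigidTransform(
            rotation=Rotation.from_euler("y", 20.0, degrees=True).as_matrix(),
            translation=np.array([0.1, 0.2, 0.3]),
        )
        T.to_yaml(tmp_path / "t.yaml")
        loaded = RigidTransform.from_yaml(tmp_path / "t.yaml")
        np.testing.assert_allclose(loaded.rotation, T.rotation, atol=1e-12)
        np.testing.assert_allclose(loaded.translation, T.translation, atol=1e-12)


class TestErrorReport:
    def test_uncompensated_tracking_error_combination(self):
        # per-axis RMS errors of an uncompensated EMT stream combine to the
        # quadratic-mean RMSE
        report = ErrorReport(e_x=2.04, e_y=1.68, e_z=23.10, n=12857)
        assert report.rmse == pytest.approx(13.42, abs=0.005)

    def test_linear_compensated_combination(self):
        report = ErrorReport(e_x=0.27, e_y=0.31, e_z=0.25, n=12857)
        assert round(report.rmse, 2) == pytest.approx(0.28)

    def test_identical_point_sets_report_zero(self, rng):
        pts = rng.uniform(-5.0, 5.0, size=(9, 3))
        report = error_report(pts, pts)
        assert report.e_x == report.e_y == report.e_z == report.rmse == 0.0

    def test_axis_rmse_computed_from_differences(self, rng):
        est = rng.normal(size=(40, 3))
        ref = rng.normal(size=(40, 3))
        report = error_report(est, ref)
        diff = est - ref
        np.testing.assert_allclose(
            [report.e_x, report.e_y, report.e_z],
            np.sqrt(np.mean(diff**2, axis=0)),
            atol=1e-12,
        )

    def test_combined_rmse_bounds(self, rng):
        for _ in range(20):
            est = rng.normal(size=(15, 3))
            ref = rng.normal(size=(15, 3))
            r = error_report(est, ref)
            top = max(r.e_x, r.e_y, r.e_z)
            assert top / np.sqrt(3.0) - 1e-12 <= r.rmse <= top + 1e-12

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            error_report(np.zeros((3, 3)), np.zeros((4, 3)))


class TestCsvRoundTrip:
    def test_triplets_round_trip(self, tmp_path, parallel_model, rng):
        points = rng.uniform(-40.0, 40.0, size=(4, 3))
        triplets = [
            triplet_for_point(parallel_model, p, timestamp_s=float(i))
            for i, p in enumerate(points)
        ]
        path = tmp_path / "triplets.csv"
        triplets_to_csv(triplets, path)
        loaded = triplets_from_csv(path)
        assert len(loaded) == len(triplets)
        for a, b in zip(loaded, triplets):
            for angle in TRIPLET_ANGLES:
                np.testing.assert_allclose(a.detections[angle], b.detections[angle])
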