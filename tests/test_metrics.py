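"""ADD / ADD-S / 2D projection error / IOU and the evaluation report."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from silpose.geometry import Pose, mesh_diameter
from silpose.metrics import (add_metric, add_s_metric, evaluate, iou,
                             projection_error_2d)
from silpose.render import MaskImage
from tests.conftest import random_pose


class TestADD:
    def test_identical_poses_zero(self, rng):
        pts = rng.normal(size=(20, 3))
        p = random_pose(0)
        assert add_metric(pts, p, p) == 0.0

    def test_pure_translation(self, rng):
        pts = rng.normal(size=(20, 3))
        gt = random_pose(1)
        pred = Pose(gt.R, gt.t + np.array([0.3, 0.0, 0.0]))
        assert add_metric(pts, pred, gt) == pytest.approx(0.3, rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_point_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(50, 3))
        pred, gt = random_pose(seed), random_pose(seed + 100)
        oracle = np.mean([np.linalg.norm((pred.R @ p + pred.t)
                                         - (gt.R @ p + gt.t)) for p in pts])
        assert add_metric(pts, pred, gt) == pytest.approx(oracle, abs=1e-12)

    def test_empty_point_set_rejected(self):
        with pytest.raises(ValueError):
            add_metric(np.zeros((0, 3)), random_pose(0), random_pose(1))


class TestADDS:
    def test_identical_poses_zero(self, rng):
        pts = rng.normal(size=(20, 3))
        p = random_pose(2)
        assert add_s_metric(pts, p, p) == 0.0

    def test_symmetric_square_rotated_90(self):
        # centered square: 90° turn about its symmetry axis permutes the
        # corners, so ADD-S vanishes while ADD does not
        square = np.array([[1, 1, 0], [1, -1, 0], [-1, -1, 0], [-1, 1, 0]],
                          dtype=float)
        gt = Pose(np.eye(3), [0, 0, 5.0])
        Rz90 = Pose.from_rotvec([0, 0, np.pi / 2], [0, 0, 5.0])
        # exhaustive nearest-point oracle on the 4-point set
        a = Rz90.apply(square)
        b = gt.apply(square)
        oracle = np.mean([min(np.linalg.norm(p - q) for q in b) for p in a])
        assert oracle == pytest.approx(0.0, abs=1e-12)
        assert add_s_metric(square, Rz90, gt) == pytest.approx(0.0, abs=1e-12)
        assert add_metric(square, Rz90, gt) > 1.0

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_add_s_never_exceeds_add(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(30, 3))
        pred, gt = random_pose(seed), random_pose(seed + 1)
        assert add_s_metric(pts, pred, gt) <= add_metric(pts, pred, gt) + 1e-12

    @pytest.mark.parametrize("seed", range(20))
    def test_kdtree_matches_quadratic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(10, 300)
        pts = rng.normal(size=(n, 3))
        pred, gt = random_pose(seed + 10), random_pose(seed + 20)
        a, b = pred.apply(pts), gt.apply(pts)
        oracle = np.mean(np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2)
                                 .sum(-1)).min(axis=1))
        assert add_s_metric(pts, pred, gt) == pytest.approx(oracle, abs=1e-12)


class TestProjectionError2D:
    def test_identical_poses_zero(self, camera_640, rng):
        pts = rng.normal(size=(8, 3))
        p = random_pose(3)
        assert projection_error_2d(pts, p, p, camera_640) == 0.0

    def test_constructed_five_pixel_shift(self, camera_640):
        # lateral shift Δx at depth Z: Δu = fx Δx / Z exactly, for points
        # at identical depth
        Z = 4.0
        pts = np.array([[x, y, 0.0] for x in (-0.2, 0.2) for y in (-0.2, 0.2)])
        gt = Pose(np.eye(3), [0, 0, Z])
        dx = 5.0 * Z / camera_640.fx
        pred = Pose(np.eye(3), [dx, 0, Z])
        err = projection_error_2d(pts, pred, gt, camera_640)
        assert err == pytest.approx(5.0, rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_loop_oracle(self, seed, camera_640):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-0.4, 0.4, (8, 3))
        pred, gt = random_pose(seed + 30), random_pose(seed + 40)
        K = camera_640
        oracle = []
        for p in pts:
            a = pred.R @ p + pred.t
            b = gt.R @ p + gt.t
            ua = (K.fx * a[0] / a[2] + K.cx, K.fy * a[1] / a[2] + K.cy)
            ub = (K.fx * b[0] / b[2] + K.cx, K.fy * b[1] / b[2] + K.cy)
            oracle.append(np.hypot(ua[0] - ub[0], ua[1] - ub[1]))
        assert projection_error_2d(pts, pred, gt, K) == \
            pytest.approx(np.mean(oracle), abs=1e-12)

    def test_point_behind_camera_raises(self, camera_640):
        pts = np.array([[0.0, 0.0, 0.0]])
        gt = Pose(np.eye(3), [0, 0, 5.0])
        behind = Pose(np.eye(3), [0, 0, -5.0])
        with pytest.raises(ValueError):
            projection_error_2d(pts, behind, gt, camera_640)


class TestIOU:
    def test_identical_masks(self):
        m = MaskImage((np.random.default_rng(0).random((20, 20)) > 0.5)
                      .astype(float))
        assert iou(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((10, 10))
        b = np.zeros((10, 10))
        a[:3], b[7:] = 1, 1
        assert iou(MaskImage(a), MaskImage(b)) == 0.0

    def test_half_overlapping_rectangles(self):
        a = np.zeros((10, 20))
        b = np.zeros((10, 20))
        a[:, :10] = 1    # area 100
        b[:, 5:15] = 1   # area 100, overlap 50
        assert iou(MaskImage(a), MaskImage(b)) == pytest.approx(1.0 / 3.0)

    def test_both_empty_is_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert iou(MaskImage(np.zeros((5, 5))),
                       MaskImage(np.zeros((5, 5)))) == 0.0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            iou(MaskImage(np.zeros((5, 5))), MaskImage(np.zeros((6, 5))))


class TestEvaluate:
    def test_perfect_predictions(self, cube, camera_640, cube_keypoints):
        pairs = [(random_pose(s), random_pose(s)) for s in range(4)]
        rep = evaluate(pairs, cube, camera_640, keypoints=cube_keypoints)
        for v in rep.accuracies.values():
            assert v == 100.0

    def test_threshold_counting(self, cube, camera_640, cube_keypoints):
        # exactly 3 of 4 samples under the 0.1 d ADD threshold
        diam = mesh_diameter(cube)
        gt = Pose(np.eye(3), [0, 0, 6.0])
        offsets = [0.01, 0.05, 0.08, 0.5]  # fractions of diameter
        pairs = [(Pose(np.eye(3), gt.t + np.array([f * diam, 0, 0])), gt)
                 for f in offsets]
        rep = evaluate(pairs, cube, camera_640, keypoints=cube_keypoints)
        assert rep.accuracies["ADD(0.1d)"] == pytest.approx(75.0)

    def test_threshold_accuracy_monotone(self, cube, camera_640,
                                         cube_keypoints):
        rng = np.random.default_rng(0)
        pairs = []
        for s in range(8):
            gt = random_pose(s)
            pred = Pose(gt.R, gt.t + rng.normal(0, 0.03, 3))
            pairs.append((pred, gt))
        rep = evaluate(pairs, cube, camera_640, keypoints=cube_keypoints)
        assert rep.accuracies["2Dproj(5px)"] >= rep.accuracies["2Dproj(3px)"]

    def test_world_frame_invariance(self, camera_640):
        # metrics built from relative pose discrepancies are unchanged by a
        # common rigid change of both poses' world frame
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(30, 3))
        pred, gt = random_pose(50), random_pose(51)
        Q = random_pose(52)
        pred2, gt2 = pred.compose(Q), gt.compose(Q)
        ptsQ = (pts - Q.t) @ Q.R  # pre-images under Q: Q.apply(ptsQ) == pts
        assert add_metric(Q.inverse().apply(pts), pred2, gt2) == \
            pytest.approx(add_metric(pts, pred, gt), abs=1e-9)
        assert add_s_metric(Q.inverse().apply(pts), pred2, gt2) == \
            pytest.approx(add_s_metric(pts, pred, gt), abs=1e-9)

    def test_iou_only_mode_without_ground_truth(self, cube, camera_640):
        from silpose.render import rasterize_hard
        pose = random_pose(60)
        mask = rasterize_hard(cube, pose, camera_640)
        rep = evaluate([(pose, None)], cube, camera_640, masks=[mask])
        assert rep.mean_iou == pytest.approx(1.0)
        assert rep.accuracies == {}

    def test_report_serialization(self, cube, camera_640, cube_keypoints,
                                  tmp_path):
        pairs = [(random_pose(s), random_pose(s)) for s in range(2)]
        rep = evaluate(pairs, cube, camera_640, keypoints=cube_keypoints)
        rep.save_json(tmp_path / "r.json")
        rep.save_csv(tmp_path / "r.csv")
        import json
        loaded = json.loads((tmp_path / "r.json").read_text())
        assert loaded["n_samples"] == 2
        assert (tmp_path / "r.csv").read_text().count("\n") == 2
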