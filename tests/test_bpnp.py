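"""Differentiable PnP: forward solve, reprojection loss, implicit backward."""

import numpy as np
import pytest

from silpose import bpnp as B
from silpose.autodiff import Tensor
from silpose.geometry import (FeaturePoints3D, Pose, Projections2D, project,
                              rotation_geodesic_deg)
from tests.conftest import random_pose


def make_instance(seed, camera, keypoints, noise=0.0):
    rng = np.random.default_rng(seed)
    pose = random_pose(seed)
    x = project(keypoints, pose, camera).points
    if noise:
        x = x + rng.normal(0.0, noise, x.shape)
    return pose, x


def fd_backward_oracle(x, z, K, grad_wrt_pose, h=1e-4):
    """Re-solve PnP with each coordinate perturbed; difference the poses."""
    g = np.zeros_like(x)
    base = B.solve_pnp(B.PnPProblem(Projections2D(x), z, K))
    for i in range(x.shape[0]):
        for c in range(2):
            xp, xm = x.copy(), x.copy()
            xp[i, c] += h
            xm[i, c] -= h
            sp = B.solve_pnp(B.PnPProblem(Projections2D(xp), z, K),
                             init=base.pose)
            sm = B.solve_pnp(B.PnPProblem(Projections2D(xm), z, K),
                             init=base.pose)
            g[i, c] = grad_wrt_pose @ (sp.pose.as_params()
                                       - sm.pose.as_params()) / (2 * h)
    return g


class TestReprojectionLoss:
    def test_exact_projection_zero(self, camera_640, cube_keypoints):
        pose, x = make_instance(0, camera_640, cube_keypoints)
        loss = B.reprojection_loss(Projections2D(x), None, pose,
                                   cube_keypoints, camera_640)
        assert loss == pytest.approx(0.0, abs=1e-16)

    def test_one_pixel_offset_each(self, camera_640, cube_keypoints):
        pose, x = make_instance(1, camera_640, cube_keypoints)
        x = x + np.array([1.0, 0.0])
        loss = B.reprojection_loss(Projections2D(x), None, pose,
                                   cube_keypoints, camera_640)
        assert loss == pytest.approx(8.0, rel=1e-12)

    def test_lambda_doubles_with_equal_ground_truth(self, camera_640,
                                                    cube_keypoints):
        pose, x = make_instance(2, camera_640, cube_keypoints, noise=1.0)
        base = B.reprojection_loss(Projections2D(x), None, pose,
                                   cube_keypoints, camera_640, 0.0)
        both = B.reprojection_loss(Projections2D(x), Projections2D(x), pose,
                                   cube_keypoints, camera_640, 1.0)
        assert both == pytest.approx(2 * base, rel=1e-12)

    def test_fewer_than_four_points_rejected(self, camera_640):
        z = FeaturePoints3D(np.random.default_rng(0).normal(size=(3, 3)))
        x = Projections2D(np.zeros((3, 2)))
        with pytest.raises(ValueError):
            B.reprojection_loss(x, None, Pose.identity(), z, camera_640)


class TestSolvePnP:
    @pytest.mark.parametrize("seed", range(10))
    def test_exact_recovery_noiseless(self, seed, camera_640, cube_keypoints):
        pose, x = make_instance(seed, camera_640, cube_keypoints)
        sol = B.solve_pnp(B.PnPProblem(Projections2D(x), cube_keypoints,
                                       camera_640))
        assert sol.converged
        assert rotation_geodesic_deg(sol.pose, pose) < 1e-4
        assert np.linalg.norm(sol.pose.t - pose.t) < 1e-6

    def test_stationarity_certificate(self, camera_640, cube_keypoints):
        _, x = make_instance(3, camera_640, cube_keypoints, noise=0.5)
        sol = B.solve_pnp(B.PnPProblem(Projections2D(x), cube_keypoints,
                                       camera_640))
        assert sol.converged
        assert sol.stationarity < 1e-8

    def test_noise_degrades_smoothly(self, camera_640, cube_keypoints):
        errs = []
        for noise in (0.1, 1.0, 4.0):
            rots = []
            for seed in range(10):
                pose, x = make_instance(seed, camera_640, cube_keypoints,
                                        noise=noise)
                sol = B.solve_pnp(B.PnPProblem(Projections2D(x),
                                               cube_keypoints, camera_640))
                rots.append(rotation_geodesic_deg(sol.pose, pose))
            errs.append(np.mean(rots))
        assert errs[0] < errs[1] < errs[2]

    def test_three_points_rejected(self, camera_640):
        z = FeaturePoints3D(np.random.default_rng(1).normal(size=(3, 3)))
        with pytest.raises(ValueError):
            B.solve_pnp(B.PnPProblem(Projections2D(np.zeros((3, 2))), z,
                                     camera_640))

    def test_invisible_points_masked(self, camera_640, cube_keypoints):
        pose, x = make_instance(4, camera_640, cube_keypoints)
        vis = np.ones(8, bool)
        vis[:2] = False
        x_bad = x.copy()
        x_bad[:2] = 1e6  # corrupt masked entries: must not matter
        sol = B.solve_pnp(B.PnPProblem(Projections2D(x_bad, vis),
                                       cube_keypoints, camera_640))
        assert rotation_geodesic_deg(sol.pose, pose) < 1e-4

    def test_frame_equivariance(self, camera_640, cube_keypoints):
        from scipy.spatial.transform import Rotation
        pose, x = make_instance(5, camera_640, cube_keypoints)
        Q = Rotation.from_rotvec([0.4, -0.2, 0.7]).as_matrix()
        z_rot = FeaturePoints3D(cube_keypoints.points @ Q.T)
        sol = B.solve_pnp(B.PnPProblem(Projections2D(x), z_rot, camera_640))
        # recovered rotation must absorb Q: R' Q = R
        assert np.allclose(sol.pose.R @ Q, pose.R, atol=1e-6)


class TestImplicitBackward:
    def test_zero_pose_gradient_gives_zero(self, camera_640, cube_keypoints):
        _, x = make_instance(6, camera_640, cube_keypoints, noise=0.5)
        prob = B.PnPProblem(Projections2D(x), cube_keypoints, camera_640)
        sol = B.solve_pnp(prob)
        g = B.implicit_backward(sol, prob, np.zeros(6))
        assert np.all(g == 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_resolve_oracle(self, seed, camera_640, cube_keypoints):
        rng = np.random.default_rng(seed)
        _, x = make_instance(seed + 50, camera_640, cube_keypoints, noise=1.0)
        prob = B.PnPProblem(Projections2D(x), cube_keypoints, camera_640)
        sol = B.solve_pnp(prob)
        gw = rng.normal(size=6)
        got = B.implicit_backward(sol, prob, gw)
        want = fd_backward_oracle(x, cube_keypoints, camera_640, gw)
        assert np.linalg.norm(got - want) / np.linalg.norm(want) < 1e-3

    def test_duplicated_point_splits_gradient(self, camera_640,
                                              cube_keypoints):
        rng = np.random.default_rng(7)
        pose = random_pose(7)
        zp = cube_keypoints.points.copy()
        zp[1] = zp[0]
        z = FeaturePoints3D(zp)
        x = project(z, pose, camera_640).points + rng.normal(0, 0.5, (8, 2))
        x[1] = x[0]
        prob = B.PnPProblem(Projections2D(x), z, camera_640)
        sol = B.solve_pnp(prob)
        g = B.implicit_backward(sol, prob, rng.normal(size=6))
        assert np.allclose(g[0], g[1], atol=1e-12)


class TestBPnPLayer:
    def test_composed_gradient_matches_finite_differences(self, camera_640,
                                                          cube_keypoints):
        rng = np.random.default_rng(11)
        pose, xpts = make_instance(11, camera_640, cube_keypoints, noise=1.0)
        x_star = project(cube_keypoints, pose, camera_640).points

        def composed(xv):
            xt = Tensor(xv, requires_grad=True)
            y, sol = B.bpnp_layer(xt, cube_keypoints, camera_640)
            loss = B.reprojection_loss_t(xt, x_star, y, cube_keypoints,
                                         camera_640)
            return xt, loss

        xt, loss = composed(xpts)
        loss.backward()
        got = xt.grad.copy()
        fd = np.zeros_like(xpts)
        h = 1e-4
        for i in range(8):
            for c in range(2):
                xp, xm = xpts.copy(), xpts.copy()
                xp[i, c] += h
                xm[i, c] -= h
                fd[i, c] = (composed(xp)[1].item()
                            - composed(xm)[1].item()) / (2 * h)
        assert np.linalg.norm(got - fd) / np.linalg.norm(fd) < 1e-3

    def test_stationary_configuration_zero_gradient(self, camera_640,
                                                    cube_keypoints):
        pose, x = make_instance(12, camera_640, cube_keypoints)
        xt = Tensor(x, requires_grad=True)
        y, sol = B.bpnp_layer(xt, cube_keypoints, camera_640)
        # loss = distance of solved pose params to themselves (frozen copy)
        diff = y - Tensor(y.data.copy())
        (diff * diff).sum().backward()
        assert np.abs(xt.grad).max() < 1e-6

    @pytest.mark.parametrize("seed", range(5))
    def test_gradient_step_decreases_composed_loss(self, seed, camera_640,
                                                   cube_keypoints):
        pose, x_clean = make_instance(seed + 200, camera_640, cube_keypoints)
        rng = np.random.default_rng(seed)
        x = x_clean + rng.normal(0, 2.0, x_clean.shape)
        x_star = x_clean

        def loss_at(xv):
            xt = Tensor(xv, requires_grad=True)
            y, _ = B.bpnp_layer(xt, cube_keypoints, camera_640)
            loss = B.reprojection_loss_t(xt, x_star, y, cube_keypoints,
                                         camera_640)
            return xt, loss

        xt, loss = loss_at(x)
        loss.backward()
        stepped = x - 1e-4 * xt.grad
        assert loss_at(stepped)[1].item() < loss.item()
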