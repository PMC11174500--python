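"""End-to-end pose inference and silhouette-based pose refinement.

``infer_pose`` chains the trained heatmap network, the soft-argmax
coordinate read-out and the PnP layer: mask -> keypoint heatmaps ->
2D coordinates -> 6D pose, with per-keypoint confidences and a reprojected
silhouette for visual inspection.

``refine_pose`` polishes a pose estimate by minimising the differentiable
rendering loss (the silhouette-consistency term of the training
objective, restricted to the pose variable) with L-BFGS over a
coarse-to-fine sharpness sweep, plus deterministic rotation restarts when
the result still disagrees with the mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .bpnp import PnPProblem, solve_pnp
from .geometry import (CameraIntrinsics, FeaturePoints3D, Pose, Projections2D,
                       TriMesh)
from .metrics import iou
from .network import HeatmapNetwork, regress_coordinates
from .render import (MaskImage, rasterize_hard, render_loss,
                     render_loss_pose_grad)

__all__ = ["InferenceResult", "infer_pose", "refine_pose"]


@dataclass
class InferenceResult:
    pose: Pose | None
    success: bool
    keypoints2d: Projections2D | None
    confidences: np.ndarray | None
    residual: float | None
    reprojected: MaskImage | None
    iou_vs_input: float | None
    message: str = ""
    refine_trace: list = field(default_factory=list)


def infer_pose(mask: MaskImage, net: HeatmapNetwork, mesh: TriMesh,
               K: CameraIntrinsics, keypoints: FeaturePoints3D | None = None,
               confidence_threshold: float = 0.2,
               refine: bool = False, refine_iters: int = 50) -> InferenceResult:
    """Two-stage pose inference from a binary silhouette.

    Keypoints whose heatmap peak falls below ``confidence_threshold`` are
    dropped from the PnP solve; with fewer than 4 confident keypoints the
    solve is skipped (refinement-only fallback when ``refine`` is set and
    a previous pose is unavailable -> failure report).
    """
    from .geometry import farthest_point_sampling
    if keypoints is None:
        keypoints = farthest_point_sampling(mesh, net.config.n_keypoints)
    if mask.area() == 0:
        return InferenceResult(None, False, None, None, None, None, None,
                               message="empty input mask")

    hm = net.predict_heatmap(mask)
    conf = hm.maps.reshape(len(hm.maps), -1).max(axis=1)
    coords = regress_coordinates(hm, tau=net.config.tau)
    usable = coords.visibility & (conf >= confidence_threshold)

    if usable.sum() < 4:
        msg = (f"only {int(usable.sum())} confident keypoints (<4); "
               "pose solve skipped")
        warnings.warn(msg, stacklevel=2)
        return InferenceResult(None, False, coords, conf, None, None, None,
                               message=msg)

    problem = PnPProblem(Projections2D(coords.points, usable), keypoints, K)
    sol = solve_pnp(problem)
    pose = sol.pose
    trace = []
    if refine:
        pose, trace = refine_pose(mask, pose, mesh, K, iters=refine_iters,
                                  return_trace=True)
    reproj = rasterize_hard(mesh, pose, K)
    return InferenceResult(
        pose=pose, success=sol.converged, keypoints2d=coords,
        confidences=conf, residual=sol.residual, reprojected=reproj,
        iou_vs_input=iou(reproj, mask),
        message="" if sol.converged else "PnP did not converge",
        refine_trace=trace)


def refine_pose(mask: MaskImage, init: Pose, mesh: TriMesh,
                K: CameraIntrinsics, iters: int = 80,
                sharpness_schedule=(5.0, 15.0),
                restart_iou: float = 0.98, restart_deg: float = 8.0,
                return_trace: bool = False):
    """Silhouette-driven pose refinement.

    Minimises the rendering loss over the 6-dof pose with L-BFGS on the
    analytic soft-rasterizer gradient, sweeping the sharpness
    coarse-to-fine.  When the refined silhouette still disagrees with the
    mask (IOU below ``restart_iou``), the optimisation retries from six
    deterministic ±``restart_deg``-degree rotation perturbations and keeps
    the lowest-loss result — silhouette landscapes have shallow local
    minima a few degrees from the true pose.  The returned pose never has
    a higher rendering loss than the initial one.  Raises if the initial
    silhouette does not overlap the observed mask at all (a coarse search
    must supply a better start).
    """
    init_mask = rasterize_hard(mesh, init, K)
    if float((init_mask.pixels * mask.pixels).sum()) == 0.0:
        raise ValueError("initial silhouette does not overlap the mask; "
                         "run a coarse pose search first")
    # restrict the loss to a window around the union of both silhouettes:
    # pixels far from either contour carry no gradient and dominate cost
    K, mask = _crop_roi(mask, init_mask, K)
    trace: list = []
    pose = _descend(mask, init, mesh, K, iters, sharpness_schedule, trace)

    if iou(rasterize_hard(mesh, pose, K), mask) < restart_iou:
        final_sharp = sharpness_schedule[-1]
        best_loss = render_loss(_soft(mesh, pose, K, final_sharp), mask)
        for axis in range(3):
            for sgn in (1.0, -1.0):
                d = np.zeros(3)
                d[axis] = sgn * np.radians(restart_deg)
                start = Pose(pose.R @ Pose.from_rotvec(d, [0, 0, 0]).R,
                             pose.t)
                if float((rasterize_hard(mesh, start, K).pixels
                          * mask.pixels).sum()) == 0.0:
                    continue
                cand = _descend(mask, start, mesh, K, max(iters * 3 // 4, 1),
                                sharpness_schedule, [])
                loss = render_loss(_soft(mesh, cand, K, final_sharp), mask)
                if loss < best_loss:
                    best_loss, pose = loss, cand
                    if not trace or loss < trace[-1]:
                        trace.append(loss)

    # guarantee the contract against the initial loss at the final sharpness
    final_sharp = sharpness_schedule[-1]
    if render_loss(_soft(mesh, pose, K, final_sharp), mask) > \
            render_loss(_soft(mesh, init, K, final_sharp), mask):
        pose = init
    return (pose, trace) if return_trace else pose


def _descend(mask, init, mesh, K, iters, sharpness_schedule, trace):
    from scipy.optimize import minimize

    params = init.as_params()
    for sharp in sharpness_schedule:
        best = [np.inf, params]

        def objective(p, _s=sharp, _b=best):
            val, grad = render_loss_pose_grad(mesh, Pose.from_params(p),
                                              mask, K, sharpness=_s)
            if val < _b[0]:
                _b[0], _b[1] = val, p.copy()
                if not trace or val < trace[-1]:
                    trace.append(val)
            return val, grad

        minimize(objective, params, jac=True, method="L-BFGS-B",
                 options={"maxiter": max(iters // len(sharpness_schedule), 1),
                          "ftol": 1e-14, "gtol": 1e-12})
        params = best[1]
    return Pose.from_params(params)


def _soft(mesh, pose, K, sharp):
    from .render import rasterize_soft
    return rasterize_soft(mesh, pose, K, sharpness=sharp)


def _crop_roi(mask: MaskImage, init_mask: MaskImage, K: CameraIntrinsics,
              margin_frac: float = 0.15, margin_px: int = 10):
    """Crop mask + intrinsics to the union silhouette bounding box."""
    both = (mask.pixels > 0.5) | (init_mask.pixels > 0.5)
    vs, us = np.nonzero(both)
    span = max(us.max() - us.min(), vs.max() - vs.min())
    m = int(margin_frac * span) + margin_px
    u0 = max(int(us.min()) - m, 0)
    u1 = min(int(us.max()) + m + 1, K.width)
    v0 = max(int(vs.min()) - m, 0)
    v1 = min(int(vs.max()) + m + 1, K.height)
    K_roi = CameraIntrinsics(K.fx, K.fy, K.cx - u0, K.cy - v0,
                             u1 - u0, v1 - v0, is_roi=True)
    return K_roi, MaskImage(mask.pixels[v0:v1, u0:u1], binary=True)
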