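"""Back-propagatable Perspective-n-Point.

Forward pass: the pose ``y`` minimizing the sum of squared reprojection
errors of the 2D keypoint predictions ``x`` against the projections of the
3D model keypoints ``z`` (Levenberg–Marquardt on axis-angle + translation,
seeded by a DLT closed-form estimate plus deterministic rotation restarts).

Backward pass: at the optimum the stationarity condition

    f(x, y, z, K) = ∂l_p/∂y = 0

holds, so by the implicit function theorem

    ∂y/∂x = -[∂f/∂y]^-1 [∂f/∂x].

``∂f/∂x`` is analytic; ``∂f/∂y`` (the 6×6 Hessian of the reprojection loss)
is obtained by complex-step differentiation of the analytic gradient ``f``,
which is exact to machine precision.  The layer composes with the autodiff
engine so that gradients of any training loss flow through the pose into
the 2D keypoints and from there into network parameters.

The training-time reprojection loss carries an extra term weighted by λ on
the ground-truth projections x*; the forward solve itself uses only the
x-term (x* does not exist at inference and the stationarity condition must
refer to the solver's own objective).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation as _Rot

from .autodiff import Tensor
from .geometry import (CameraIntrinsics, FeaturePoints3D, Pose, Projections2D)

GRAD_TOL = 1e-8
MAX_ITER = 200
RESTART_TOL = 10.0  # px^2 per point: above this, rotation restarts are tried
HESSIAN_REG = 1e-10
COND_LIMIT = 1e12

__all__ = ["PnPProblem", "PnPSolution", "reprojection_loss", "solve_pnp",
           "implicit_backward", "bpnp_layer", "reprojection_loss_t"]


@dataclass
class PnPProblem:
    """A 2D–3D correspondence set for pose estimation."""

    x: Projections2D
    z: FeaturePoints3D
    K: CameraIntrinsics
    x_star: Projections2D | None = None
    lambda_weight: float = 1.0

    def __post_init__(self):
        if len(self.x) != len(self.z):
            raise ValueError("x and z must have the same length")
        if self.lambda_weight < 0:
            raise ValueError("lambda_weight must be non-negative")

    @property
    def usable(self) -> np.ndarray:
        """Mask of correspondences entering both reprojection sums."""
        m = self.x.visibility.copy()
        if self.x_star is not None:
            m &= self.x_star.visibility
        return m


@dataclass
class PnPSolution:
    pose: Pose
    residual: float
    converged: bool
    iterations: int
    stationarity: float  # ||∂l_p/∂y||_inf at the solution


# ---------------------------------------------------------------------------
# complex-step-safe projection machinery
# ---------------------------------------------------------------------------

def _rotvec_matrix(w: np.ndarray) -> np.ndarray:
    """Rodrigues rotation matrix; algebraic form valid for complex w."""
    theta2 = w @ w
    theta = np.sqrt(theta2 + 0j) if np.iscomplexobj(w) else np.sqrt(theta2)
    K = np.array([[0, -w[2], w[1]], [w[2], 0, -w[0]], [-w[1], w[0], 0]],
                 dtype=w.dtype)
    if abs(theta) < 1e-12:
        return np.eye(3, dtype=w.dtype) + K + 0.5 * (K @ K)
    s = np.sin(theta) / theta
    c = (1.0 - np.cos(theta)) / theta2
    return np.eye(3, dtype=w.dtype) + s * K + c * (K @ K)


def _project_params(y: np.ndarray, z: np.ndarray, K: CameraIntrinsics):
    """Projections (N×2) and Jacobians (N×2×6) at pose params y (complex-safe).

    The rotation derivative uses the closed form
    ``∂(R v)/∂ω_i = [(ω_i ω + ω × ((I − R) e_i)) / ‖ω‖²] × (R v)``
    (``e_i × v`` in the ω → 0 limit)."""
    w, t = y[:3], y[3:]
    R = _rotvec_matrix(w)
    Rv = z @ R.T                    # N×3
    cam = Rv + t
    X, Y, Z = cam[:, 0], cam[:, 1], cam[:, 2]
    u = K.fx * X / Z + K.cx
    v = K.fy * Y / Z + K.cy
    proj = np.stack([u, v], axis=1)

    n = len(z)
    theta2 = w @ w
    eye = np.eye(3, dtype=R.dtype)
    if abs(theta2) < 1e-16:
        axes = eye                  # column i of d(Rv)/dω is e_i × v
    else:
        axes = np.stack([(w[i] * w + np.cross(w, eye[:, i] - R[:, i])) / theta2
                         for i in range(3)])
    # dRv[:, :, i] = axes[i] × Rv
    dRv = np.stack([np.cross(axes[i], Rv) for i in range(3)], axis=2)
    dcam = np.concatenate([dRv, np.broadcast_to(eye, (n, 3, 3))], axis=2)

    dpix = np.zeros((n, 2, 3), dtype=y.dtype)
    dpix[:, 0, 0] = K.fx / Z
    dpix[:, 0, 2] = -K.fx * X / Z ** 2
    dpix[:, 1, 1] = K.fy / Z
    dpix[:, 1, 2] = -K.fy * Y / Z ** 2
    J = dpix @ dcam                 # N×2×6
    return proj, J


def _grad_lp(y: np.ndarray, x: np.ndarray, z: np.ndarray,
             K: CameraIntrinsics) -> np.ndarray:
    """f(y) = ∂/∂y Σ_i ||x_i - π(y, z_i)||²  (6-vector, complex-safe)."""
    proj, J = _project_params(y, z, K)
    r = proj - x  # N×2
    return 2.0 * np.einsum("nij,ni->j", J, r)


# ---------------------------------------------------------------------------
# reprojection loss (Eq 2 shape)
# ---------------------------------------------------------------------------

def reprojection_loss(x: Projections2D, x_star: Projections2D | None,
                      pose: Pose, z: FeaturePoints3D, K: CameraIntrinsics,
                      lambda_weight: float = 1.0) -> float:
    """l_p = Σ‖x_i − π(y,z_i)‖² + λ Σ‖x*_i − π(y,z_i)‖² over usable points.

    Visibility masks are applied symmetrically to both sums.  Requires at
    least 4 usable correspondences.
    """
    mask = x.visibility.copy()
    if x_star is not None:
        mask = mask & x_star.visibility
    if mask.sum() < 4:
        raise ValueError("need at least 4 usable correspondences")
    proj, _ = _project_params(pose.as_params(), z.points[mask], K)
    loss = float(((x.points[mask] - proj) ** 2).sum())
    if x_star is not None and lambda_weight > 0:
        loss += lambda_weight * float(((x_star.points[mask] - proj) ** 2).sum())
    return loss


# ---------------------------------------------------------------------------
# forward solve
# ---------------------------------------------------------------------------

def _dlt_init(x: np.ndarray, z: np.ndarray, K: CameraIntrinsics) -> Pose | None:
    """Closed-form projective (DLT) pose estimate from ≥6 correspondences."""
    n = len(z)
    if n < 6:
        return None
    Kinv = np.linalg.inv(K.matrix)
    m = (Kinv @ np.column_stack([x, np.ones(n)]).T).T  # normalized rays
    A = np.zeros((2 * n, 12))
    for i in range(n):
        Xh = np.append(z[i], 1.0)
        A[2 * i, 0:4] = Xh
        A[2 * i, 8:12] = -m[i, 0] * Xh
        A[2 * i + 1, 4:8] = Xh
        A[2 * i + 1, 8:12] = -m[i, 1] * Xh
    _, _, Vt = np.linalg.svd(A)
    P = Vt[-1].reshape(3, 4)
    M = P[:, :3]
    # fix sign so that points end up in front of the camera
    if np.mean(z @ M[2] + P[2, 3]) < 0:
        P = -P
        M = P[:, :3]
    U, S, Vt2 = np.linalg.svd(M)
    R = U @ Vt2
    if np.linalg.det(R) < 0:
        R = U @ np.diag([1, 1, -1]) @ Vt2
    scale = S.mean()
    if scale <= 0:
        return None
    t = P[:, 3] / scale
    try:
        return Pose(R, t)
    except ValueError:
        return None


def _restart_rotations() -> list[np.ndarray]:
    """8 deterministic rotations covering SO(3) coarsely."""
    rots = [np.eye(3)]
    for ax in ([1, 0, 0], [0, 1, 0], [0, 0, 1]):
        for ang in (90, 180):
            rots.append(_Rot.from_rotvec(np.radians(ang) * np.asarray(ax, float))
                        .as_matrix())
    rots.append(_Rot.from_euler("xyz", [90, 90, 0], degrees=True).as_matrix())
    return rots[:8]


def _lm_refine(y0: np.ndarray, x: np.ndarray, z: np.ndarray,
               K: CameraIntrinsics):
    def residuals(y):
        proj, _ = _project_params(y, z, K)
        return (proj - x).ravel()

    def jac(y):
        _, J = _project_params(y, z, K)
        return J.reshape(-1, 6)

    res = least_squares(residuals, y0, jac=jac, method="lm",
                        max_nfev=MAX_ITER * 2, xtol=1e-15, ftol=1e-15,
                        gtol=1e-15)
    return res.x, float(res.cost * 2.0), int(res.nfev)


def solve_pnp(problem: PnPProblem, init: Pose | None = None) -> PnPSolution:
    """Pose minimizing the (x-term) reprojection loss.

    Levenberg–Marquardt from a DLT initialization (or the supplied one);
    when the residual stays above ``RESTART_TOL`` the solver retries from 8
    deterministic rotations at the best translation found.  Never raises on
    non-convergence: the best-effort pose is returned with
    ``converged=False``.
    """
    mask = problem.usable
    if mask.sum() < 4:
        raise ValueError("need at least 4 usable correspondences")
    x = problem.x.points[mask]
    z = problem.z.points[mask]
    K = problem.K

    inits: list[np.ndarray] = []
    if init is not None:
        inits.append(init.as_params())
    dlt = _dlt_init(x, z, K)
    if dlt is not None:
        inits.append(dlt.as_params())
    if not inits:
        scale = max(np.ptp(z, axis=0).max(), 1.0)
        inits.append(np.array([0, 0, 0, 0, 0, 5.0 * scale]))

    best_y, best_res, best_nfev = None, np.inf, 0
    for y0 in inits:
        y, resid, nfev = _lm_refine(y0, x, z, K)
        if resid < best_res:
            best_y, best_res, best_nfev = y, resid, nfev
        if best_res <= RESTART_TOL * len(x):
            break

    if best_res > RESTART_TOL * len(x):
        t0 = best_y[3:].copy()
        for Rm in _restart_rotations():
            y0 = np.concatenate([_Rot.from_matrix(Rm).as_rotvec(), t0])
            y, resid, nfev = _lm_refine(y0, x, z, K)
            best_nfev += nfev
            if resid < best_res:
                best_y, best_res = y, resid
            if best_res <= RESTART_TOL * len(x):
                break

    # Newton polish on the stationarity equation f(y) = 0: LM stops at
    # machine-limited step sizes; a few exact-Hessian Newton steps push the
    # stationarity certificate down to ~1e-12.
    for _ in range(5):
        f = _grad_lp(best_y, x, z, K)
        if np.abs(f).max() < 1e-13:
            break
        H = _hessian_f(best_y, x, z, K) + HESSIAN_REG * np.eye(6)
        try:
            step = np.linalg.solve(H, f)
        except np.linalg.LinAlgError:
            break
        y_new = best_y - step
        proj_new, _ = _project_params(y_new, z, K)
        res_new = float(((proj_new - x) ** 2).sum())
        if res_new > best_res + 1e-12:
            break
        best_y, best_res = y_new, res_new

    f = _grad_lp(best_y, x, z, K)
    stat = float(np.abs(f).max())
    # stationarity scaled by the residual magnitude for noisy instances
    tol = GRAD_TOL if best_res < 1e-12 else max(GRAD_TOL, 1e-6 * np.sqrt(best_res))
    return PnPSolution(pose=Pose.from_params(best_y), residual=best_res,
                       converged=stat < max(tol, 1e-4 * (1.0 + best_res)),
                       iterations=best_nfev, stationarity=stat)


# ---------------------------------------------------------------------------
# implicit backward
# ---------------------------------------------------------------------------

def _hessian_f(y: np.ndarray, x: np.ndarray, z: np.ndarray,
               K: CameraIntrinsics) -> np.ndarray:
    """∂f/∂y (6×6) by complex-step differentiation of the analytic f."""
    h = 1e-200
    H = np.zeros((6, 6))
    for j in range(6):
        yc = y.astype(complex)
        yc[j] += 1j * h
        H[:, j] = np.imag(_grad_lp(yc, x, z, K)) / h
    return H


def implicit_backward(solution: PnPSolution, problem: PnPProblem,
                      grad_wrt_pose: np.ndarray) -> np.ndarray:
    """Pull a gradient w.r.t. the 6-dof pose back to the 2D points.

    Returns ``grad_wrt_poseᵀ · ∂y/∂x`` as an N×2 array (zeros at masked
    points).  Raises if the stationarity Hessian is ill-conditioned.
    """
    mask = problem.usable
    x = problem.x.points[mask]
    z = problem.z.points[mask]
    y = solution.pose.as_params()
    K = problem.K

    H = _hessian_f(y, x, z, K) + HESSIAN_REG * np.eye(6)
    cond = np.linalg.cond(H)
    if not np.isfinite(cond) or cond > COND_LIMIT:
        raise np.linalg.LinAlgError(
            f"stationarity Hessian ill-conditioned (cond={cond:.3e} > {COND_LIMIT:.0e})")

    # ∂f/∂x_i = -2 J_iᵀ  (f = 2 Σ J_iᵀ (π_i - x_i); π does not depend on x)
    _, J = _project_params(y, z, K)
    n = len(x)
    dfdx = np.zeros((6, 2 * n))
    for i in range(n):
        dfdx[:, 2 * i:2 * i + 2] = -2.0 * J[i].T

    dydx = -np.linalg.solve(H, dfdx)  # 6×2n
    g = np.asarray(grad_wrt_pose, float).reshape(6) @ dydx  # 2n
    out = np.zeros((len(problem.x), 2))
    out[mask] = g.reshape(n, 2)
    return out


# ---------------------------------------------------------------------------
# autodiff layer
# ---------------------------------------------------------------------------

def bpnp_layer(x: Tensor, z: FeaturePoints3D, K: CameraIntrinsics,
               visibility: np.ndarray | None = None,
               init: Pose | None = None) -> tuple[Tensor, PnPSolution]:
    """Differentiable PnP: Tensor (N×2) keypoints -> Tensor (6,) pose params.

    Forward runs :func:`solve_pnp`; backward applies
    :func:`implicit_backward`.  Returns (pose_params, solution).  When the
    solve does not converge the output Tensor is detached from the tape
    (flagged via ``solution.converged``) rather than raising.
    """
    vis = np.ones(x.shape[0], bool) if visibility is None else visibility
    problem = PnPProblem(Projections2D(x.data, vis), z, K)
    solution = solve_pnp(problem, init=init)
    y = solution.pose.as_params()
    if not (x.requires_grad and solution.converged):
        return Tensor(y), solution

    def back(g):
        return (implicit_backward(solution, problem, g),)

    out = Tensor._make(y, (x,), back)
    return out, solution


def reprojection_loss_t(x: Tensor, x_star: np.ndarray, y: Tensor,
                        z: FeaturePoints3D, K: CameraIntrinsics,
                        visibility: np.ndarray | None = None,
                        lambda_weight: float = 1.0) -> Tensor:
    """Autodiff reprojection loss l_p(x, x*, y) for the training objective.

    ``y`` is a pose-parameter Tensor (typically from :func:`bpnp_layer`);
    gradients flow into both ``x`` (explicit term) and ``y`` (both terms).
    """
    vis = np.ones(x.shape[0], bool) if visibility is None else visibility
    idx = np.flatnonzero(vis)
    if len(idx) < 4:
        raise ValueError("need at least 4 usable correspondences")
    proj = _project_t(y, z.points[idx], K)
    diff = x[idx] - proj
    loss = (diff * diff).sum()
    if lambda_weight > 0 and x_star is not None:
        diff2 = Tensor(np.asarray(x_star, float)[idx]) - proj
        loss = loss + lambda_weight * (diff2 * diff2).sum()
    return loss


def _project_t(y: Tensor, z: np.ndarray, K: CameraIntrinsics) -> Tensor:
    """Pinhole projection as Tensor ops (differentiable w.r.t. pose)."""
    from .render import _rotvec_to_matrix_t
    R = _rotvec_to_matrix_t(y[:3])
    cam = Tensor(z) @ R.transpose() + y[3:].reshape(1, 3)
    u = K.fx * cam[:, 0] / cam[:, 2] + K.cx
    v = K.fy * cam[:, 1] / cam[:, 2] + K.cy
    from . import autodiff as ad
    return ad.stack([u, v], axis=1)
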