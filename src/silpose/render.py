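"""Hard and soft silhouette rasterization of a posed triangle mesh.

The hard rasterizer stands in for a rendering engine during synthetic-data
generation: a pixel is foreground iff its center lies inside the projection
of any front-of-camera face.

The soft rasterizer is the differentiable counterpart used by the contour
consistency loss: per-pixel occupancy is

    O(p) = sigmoid(sharpness * d(p))

where ``d(p)`` is the signed 2D distance from the pixel center to the
silhouette contour — the distance to the nearest projected *silhouette
edge* (a mesh edge whose adjacent faces project with opposite winding, or
a boundary/clipped edge), positive inside the union of projected faces.
This keeps the occupancy exactly 0.5 on the contour and saturated in the
interior (a per-face aggregation would dip to 0.5 along every shared
projected edge and bias pose refinement).  It is differentiable with
respect to the pose, so the mean-squared silhouette discrepancy against an
observed mask can drive gradient-based pose refinement.

Faces crossing the near plane (Z = depth_eps) are clipped, not dropped, in
both modes, so silhouettes do not pop during pose optimization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from PIL import Image

from . import autodiff as ad
from .autodiff import Tensor
from .geometry import DEPTH_EPS, CameraIntrinsics, Pose, TriMesh

__all__ = ["MaskImage", "rasterize_hard", "rasterize_soft", "render_loss",
           "render_loss_pose_grad", "save_mask_png", "load_mask_png"]

DEFAULT_SHARPNESS = 10.0  # px^-1


@dataclass
class MaskImage:
    """H×W silhouette image; binary mode holds {0,1}, soft mode [0,1]."""

    pixels: np.ndarray
    binary: bool = True

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2D")
        if self.binary:
            self.pixels = (self.pixels > 0.5).astype(np.float64)
        else:
            self.pixels = np.clip(self.pixels, 0.0, 1.0)

    @property
    def shape(self):
        return self.pixels.shape

    def area(self) -> float:
        return float(self.pixels.sum())

    def threshold(self, level: float = 0.5) -> "MaskImage":
        return MaskImage((self.pixels > level).astype(np.float64), binary=True)


# ---------------------------------------------------------------------------
# near-plane clipping (numpy path)
# ---------------------------------------------------------------------------

def _clip_triangle_np(cam: np.ndarray, eps: float) -> list[np.ndarray]:
    """Sutherland–Hodgman clip of one camera-space triangle against Z=eps.

    Returns 0, 1 or 2 triangles (each 3×3 camera coordinates)."""
    z = cam[:, 2]
    inside = z > eps
    if inside.all():
        return [cam]
    if not inside.any():
        return []
    poly = []
    for i in range(3):
        j = (i + 1) % 3
        a, b = cam[i], cam[j]
        if inside[i]:
            poly.append(a)
        if inside[i] != inside[j]:
            w = (eps - a[2]) / (b[2] - a[2])
            poly.append(a + w * (b - a))
    if len(poly) == 3:
        return [np.asarray(poly)]
    # quad -> two triangles
    p = np.asarray(poly)
    return [p[[0, 1, 2]], p[[0, 2, 3]]]


def _project_cam(cam: np.ndarray, K: CameraIntrinsics) -> np.ndarray:
    return np.stack([K.fx * cam[:, 0] / cam[:, 2] + K.cx,
                     K.fy * cam[:, 1] / cam[:, 2] + K.cy], axis=1)


# ---------------------------------------------------------------------------
# hard rasterizer
# ---------------------------------------------------------------------------

def rasterize_hard(mesh: TriMesh, pose: Pose, K: CameraIntrinsics,
                   depth_eps: float = DEPTH_EPS) -> MaskImage:
    """Binary silhouette: pixel = 1 iff its center is inside any projected
    front-of-camera face (boundary pixels count as inside).

    A mesh entirely behind the camera yields an all-zero mask and a warning.
    """
    h, w = K.height, K.width
    out = np.zeros((h, w), dtype=bool)
    cam_all = pose.apply(mesh.vertices)
    any_face = False
    for f in mesh.faces:
        for tri in _clip_triangle_np(cam_all[f], depth_eps):
            any_face = True
            uv = _project_cam(tri, K)
            _fill_triangle(out, uv)
    if not any_face:
        warnings.warn("mesh entirely behind the camera: empty silhouette",
                      stacklevel=2)
    return MaskImage(out.astype(np.float64), binary=True)


def _fill_triangle(out: np.ndarray, uv: np.ndarray) -> None:
    h, w = out.shape
    u0 = max(int(np.floor(uv[:, 0].min())), 0)
    u1 = min(int(np.ceil(uv[:, 0].max())), w - 1)
    v0 = max(int(np.floor(uv[:, 1].min())), 0)
    v1 = min(int(np.ceil(uv[:, 1].max())), h - 1)
    if u1 < u0 or v1 < v0:
        return
    uu, vv = np.meshgrid(np.arange(u0, u1 + 1, dtype=np.float64),
                         np.arange(v0, v1 + 1, dtype=np.float64))
    a, b, c = uv
    s1 = (b[0] - a[0]) * (vv - a[1]) - (b[1] - a[1]) * (uu - a[0])
    s2 = (c[0] - b[0]) * (vv - b[1]) - (c[1] - b[1]) * (uu - b[0])
    s3 = (a[0] - c[0]) * (vv - c[1]) - (a[1] - c[1]) * (uu - c[0])
    inside = ((s1 >= 0) & (s2 >= 0) & (s3 >= 0)) | ((s1 <= 0) & (s2 <= 0) & (s3 <= 0))
    out[v0:v1 + 1, u0:u1 + 1] |= inside


# ---------------------------------------------------------------------------
# soft rasterizer (autodiff)
# ---------------------------------------------------------------------------

def _rotvec_to_matrix_t(w: Tensor) -> Tensor:
    """Rodrigues formula on a Tensor axis-angle 3-vector -> 3×3 Tensor."""
    theta2 = (w * w).sum() + 1e-30
    theta = theta2.sqrt()
    s = _sinc(theta)                      # sin(t)/t
    c = _cosc(theta)                      # (1-cos(t))/t^2
    wx, wy, wz = w[0], w[1], w[2]
    zero = Tensor(0.0)
    K = ad.stack([ad.stack([zero, -wz, wy]),
                  ad.stack([wz, zero, -wx]),
                  ad.stack([-wy, wx, zero])])
    eye = Tensor(np.eye(3))
    return eye + s * K + c * (K @ K)


def _sinc(theta: Tensor) -> Tensor:
    # sin(t)/t via stable series for tiny t is unnecessary here: theta>=1e-15
    data = np.sinc(theta.data / np.pi)
    t = theta.data
    dd = np.where(np.abs(t) > 1e-6, (np.cos(t) * t - np.sin(t)) / (t * t + 1e-300),
                  -t / 3.0)
    return Tensor._make(data, (theta,), lambda g: (g * dd,))


def _cosc(theta: Tensor) -> Tensor:
    t = theta.data
    data = np.where(np.abs(t) > 1e-6, (1.0 - np.cos(t)) / (t * t + 1e-300), 0.5)
    dd = np.where(np.abs(t) > 1e-6,
                  (np.sin(t) * t - 2.0 * (1.0 - np.cos(t))) / (t ** 3 + 1e-300),
                  -t / 12.0)
    return Tensor._make(np.asarray(data), (theta,), lambda g: (g * dd,))


def _scatter_fill(values: Tensor, idx: np.ndarray, size: int,
                  fill: float) -> Tensor:
    """Place `values` at flat indices `idx` of a `fill`-valued vector."""
    data = np.full(size, fill, dtype=np.float64)
    data[idx] = values.data
    return Tensor._make(data, (values,), lambda g: (g[idx],))


def _clip_triangle_t(cam: Tensor, eps: float) -> list[Tensor]:
    """Near-plane clip in the Tensor domain (gradients flow through the
    interpolation weights of the clipped vertices)."""
    z = cam.data[:, 2]
    inside = z > eps
    if inside.all():
        return [cam]
    if not inside.any():
        return []
    poly = []
    for i in range(3):
        j = (i + 1) % 3
        a, b = cam[i], cam[j]
        if inside[i]:
            poly.append(a)
        if inside[i] != inside[j]:
            w = (eps - a[2]) / (b[2] - a[2])
            poly.append(a + w * (b - a))
    if len(poly) == 3:
        return [ad.stack(poly)]
    return [ad.stack([poly[0], poly[1], poly[2]]),
            ad.stack([poly[0], poly[2], poly[3]])]


def _segment_distance_t(p: np.ndarray, a: Tensor, b: Tensor) -> Tensor:
    """Distance from constant points p (m×2) to segment [a, b] (Tensors)."""
    ab = b - a
    ab2 = (ab * ab).sum() + 1e-30
    pa = Tensor(p) - a.reshape(1, 2)
    t = ((pa * ab.reshape(1, 2)).sum(axis=1) / ab2).clip(0.0, 1.0)
    closest = a.reshape(1, 2) + t.reshape(-1, 1) * ab.reshape(1, 2)
    d2 = ((Tensor(p) - closest) ** 2.0).sum(axis=1)
    return (d2 + 1e-12).sqrt()


def soft_occupancy(mesh: TriMesh, pose_params: Tensor, K: CameraIntrinsics,
                   sharpness: float = DEFAULT_SHARPNESS,
                   depth_eps: float = DEPTH_EPS,
                   band: float | None = None) -> Tensor:
    """Soft silhouette as an autodiff Tensor of shape (H, W).

    ``pose_params`` is the 6-vector [axis-angle, translation].  The signed
    distance to the union silhouette is assembled from the projected
    *silhouette edges* — mesh edges whose two adjacent faces project with
    opposite winding, plus boundary edges and edges of near-plane-clipped
    faces — with the sign taken from a point-in-any-face test.  Distances
    are evaluated only within ``band`` pixels of each edge (default
    ``3/sharpness + 3``); beyond the band the occupancy is saturated.
    """
    if sharpness <= 0:
        raise ValueError("sharpness must be positive")
    h, w = K.height, K.width
    if band is None:
        band = 3.0 / sharpness + 3.0
    R_t = _rotvec_to_matrix_t(pose_params[:3])
    t_t = pose_params[3:]
    verts_cam = Tensor(mesh.vertices) @ R_t.transpose() + t_t.reshape(1, 3)
    zs = verts_cam.data[:, 2]

    def _project_tri(tri: Tensor) -> Tensor:
        z = tri[:, 2]
        u = K.fx * tri[:, 0] / z + K.cx
        v = K.fy * tri[:, 1] / z + K.cy
        return ad.stack([u, v], axis=1)

    inside = np.zeros((h, w), dtype=bool)
    edge_windings: dict[tuple, list] = {}
    sil_edges: list[tuple[Tensor, Tensor]] = []  # (a, b) projected endpoints
    proj_cache: dict[int, Tensor] = {}
    any_face = False

    for f in mesh.faces:
        i0, i1, i2 = int(f[0]), int(f[1]), int(f[2])
        if zs[i0] > depth_eps and zs[i1] > depth_eps and zs[i2] > depth_eps:
            any_face = True
            for i in (i0, i1, i2):
                if i not in proj_cache:
                    vi = verts_cam[i]
                    zi = vi[2]
                    proj_cache[i] = ad.stack([K.fx * vi[0] / zi + K.cx,
                                              K.fy * vi[1] / zi + K.cy])
            pa, pb, pc = proj_cache[i0], proj_cache[i1], proj_cache[i2]
            a2, b2, c2 = pa.data, pb.data, pc.data
            winding = np.sign((b2[0] - a2[0]) * (c2[1] - a2[1])
                              - (b2[1] - a2[1]) * (c2[0] - a2[0])) or 1.0
            _fill_triangle(inside, np.stack([a2, b2, c2]))
            for (i, j), (p, q) in (((i0, i1), (pa, pb)), ((i1, i2), (pb, pc)),
                                   ((i2, i0), (pc, pa))):
                key = (min(i, j), max(i, j))
                edge_windings.setdefault(key, []).append((winding, p, q))
        else:
            # face crosses (or is behind) the near plane: clip it and treat
            # every clipped edge as a silhouette edge (conservative)
            cam = ad.stack([verts_cam[i0], verts_cam[i1], verts_cam[i2]])
            for tri in _clip_triangle_t(cam, depth_eps):
                any_face = True
                uv = _project_tri(tri)
                _fill_triangle(inside, uv.data)
                for i in range(3):
                    sil_edges.append((uv[i], uv[(i + 1) % 3]))

    for recs in edge_windings.values():
        signs = {r[0] for r in recs}
        if len(recs) == 1 or len(signs) > 1:  # boundary or front/back flip
            sil_edges.append((recs[0][1], recs[0][2]))

    if not any_face:
        warnings.warn("mesh entirely behind the camera: empty soft silhouette",
                      stacklevel=2)

    big = 1e6
    dmin = Tensor(np.full(h * w, big))  # distance to nearest silhouette edge
    for a, b in sil_edges:
        ax, ay = a.data[0], a.data[1]
        bx, by = b.data[0], b.data[1]
        u0 = max(int(np.floor(min(ax, bx) - band)), 0)
        u1 = min(int(np.ceil(max(ax, bx) + band)), w - 1)
        v0 = max(int(np.floor(min(ay, by) - band)), 0)
        v1 = min(int(np.ceil(max(ay, by) + band)), h - 1)
        if u1 < u0 or v1 < v0:
            continue
        uu, vv = np.meshgrid(np.arange(u0, u1 + 1), np.arange(v0, v1 + 1))
        pix = np.stack([uu.ravel(), vv.ravel()], axis=1).astype(np.float64)
        flat_idx = (vv.ravel() * w + uu.ravel()).astype(np.int64)
        d = _segment_distance_t(pix, a, b)
        dmin = ad.minimum(dmin, _scatter_fill(d, flat_idx, h * w, big))

    sign = np.where(inside.ravel(), 1.0, -1.0)
    occ = (Tensor(sign) * dmin * sharpness).sigmoid()
    return occ.reshape(h, w)


def rasterize_soft(mesh: TriMesh, pose: Pose, K: CameraIntrinsics,
                   sharpness: float = DEFAULT_SHARPNESS,
                   depth_eps: float = DEPTH_EPS) -> MaskImage:
    """Non-differentiable convenience wrapper returning a soft MaskImage."""
    occ = soft_occupancy(mesh, Tensor(pose.as_params()), K,
                         sharpness=sharpness, depth_eps=depth_eps)
    return MaskImage(occ.data, binary=False)


# ---------------------------------------------------------------------------
# rendering loss
# ---------------------------------------------------------------------------

def render_loss(mr, ms) -> float:
    """Mean squared silhouette discrepancy between rendered and observed
    masks (the contour global-consistency loss)."""
    pr = mr.pixels if isinstance(mr, MaskImage) else np.asarray(mr, float)
    ps = ms.pixels if isinstance(ms, MaskImage) else np.asarray(ms, float)
    if pr.shape != ps.shape:
        raise ValueError(f"shape mismatch {pr.shape} vs {ps.shape}")
    return float(np.mean((pr - ps) ** 2))


def render_loss_pose_grad(mesh: TriMesh, pose: Pose, observed: MaskImage,
                          K: CameraIntrinsics,
                          sharpness: float = DEFAULT_SHARPNESS):
    """Rendering loss and its gradient with respect to the 6-dof pose.

    Returns ``(loss, grad6)`` where grad6 is d(loss)/d[axis-angle, t]."""
    params = Tensor(pose.as_params(), requires_grad=True)
    occ = soft_occupancy(mesh, params, K, sharpness=sharpness)
    diff = occ - Tensor(observed.pixels)
    loss = (diff * diff).mean()
    loss.backward()
    if params.grad is None:
        # no silhouette edge reaches the image: the loss is locally
        # constant in the pose and the gradient is exactly zero
        return float(loss.data), np.zeros(6)
    return float(loss.data), params.grad.copy()


# ---------------------------------------------------------------------------
# PNG I/O (8-bit; binary masks use {0, 255})
# ---------------------------------------------------------------------------

def save_mask_png(mask: MaskImage, path) -> None:
    arr = np.round(mask.pixels * 255.0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(str(path))


def load_mask_png(path, binary: bool = True) -> MaskImage:
    arr = np.asarray(Image.open(str(path)).convert("L"), dtype=np.float64) / 255.0
    return MaskImage(arr, binary=binary)
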