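"""Rigid transforms, pinhole projection, mesh utilities and keypoint selection.

Conventions used throughout the package (fixed once, here):

* **Pose** maps model coordinates to camera coordinates:
  ``p_cam = R @ p_model + t``.
* **Pixels** are 0-based with pixel centers at integer coordinates; ``u``
  runs along the image width, ``v`` along the height.
* Model units are arbitrary but must be consistent between mesh, keypoints
  and translations; no metric unit is assumed anywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh as _trimesh
import yaml
from scipy.spatial import ConvexHull
from scipy.spatial.transform import Rotation as _Rot

DEPTH_EPS = 1e-6

__all__ = [
    "CameraIntrinsics", "Pose", "TriMesh", "FeaturePoints3D", "Projections2D",
    "project", "farthest_point_sampling", "mesh_diameter",
    "rotation_geodesic_deg", "load_mesh", "load_intrinsics", "save_intrinsics",
]


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole camera parameters (zero skew, no distortion)."""

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int
    # cropped sub-views (ROIs) of a camera legitimately carry a principal
    # point outside their own bounds; only full cameras enforce containment
    is_roi: bool = False

    def __post_init__(self):
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not self.is_roi and not (0 <= self.cx < self.width
                                    and 0 <= self.cy < self.height):
            raise ValueError("principal point must lie inside the image")

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.fx, 0.0, self.cx],
                         [0.0, self.fy, self.cy],
                         [0.0, 0.0, 1.0]])

    def to_dict(self) -> dict:
        return {"fx": self.fx, "fy": self.fy, "cx": self.cx, "cy": self.cy,
                "width": self.width, "height": self.height}

    @classmethod
    def from_dict(cls, d: dict) -> "CameraIntrinsics":
        return cls(fx=float(d["fx"]), fy=float(d["fy"]), cx=float(d["cx"]),
                   cy=float(d["cy"]), width=int(d["width"]), height=int(d["height"]))


class Pose:
    """Rigid transform, camera-from-model: ``p_cam = R @ p_model + t``."""

    __slots__ = ("R", "t")

    def __init__(self, rotation, translation):
        R = np.asarray(rotation, dtype=np.float64)
        if R.shape == (3,):  # axis-angle vector
            R = _Rot.from_rotvec(R).as_matrix()
        if R.shape != (3, 3):
            raise ValueError("rotation must be a 3x3 matrix or axis-angle 3-vector")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation matrix determinant must be +1")
        self.R = R
        self.t = np.asarray(translation, dtype=np.float64).reshape(3)

    @classmethod
    def identity(cls) -> "Pose":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotvec(cls, rotvec, translation) -> "Pose":
        return cls(_Rot.from_rotvec(np.asarray(rotvec, float)).as_matrix(),
                   translation)

    @classmethod
    def from_quat_wxyz(cls, q, translation) -> "Pose":
        q = np.asarray(q, dtype=np.float64)
        return cls(_Rot.from_quat([q[1], q[2], q[3], q[0]]).as_matrix(), translation)

    @property
    def rotvec(self) -> np.ndarray:
        return _Rot.from_matrix(self.R).as_rotvec()

    @property
    def quat_wxyz(self) -> np.ndarray:
        x, y, z, w = _Rot.from_matrix(self.R).as_quat()
        return np.array([w, x, y, z])

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform (..., 3) model points to camera coordinates."""
        return np.asarray(points, float) @ self.R.T + self.t

    def compose(self, other: "Pose") -> "Pose":
        """self ∘ other: apply `other` first."""
        return Pose(self.R @ other.R, self.R @ other.t + self.t)

    def inverse(self) -> "Pose":
        return Pose(self.R.T, -self.R.T @ self.t)

    def as_params(self) -> np.ndarray:
        """6-vector [axis-angle, translation] used by the PnP optimizer."""
        return np.concatenate([self.rotvec, self.t])

    @classmethod
    def from_params(cls, p) -> "Pose":
        p = np.asarray(p, dtype=np.float64)
        return cls.from_rotvec(p[:3], p[3:])

    def to_dict(self) -> dict:
        return {"quaternion_wxyz": self.quat_wxyz.tolist(),
                "translation_xyz": self.t.tolist(),
                "convention": "camera_from_model"}

    @classmethod
    def from_dict(cls, d: dict) -> "Pose":
        return cls.from_quat_wxyz(d["quaternion_wxyz"], d["translation_xyz"])

    def __repr__(self):
        return f"Pose(rotvec={np.round(self.rotvec, 4)}, t={np.round(self.t, 4)})"


@dataclass
class TriMesh:
    """Triangle mesh: V×3 vertices, F×3 integer faces (model units)."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and (self.faces.min() < 0
                                or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")

    def cleaned(self, area_eps: float = 1e-12) -> "TriMesh":
        """Drop zero-area faces."""
        v = self.vertices
        a = v[self.faces[:, 1]] - v[self.faces[:, 0]]
        b = v[self.faces[:, 2]] - v[self.faces[:, 0]]
        areas = 0.5 * np.linalg.norm(np.cross(a, b), axis=1)
        return TriMesh(v, self.faces[areas > area_eps])

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


@dataclass
class FeaturePoints3D:
    """The implicit model keypoints (default 8, chosen by farthest-point
    sampling on the mesh vertices)."""

    points: np.ndarray
    indices: np.ndarray | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if self.indices is not None:
            self.indices = np.asarray(self.indices, dtype=np.int64)

    def __len__(self):
        return len(self.points)


@dataclass
class Projections2D:
    """Continuous pixel coordinates of projected keypoints + visibility."""

    points: np.ndarray
    visibility: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 2)
        if self.visibility is None:
            self.visibility = np.ones(len(self.points), dtype=bool)
        else:
            self.visibility = np.asarray(self.visibility, dtype=bool)

    def __len__(self):
        return len(self.points)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def project(points, pose: Pose, K: CameraIntrinsics,
            depth_eps: float = DEPTH_EPS) -> Projections2D:
    """Pinhole projection of 3D model points.

    ``u = fx*Xc/Zc + cx, v = fy*Yc/Zc + cy`` with
    ``(Xc,Yc,Zc) = R p + t``.  Points at or behind the camera plane
    (``Zc <= depth_eps``) are flagged invisible and their coordinates are
    not meaningful; visible points outside the image bounds are also
    flagged invisible.
    """
    pts = points.points if isinstance(points, FeaturePoints3D) else np.asarray(points, float)
    pts = pts.reshape(-1, 3)
    cam = pose.apply(pts)
    z = cam[:, 2]
    in_front = z > depth_eps
    zsafe = np.where(in_front, z, 1.0)
    u = K.fx * cam[:, 0] / zsafe + K.cx
    v = K.fy * cam[:, 1] / zsafe + K.cy
    uv = np.stack([u, v], axis=1)
    inside = ((uv[:, 0] >= 0) & (uv[:, 0] < K.width)
              & (uv[:, 1] >= 0) & (uv[:, 1] < K.height))
    return Projections2D(uv, in_front & inside)


def unproject(uv, depth, K: CameraIntrinsics) -> np.ndarray:
    """Inverse pinhole map at known camera-frame depth (camera coords)."""
    uv = np.asarray(uv, float).reshape(-1, 2)
    depth = np.asarray(depth, float).reshape(-1)
    x = (uv[:, 0] - K.cx) / K.fx * depth
    y = (uv[:, 1] - K.cy) / K.fy * depth
    return np.stack([x, y, depth], axis=1)


def farthest_point_sampling(mesh: TriMesh, k: int,
                            start_index: int | None = None) -> FeaturePoints3D:
    """Greedy max-min selection of ``k`` vertices.

    Deterministic: each new point maximizes its minimum Euclidean distance
    to the already-selected set; ties break toward the lowest vertex index.
    ``start_index`` defaults to the vertex of maximal norm so the selection
    is reproducible without a random seed.
    """
    v = mesh.vertices
    n = len(v)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if start_index is None:
        start_index = int(np.argmax(np.linalg.norm(v, axis=1)))
    if not 0 <= start_index < n:
        raise ValueError("start_index out of range")
    chosen = [start_index]
    mind = np.linalg.norm(v - v[start_index], axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(mind))
        chosen.append(nxt)
        mind = np.minimum(mind, np.linalg.norm(v - v[nxt], axis=1))
    idx = np.array(chosen, dtype=np.int64)
    return FeaturePoints3D(v[idx], idx)


def mesh_diameter(mesh: TriMesh, exact_limit: int = 5000) -> float:
    """Maximum pairwise vertex distance.

    Exact O(V²) scan for small meshes; for larger ones the diameter is
    realised on the convex hull, so only hull vertices are scanned.
    """
    v = mesh.vertices
    if len(v) < 2:
        raise ValueError("mesh needs at least 2 vertices")
    if len(v) > exact_limit:
        try:
            v = v[ConvexHull(v).vertices]
        except Exception:  # degenerate (coplanar) clouds: fall back to full scan
            pass
    # blocked pairwise scan keeps memory bounded
    best = 0.0
    for i in range(0, len(v), 2048):
        blk = v[i:i + 2048]
        d2 = ((blk[:, None, :] - v[None, :, :]) ** 2).sum(-1)
        best = max(best, float(d2.max()))
    return float(np.sqrt(best))


def rotation_geodesic_deg(a: Pose, b: Pose) -> float:
    """Geodesic angle between two rotations, degrees in [0, 180]."""
    c = (np.trace(a.R.T @ b.R) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_mesh(path) -> TriMesh:
    """Read an OBJ or PLY triangle mesh (via trimesh) and clean it."""
    m = _trimesh.load_mesh(str(path), process=False)
    if isinstance(m, _trimesh.Scene):
        m = m.to_geometry()
    return TriMesh(np.asarray(m.vertices), np.asarray(m.faces)).cleaned()


def save_mesh(mesh: TriMesh, path) -> None:
    _trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces,
                     process=False).export(str(path))


def load_intrinsics(path) -> CameraIntrinsics:
    """Read a YAML/JSON intrinsics block {fx, fy, cx, cy, width, height}."""
    text = Path(path).read_text()
    d = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if "intrinsics" in d:
        d = d["intrinsics"]
    return CameraIntrinsics.from_dict(d)


def save_intrinsics(K: CameraIntrinsics, path) -> None:
    p = Path(path)
    if p.suffix == ".json":
        p.write_text(json.dumps(K.to_dict(), indent=2) + "\n")
    else:
        p.write_text(yaml.safe_dump(K.to_dict(), sort_keys=False))
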