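"""Synthetic weak-supervision training data.

Each generated sample is a rendered binary silhouette of an instrument mesh
under a randomly drawn camera-from-model pose, together with the pose label,
the 8 farthest-point 3D keypoints, their 2D projections, and (on demand)
Gaussian heatmap ground truth.  Noise augmentation emulates the boundary
errors, speckle and holes of an imperfect upstream segmentation.

Default sampling ranges keep the instrument in frame at 640×480 with the
default intrinsics: rotations uniform over SO(3) (via uniformly sampled unit
quaternions), depth uniform in [3, 8] mesh diameters, lateral offsets
uniform in ±0.3·Z.

The whole pipeline is a pure function of (mesh, intrinsics, ranges, n,
seed): per-sample RNG streams are derived from the master seed and the
sample index, so regeneration is byte-identical and order-independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh as _trimesh
from scipy import ndimage

from .geometry import (CameraIntrinsics, FeaturePoints3D, Pose, Projections2D,
                       TriMesh, farthest_point_sampling, mesh_diameter, project)
from .render import MaskImage, rasterize_hard, save_mask_png

SCHEMA_VERSION = 1
DEFAULT_SIGMA = 8.0      # px, Gaussian heatmap ground-truth width
DEFAULT_STRIDE = 4       # image px per heatmap px
DEFAULT_N_KEYPOINTS = 8

__all__ = [
    "PoseSamplingRanges", "NoiseConfig", "SampleRecord", "Heatmap",
    "sample_poses", "make_heatmap_gt", "add_noise", "generate_dataset",
    "load_manifest", "default_intrinsics", "make_cube",
    "make_cylinder_with_hook", "make_cylinder_with_jaws", "make_tube",
    "toy_instrument",
]


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PoseSamplingRanges:
    """Pose-space sampling box.

    rotation: "uniform" for uniform SO(3), or a dict of per-axis degree
    intervals {"x": (lo, hi), "y": ..., "z": ...} applied extrinsically
    in x-y-z order.  depth: (Zmin, Zmax) in model units, Zmin > 0.
    xy_frac: lateral offsets drawn uniformly in ±xy_frac·Z.
    """

    rotation: object = "uniform"
    depth: tuple = (3.0, 8.0)
    xy_frac: float = 0.3

    def __post_init__(self):
        zmin, zmax = self.depth
        if not (0 < zmin <= zmax):
            raise ValueError("depth interval must satisfy 0 < Zmin <= Zmax")
        if self.xy_frac < 0:
            raise ValueError("xy_frac must be non-negative")
        if self.rotation != "uniform":
            for ax in ("x", "y", "z"):
                lo, hi = self.rotation[ax]
                if hi < lo:
                    raise ValueError(f"empty rotation interval for axis {ax}")

    @classmethod
    def for_mesh(cls, mesh: TriMesh, depth_diameters=(3.0, 8.0),
                 xy_frac: float = 0.3) -> "PoseSamplingRanges":
        d = mesh_diameter(mesh)
        return cls(depth=(depth_diameters[0] * d, depth_diameters[1] * d),
                   xy_frac=xy_frac)


@dataclass(frozen=True)
class NoiseConfig:
    """Segmentation-imperfection model applied to clean binary masks.

    morph_radius: max radius (px) of a random boundary erosion/dilation;
    flip_rate: per-pixel salt-and-pepper flip probability;
    blob_rate: expected count of random disc speckles/holes per image;
    blob_radius: (min, max) disc radius in px.  Every component can be
    switched off by setting its parameter to zero.
    """

    morph_radius: int = 2
    flip_rate: float = 0.002
    blob_rate: float = 1.0
    blob_radius: tuple = (2.0, 6.0)

    def __post_init__(self):
        if not 0.0 <= self.flip_rate <= 1.0:
            raise ValueError("flip_rate must be in [0, 1]")
        if self.morph_radius < 0 or self.blob_rate < 0:
            raise ValueError("noise magnitudes must be non-negative")

    @classmethod
    def off(cls) -> "NoiseConfig":
        return cls(morph_radius=0, flip_rate=0.0, blob_rate=0.0)


@dataclass
class SampleRecord:
    """One training sample: mask path + pose and keypoint labels."""

    mask_path: str
    pose: Pose
    keypoints3d: FeaturePoints3D
    keypoints2d: Projections2D
    instrument_id: str
    rng_seed: int
    index: int

    def to_json(self) -> dict:
        return {
            "index": self.index,
            "mask": self.mask_path,
            "pose": self.pose.to_dict(),
            "keypoints3d": self.keypoints3d.points.tolist(),
            "keypoints2d": self.keypoints2d.points.tolist(),
            "visibility": self.keypoints2d.visibility.astype(int).tolist(),
            "instrument_id": self.instrument_id,
            "rng_seed": int(self.rng_seed),
        }

    @classmethod
    def from_json(cls, d: dict) -> "SampleRecord":
        return cls(mask_path=d["mask"], pose=Pose.from_dict(d["pose"]),
                   keypoints3d=FeaturePoints3D(np.asarray(d["keypoints3d"])),
                   keypoints2d=Projections2D(np.asarray(d["keypoints2d"]),
                                             np.asarray(d["visibility"], bool)),
                   instrument_id=d["instrument_id"], rng_seed=d["rng_seed"],
                   index=d["index"])


@dataclass
class Heatmap:
    """Per-keypoint 2D likelihood maps at image/stride resolution."""

    maps: np.ndarray  # N×h×w
    stride: int = DEFAULT_STRIDE
    sigma: float = DEFAULT_SIGMA

    def __post_init__(self):
        self.maps = np.asarray(self.maps, dtype=np.float64)
        if self.maps.ndim != 3:
            raise ValueError("heatmap stack must be N×h×w")


# ---------------------------------------------------------------------------
# pose sampling
# ---------------------------------------------------------------------------

def _uniform_quaternion(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix via a uniform unit quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _sample_one_pose(ranges: PoseSamplingRanges,
                     rng: np.random.Generator) -> Pose:
    if ranges.rotation == "uniform":
        R = _uniform_quaternion(rng)
    else:
        from scipy.spatial.transform import Rotation as _Rot
        angs = [rng.uniform(*ranges.rotation[ax]) for ax in ("x", "y", "z")]
        R = _Rot.from_euler("xyz", angs, degrees=True).as_matrix()
    z = rng.uniform(*ranges.depth)
    x = rng.uniform(-ranges.xy_frac, ranges.xy_frac) * z
    y = rng.uniform(-ranges.xy_frac, ranges.xy_frac) * z
    return Pose(R, np.array([x, y, z]))


def sample_poses(ranges: PoseSamplingRanges, n: int, seed: int) -> list[Pose]:
    """Draw ``n`` poses uniformly from the sampling box (deterministic)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return [_sample_one_pose(ranges, rng) for _ in range(n)]


# ---------------------------------------------------------------------------
# heatmap ground truth
# ---------------------------------------------------------------------------

def make_heatmap_gt(x_star: Projections2D, sigma: float = DEFAULT_SIGMA,
                    grid_hw: tuple = (120, 160),
                    stride: int = DEFAULT_STRIDE) -> Heatmap:
    """Gaussian heatmaps: an impulse at each visible keypoint convolved
    with an isotropic Gaussian of width ``sigma`` image pixels.

    ``map_i(p) = exp(-|p·stride − x*_i|² / 2σ²)`` — peak value 1.
    Invisible keypoints yield all-zero maps.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    h, w = grid_hw
    gu = np.arange(w) * float(stride)
    gv = np.arange(h) * float(stride)
    maps = np.zeros((len(x_star), h, w))
    for i, (pt, vis) in enumerate(zip(x_star.points, x_star.visibility)):
        if not vis:
            continue
        du2 = (gu - pt[0]) ** 2
        dv2 = (gv - pt[1]) ** 2
        maps[i] = np.exp(-(dv2[:, None] + du2[None, :]) / (2.0 * sigma ** 2))
    return Heatmap(maps, stride=stride, sigma=sigma)


# ---------------------------------------------------------------------------
# noise augmentation
# ---------------------------------------------------------------------------

def _disc(radius: float) -> np.ndarray:
    r = int(np.ceil(radius))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    return (xx ** 2 + yy ** 2) <= radius ** 2


def add_noise(mask: MaskImage, params: NoiseConfig, seed: int) -> MaskImage:
    """Seeded segmentation-style corruption of a binary mask.

    Applies (in order) a random boundary erosion or dilation of radius
    ≤ morph_radius, salt-and-pepper flips at flip_rate, and Poisson-many
    random disc blobs (foreground speckles) or holes.  Output is binary.
    """
    if not mask.binary:
        raise ValueError("add_noise expects a binary mask")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    m = mask.pixels.astype(bool)

    if params.morph_radius > 0:
        radius = rng.integers(0, params.morph_radius + 1)
        if radius > 0:
            op = ndimage.binary_dilation if rng.random() < 0.5 else ndimage.binary_erosion
            m = op(m, structure=_disc(radius))

    if params.blob_rate > 0:
        h, w = m.shape
        for _ in range(rng.poisson(params.blob_rate)):
            r = rng.uniform(*params.blob_radius)
            cy, cx = rng.uniform(0, h), rng.uniform(0, w)
            yy, xx = np.ogrid[:h, :w]
            blob = (xx - cx) ** 2 + (yy - cy) ** 2 <= r ** 2
            if rng.random() < 0.5:
                m = m | blob     # speckle
            else:
                m = m & ~blob    # hole

    if params.flip_rate > 0:
        flips = rng.random(m.shape) < params.flip_rate
        m = m ^ flips

    return MaskImage(m.astype(np.float64), binary=True)


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def default_intrinsics(width: int = 640, height: int = 480,
                       focal: float = 800.0) -> CameraIntrinsics:
    return CameraIntrinsics(fx=focal, fy=focal, cx=width / 2.0,
                            cy=height / 2.0, width=width, height=height)


def _sample_seed(master: int, index: int, attempt: int) -> int:
    ss = np.random.SeedSequence(entropy=master, spawn_key=(index, attempt))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def generate_dataset(mesh: TriMesh, K: CameraIntrinsics,
                     ranges: PoseSamplingRanges, n: int, seed: int,
                     out_dir, instrument_id: str = "instrument",
                     noise: NoiseConfig | None = None,
                     n_keypoints: int = DEFAULT_N_KEYPOINTS,
                     sigma: float = DEFAULT_SIGMA,
                     stride: int = DEFAULT_STRIDE,
                     max_resample: int = 50) -> Path:
    """Render ``n`` labelled silhouette samples into ``out_dir``.

    Writes ``masks/<index>.png`` (clean mask, plus ``masks/<index>_noisy.png``
    when noise is enabled) and a JSON-lines ``manifest.jsonl`` whose first
    line is a schema/config header.  Poses whose silhouette is empty are
    resampled (the count is recorded in the header).  Deterministic per
    (seed, index).  Returns the manifest path.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out = Path(out_dir)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    keypoints = farthest_point_sampling(mesh, n_keypoints)

    records = []
    n_resampled = 0
    for i in range(n):
        for attempt in range(max_resample):
            sub_seed = _sample_seed(seed, i, attempt)
            rng = np.random.default_rng(np.random.SeedSequence(sub_seed))
            pose = _sample_one_pose(ranges, rng)
            mask = rasterize_hard(mesh, pose, K)
            if mask.area() > 0:
                break
            n_resampled += 1
        else:
            raise RuntimeError(f"could not render a non-empty mask for sample {i}")
        proj = project(keypoints, pose, K)
        rel = f"masks/{i:05d}.png"
        save_mask_png(mask, out / rel)
        if noise is not None:
            noisy = add_noise(mask, noise, seed=sub_seed + 1)
            save_mask_png(noisy, out / f"masks/{i:05d}_noisy.png")
        records.append(SampleRecord(rel, pose, keypoints, proj,
                                    instrument_id, sub_seed, i))

    header = {
        "schema_version": SCHEMA_VERSION,
        "n_samples": n,
        "seed": int(seed),
        "instrument_id": instrument_id,
        "intrinsics": K.to_dict(),
        "keypoints3d": keypoints.points.tolist(),
        "sigma": float(sigma),
        "heatmap_stride": int(stride),
        "noise": None if noise is None else vars(noise) | {
            "blob_radius": list(noise.blob_radius)},
        "n_resampled": n_resampled,
    }
    manifest = out / "manifest.jsonl"
    with open(manifest, "w") as fh:
        fh.write(json.dumps(header, sort_keys=True) + "\n")
        for rec in records:
            fh.write(json.dumps(rec.to_json(), sort_keys=True) + "\n")
    return manifest


def load_manifest(manifest_path) -> tuple[dict, list[SampleRecord]]:
    """Read a dataset manifest; returns (header, records)."""
    path = Path(manifest_path)
    with open(path) as fh:
        lines = [json.loads(line) for line in fh if line.strip()]
    header, body = lines[0], lines[1:]
    if header.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported manifest schema: {header.get('schema_version')}")
    return header, [SampleRecord.from_json(d) for d in body]


# ---------------------------------------------------------------------------
# built-in parametric toy instruments
# ---------------------------------------------------------------------------
# Stand-ins for real instrument meshes: a laparoscopic-style shaft with an
# asymmetric tip (hook or jaws) or a plain symmetric tube.  All are generated
# programmatically; dimensions are in arbitrary model units.

def _mesh_from_trimesh(parts: list[_trimesh.Trimesh]) -> TriMesh:
    merged = _trimesh.util.concatenate(parts)
    return TriMesh(np.asarray(merged.vertices), np.asarray(merged.faces)).cleaned()


def make_cube(size: float = 1.0) -> TriMesh:
    b = _trimesh.creation.box(extents=(size, size, size))
    return TriMesh(np.asarray(b.vertices), np.asarray(b.faces)).cleaned()


def make_tube(length: float = 4.0, radius: float = 0.15,
              sections: int = 12) -> TriMesh:
    """Plain cylindrical shaft (rotationally symmetric about its axis)."""
    c = _trimesh.creation.cylinder(radius=radius, height=length,
                                   sections=sections)
    return TriMesh(np.asarray(c.vertices), np.asarray(c.faces)).cleaned()


def make_cylinder_with_hook(length: float = 4.0, radius: float = 0.15,
                            hook_len: float = 0.8,
                            sections: int = 12) -> TriMesh:
    """Shaft with a bent hook tip (electro-cautery hook style)."""
    shaft = _trimesh.creation.cylinder(radius=radius, height=length,
                                       sections=sections)
    hook = _trimesh.creation.cylinder(radius=radius * 0.6, height=hook_len,
                                      sections=sections)
    bend = _trimesh.transformations.rotation_matrix(np.radians(60), [1, 0, 0])
    hook.apply_transform(bend)
    hook.apply_translation([0, hook_len * 0.4, length / 2 + hook_len * 0.25])
    return _mesh_from_trimesh([shaft, hook])


def make_cylinder_with_jaws(length: float = 4.0, radius: float = 0.15,
                            jaw_len: float = 0.9,
                            sections: int = 12) -> TriMesh:
    """Shaft with two opened flat jaws (grasper/clipper style)."""
    shaft = _trimesh.creation.cylinder(radius=radius, height=length,
                                       sections=sections)
    jaws = []
    for sgn in (+1.0, -1.0):
        jaw = _trimesh.creation.box(extents=(radius * 0.8, radius * 0.5, jaw_len))
        rot = _trimesh.transformations.rotation_matrix(
            sgn * np.radians(20), [1, 0, 0])
        jaw.apply_transform(rot)
        jaw.apply_translation([0, sgn * jaw_len * 0.18, length / 2 + jaw_len * 0.45])
        jaws.append(jaw)
    return _mesh_from_trimesh([shaft] + jaws)


_TOYS = {"hook": make_cylinder_with_hook, "jaws": make_cylinder_with_jaws,
         "tube": make_tube, "cube": make_cube}


def toy_instrument(name: str) -> TriMesh:
    """Built-in parametric instrument by name: hook, jaws, tube, cube."""
    if name not in _TOYS:
        raise KeyError(f"unknown toy instrument {name!r}; have {sorted(_TOYS)}")
    return _TOYS[name]()
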