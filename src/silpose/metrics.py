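"""Pose evaluation metrics: ADD, ADD-S, 2D projection error, IOU.

ADD is the mean 3D distance between model points transformed by the
predicted and ground-truth poses; ADD-S pairs each transformed point with
its nearest counterpart (for rotationally symmetric instruments).  A pose
counts as correct when ADD(S) is below 10% of the model diameter.  The 2D
projection error averages the pixel distance between the keypoint
projections under the two poses, with 5 px and 3 px accuracy thresholds.
IOU compares the silhouette re-rendered at the predicted pose against the
observed segmentation mask, and is the only metric available when pose
ground truth does not exist (real footage).
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .geometry import (CameraIntrinsics, FeaturePoints3D, Pose, TriMesh,
                       mesh_diameter, project)
from .render import MaskImage, rasterize_hard

MAX_ADD_POINTS = 10_000

__all__ = ["EvalReport", "add_metric", "add_s_metric", "projection_error_2d",
           "iou", "evaluate"]


def _model_points(points) -> np.ndarray:
    if isinstance(points, FeaturePoints3D):
        pts = points.points
    elif isinstance(points, TriMesh):
        pts = points.vertices
    else:
        pts = np.asarray(points, float)
    pts = pts.reshape(-1, 3)
    if len(pts) == 0:
        raise ValueError("empty model point set")
    return pts


def add_metric(model_points, pred: Pose, gt: Pose) -> float:
    """Mean distance between model points under predicted vs true pose."""
    pts = _model_points(model_points)
    return float(np.linalg.norm(pred.apply(pts) - gt.apply(pts), axis=1).mean())


def add_s_metric(model_points, pred: Pose, gt: Pose) -> float:
    """Symmetric variant: each predicted-pose point pairs with the nearest
    true-pose point (KD-tree accelerated)."""
    pts = _model_points(model_points)
    tree = cKDTree(gt.apply(pts))
    d, _ = tree.query(pred.apply(pts), k=1)
    return float(np.mean(d))


def projection_error_2d(keypoints, pred: Pose, gt: Pose,
                        K: CameraIntrinsics) -> float:
    """Mean pixel distance between keypoint projections under the two poses.

    Raises if any keypoint falls at or behind the camera under either pose
    (the sample should be flagged by the caller)."""
    pts = _model_points(keypoints)
    for pose in (pred, gt):
        if (pose.apply(pts)[:, 2] <= 0).any():
            raise ValueError("keypoint behind the camera; sample must be flagged")
    pp = project(pts, pred, K).points
    pg = project(pts, gt, K).points
    return float(np.linalg.norm(pp - pg, axis=1).mean())


def iou(a: MaskImage, b: MaskImage) -> float:
    """Intersection over union of two binary masks (0 when both empty)."""
    pa = a.pixels if isinstance(a, MaskImage) else np.asarray(a, float)
    pb = b.pixels if isinstance(b, MaskImage) else np.asarray(b, float)
    if pa.shape != pb.shape:
        raise ValueError(f"shape mismatch {pa.shape} vs {pb.shape}")
    ba, bb = pa > 0.5, pb > 0.5
    union = np.logical_or(ba, bb).sum()
    if union == 0:
        warnings.warn("both masks empty: IOU defined as 0", stacklevel=2)
        return 0.0
    return float(np.logical_and(ba, bb).sum() / union)


@dataclass
class EvalReport:
    """Per-sample metric values and threshold accuracies for one run."""

    instrument_id: str
    symmetric: bool
    n_samples: int
    diameter: float
    add_threshold: float
    per_sample: dict = field(default_factory=dict)
    accuracies: dict = field(default_factory=dict)
    mean_iou: float | None = None
    n_model_points: int = 0
    n_flagged: int = 0

    def to_dict(self) -> dict:
        return {
            "instrument_id": self.instrument_id,
            "symmetric": self.symmetric,
            "n_samples": self.n_samples,
            "diameter": self.diameter,
            "add_threshold": self.add_threshold,
            "n_model_points": self.n_model_points,
            "n_flagged": self.n_flagged,
            "accuracies_percent": self.accuracies,
            "mean_iou": self.mean_iou,
            "per_sample": {k: list(np.asarray(v, float))
                           for k, v in self.per_sample.items()},
        }

    def save_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def save_csv(self, path) -> None:
        """One-row CSV mirror (columns = metrics) for table assembly."""
        with open(path, "w", newline="") as fh:
            wr = csv.writer(fh)
            cols = ["instrument_id", "symmetric", "n_samples"] + \
                list(self.accuracies) + ["mean_iou"]
            wr.writerow(cols)
            wr.writerow([self.instrument_id, self.symmetric, self.n_samples]
                        + [f"{v:.2f}" for v in self.accuracies.values()]
                        + ["" if self.mean_iou is None else f"{self.mean_iou:.4f}"])


def evaluate(pose_pairs, mesh: TriMesh, K: CameraIntrinsics,
             keypoints: FeaturePoints3D | None = None,
             masks: list | None = None,
             instrument_id: str = "instrument",
             symmetric: bool = False,
             px_thresholds=(5.0, 3.0),
             add_fraction: float = 0.1,
             seed: int = 0) -> EvalReport:
    """Full metric suite over (pred, gt) pose pairs.

    ``pose_pairs``: list of (pred, gt) with gt possibly None; samples
    without ground truth contribute to IOU only (when ``masks`` supplies
    the observed mask per sample).  Model points for ADD are all mesh
    vertices up to 10^4, else a seeded uniform subsample.  The 2D error is
    averaged over the implicit keypoints (mesh vertices if none given).
    """
    verts = mesh.vertices
    if len(verts) > MAX_ADD_POINTS:
        rng = np.random.default_rng(seed)
        verts = verts[rng.choice(len(verts), MAX_ADD_POINTS, replace=False)]
    kp = keypoints if keypoints is not None else FeaturePoints3D(mesh.vertices)
    diam = mesh_diameter(mesh)
    thr = add_fraction * diam

    adds, add_ss, projs, ious = [], [], [], []
    n_flagged = 0
    for i, (pred, gt) in enumerate(pose_pairs):
        if gt is not None:
            adds.append(add_metric(verts, pred, gt))
            add_ss.append(add_s_metric(verts, pred, gt))
            try:
                projs.append(projection_error_2d(kp, pred, gt, K))
            except ValueError:
                n_flagged += 1
                projs.append(np.nan)
        if masks is not None and masks[i] is not None:
            ious.append(iou(rasterize_hard(mesh, pred, K), masks[i]))

    adds, add_ss = np.asarray(adds), np.asarray(add_ss)
    projs = np.asarray(projs)
    primary = add_ss if symmetric else adds
    accs = {}
    if len(primary):
        accs[f"ADD{'-S' if symmetric else ''}({add_fraction:g}d)"] = \
            100.0 * float((primary < thr).mean())
        valid = np.isfinite(projs)
        for px in px_thresholds:
            accs[f"2Dproj({px:g}px)"] = \
                100.0 * float((projs[valid] < px).mean()) if valid.any() else 0.0

    report = EvalReport(
        instrument_id=instrument_id, symmetric=symmetric,
        n_samples=len(pose_pairs), diameter=diam, add_threshold=thr,
        accuracies=accs,
        mean_iou=float(np.mean(ious)) if ious else None,
        n_model_points=len(verts), n_flagged=n_flagged)
    report.per_sample = {"add": adds, "add_s": add_ss, "proj2d": projs}
    if ious:
        report.per_sample["iou"] = np.asarray(ious)
    return report
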