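# silpose

Weakly supervised 6D pose estimation of rigid surgical instruments from
binary silhouette masks.

Minimally invasive surgery needs the pose (3D rotation **R** and
translation **t**, camera-from-model) of each instrument, but real
endoscopic footage has no pose annotations. This package implements a
pipeline that trains entirely on *synthetic* silhouettes rendered from an
instrument mesh — where pose labels are free — and at run time consumes
only a binary foreground mask from an upstream segmentation step:

1. **Synthetic data**: uniform SE(3) pose sampling, silhouette
   rasterization, 8 farthest-point-sampled 3D keypoints `z` and their
   projections `x*`, Gaussian heatmap ground truth (σ = 8 px), noise
   augmentation.
2. **Heatmap network**: a multi-resolution convolutional backbone
   (branches at strides 4/8/16/32, channel–space tensor self-attention)
   predicts one heatmap per keypoint; a differentiable soft-argmax reads
   off coordinates `x`.
3. **Back-propagatable PnP**: the pose solves
   `y = argmin_y Σᵢ‖xᵢ − π(y, zᵢ, K)‖²` (π the pinhole projection under
   intrinsics K); the backward pass applies the implicit function theorem
   to the stationarity condition `f = ∂l_p/∂y = 0`,
   `∂y/∂x = −[∂f/∂y]⁻¹ ∂f/∂x`, so the reprojection loss trains the
   network end to end.
4. **Silhouette consistency**: a differentiable soft rasterizer renders
   the mesh at a candidate pose; `l_r = MSE(rendered, observed)` serves
   as a training term and as a direct pose-refinement objective.
5. **Metrics**: ADD, ADD-S, 2D projection error (5 px / 3 px) and IOU,
   with the 0.1-diameter correctness criterion.

The training objective is `l = l_h + α·l_p + β·l_r` (α = 5·10⁻⁵,
β = 1.2), applied in stages: heatmap loss alone, then + reprojection,
then the full loss.

Everything runs on numpy/scipy with a compact reverse-mode autodiff tape
built into the package (`silpose.autodiff`); no GPU framework is
required.

## Worked example

Generate a small labelled dataset for the built-in hook instrument,
perturb the stored keypoint projections with 1 px of Gaussian noise
(standing in for network predictions), re-solve the pose, and score it:

```python
import numpy as np
from silpose.data import (PoseSamplingRanges, default_intrinsics,
                          generate_dataset, load_manifest, toy_instrument)
from silpose.geometry import farthest_point_sampling, mesh_diameter, Projections2D
from silpose.bpnp import PnPProblem, solve_pnp
from silpose.metrics import evaluate

mesh = toy_instrument("hook")
K = default_intrinsics()                      # 640x480, f = 800 px
manifest = generate_dataset(mesh, K, PoseSamplingRanges.for_mesh(mesh),
                            n=20, seed=42, out_dir="demo",
                            instrument_id="hook")
header, records = load_manifest(manifest)
keypoints = farthest_point_sampling(mesh, 8)
print(f"instrument diameter: {mesh_diameter(mesh):.3f} model units")

rng = np.random.default_rng(0)
pairs = []
for rec in records:
    noisy = rec.keypoints2d.points + rng.normal(0.0, 1.0, (8, 2))
    vis = rec.keypoints2d.visibility
    if vis.sum() < 4:
        continue                              # keypoints left the frame
    sol = solve_pnp(PnPProblem(Projections2D(noisy, vis), keypoints, K))
    pairs.append((sol.pose, rec.pose))

report = evaluate(pairs, mesh, K, keypoints=keypoints, instrument_id="hook")
print(f"samples: {report.n_samples}, ADD threshold: {report.add_threshold:.4f}")
for name, value in report.accuracies.items():
    print(f"  {name}: {value:.1f}%")
print(f"median ADD: {np.median(report.per_sample['add']):.4f} model units")
print(f"median 2D error: {np.nanmedian(report.per_sample['proj2d']):.2f} px")
```

Output:

```
instrument diameter: 4.481 model units
samples: 18, ADD threshold: 0.4481
  ADD(0.1d): 55.6%
  2Dproj(5px): 100.0%
  2Dproj(3px): 94.4%
median ADD: 0.3808 model units
median 2D error: 0.85 px
```

Reading it: with 1 px keypoint noise the reprojected keypoints are
sub-pixel accurate (median 0.85 px, 100% under 5 px), yet only 56% of
poses pass the 0.1-diameter ADD test — the hook is thin, so its eight
farthest-point keypoints are nearly collinear and the PnP problem is
ill-conditioned in the directions transverse to the shaft. That gap
between image-space and 3D accuracy is exactly why the pipeline carries a
silhouette-refinement stage (`silpose.pipeline.refine_pose`), which
polishes the pose against the full mask contour.

A command-line interface mirrors the library
(`silpose generate-data / train / infer / refine / evaluate /
make-fixtures`); run `silpose --help`.

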