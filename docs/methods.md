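# Methods

`silpose` estimates the 6D pose (rotation + translation, camera-from-model)
of a rigid surgical instrument from a single binary foreground silhouette.
The design assumes an upstream segmentation network supplies the mask; this
package covers everything after segmentation: synthetic training-data
generation, the keypoint-heatmap network, differentiable pose recovery, the
silhouette-consistency loss, and the evaluation metrics.

## Pipeline

1. **Implicit keypoints.** Eight 3D keypoints are selected on the instrument
   mesh by greedy farthest-point sampling over the vertices (start vertex =
   the vertex of maximal norm, so the selection is deterministic without a
   seed). The keypoints need not be visually salient; they only anchor the
   2D–3D correspondences.
2. **Synthetic data.** Poses are sampled uniformly from a configurable box
   of SE(3) — rotations uniform over SO(3) via uniformly distributed unit
   quaternions (or per-axis Euler intervals), depth uniform in model units,
   lateral offsets uniform in ±`xy_frac`·Z. For each pose the silhouette is
   rasterized, the keypoints are projected, and the record (mask PNG, pose,
   3D keypoints, 2D projections, per-sample seed) is written to a JSON-lines
   manifest. Ground-truth heatmaps place a Gaussian of σ = 8 image pixels
   (peak 1) at each visible projection, sampled on the stride-4 heatmap
   grid.
3. **Heatmap network.** A multi-resolution convolutional backbone (stride-4
   stem; four stages with parallel branches at strides 4/8/16/32, widths
   32/64/128/256 doubling as resolution halves; all-to-all fusion after
   each stage; channel–space tensor self-attention on the finest branch
   after stage 3; 1×1 head) emits one heatmap per keypoint at 1/4 input
   resolution. Keypoint coordinates are read off by a differentiable
   soft-argmax.
4. **Differentiable PnP.** The pose minimizes the squared reprojection
   error of the predicted 2D keypoints. The backward pass differentiates
   the solution through the implicit function theorem applied to the
   stationarity condition (details below), so reprojection-loss gradients
   reach the network.
5. **Silhouette consistency.** A soft rasterizer renders the mesh at a
   (candidate) pose differentiably; the mean-squared discrepancy against
   the observed mask is the rendering loss, used both as a training term
   and for direct pose refinement.

The composite training objective is `l = l_h + α·l_p + β·l_r` with heatmap
MSE `l_h`, reprojection loss `l_p`, rendering loss `l_r`, α = 5·10⁻⁵,
β = 1.2. Training is staged over 130 epochs — 50 epochs of `l_h` alone,
70 of `l_h + α·l_p`, 10 of the full loss — with learning rate 2·10⁻⁵
stepped to 5·10⁻⁶ / 2·10⁻⁶ / 2·10⁻⁷ at epochs 50/100/120, Adam (β₁ = 0.9)
and decoupled weight decay 10⁻³. (The learning-rate and weight-decay
magnitudes are printed without minus signs in some sources; positive
exponents are physically impossible and the values above are the intended
ones.) `TrainSchedule.scaled(n)` shrinks the plan proportionally for small
runs.

## Differentiation engine

No GPU autodiff framework is used: the package carries a compact
numpy-based reverse-mode tape (`silpose.autodiff`) with exactly the
operations the pipeline needs (elementwise arithmetic, matmul, im2col
convolution, reductions, indexing, softmax, nearest-neighbour upsampling).
All arrays are float64; the test-suite checks every operation against
central finite differences.

## Back-propagatable PnP

Forward: Levenberg–Marquardt over axis-angle + translation on the visible
correspondences, initialized by a DLT (direct linear transform) estimate
when ≥ 6 points are available, with 8 deterministic rotation restarts when
the residual exceeds 10 px² per point, followed by Newton polishing of the
stationarity condition to ‖∂l_p/∂y‖∞ ≈ 10⁻¹²; `converged` certifies
stationarity. Fewer than 4 usable correspondences is an error; an
unconverged solve returns the best-effort pose flagged, never an
exception.

Backward: with `f(x, y) = ∂l_p/∂y = 0` at the optimum,
`∂y/∂x = −[∂f/∂y]⁻¹ ∂f/∂x`. `∂f/∂x` is analytic (−2Jᵀ per point, J the
projection Jacobian); `∂f/∂y` (the 6×6 Hessian) is obtained by
complex-step differentiation of the analytic `f`, exact to machine
precision. The Hessian is regularized by +10⁻¹⁰·I and rejected above
condition number 10¹². The λ-weighted ground-truth term of the training
loss (default λ = 1) enters the loss value and its explicit gradients
only; the forward solve minimizes the prediction term alone, since ground
truth does not exist at inference and the implicit gradient must refer to
the solver's own objective.

## Soft rasterization

Per-pixel occupancy is `sigmoid(sharpness · d(p))` where `d(p)` is the
signed 2D distance from the pixel center to the silhouette contour,
computed as the distance to the nearest projected *silhouette edge* — a
mesh edge whose two adjacent faces project with opposite winding, a
boundary edge, or an edge of a near-plane-clipped face — with the sign
from a point-in-any-projected-face test. Distances are evaluated within
`3/sharpness + 3` pixels of each edge; beyond that the occupancy is
saturated and carries no gradient. Default sharpness 10 px⁻¹.

Design note: a per-face aggregation (probabilistic product of per-triangle
sigmoids, or a max over per-triangle signed distances) was evaluated first
and rejected: both dip toward 0.5 along *shared* projected edges — the
product form additionally inflates the contour where two faces meet
(occupancy 3/4 instead of 1/2) — which biased refined depth by 2–4% of the
model diameter. The silhouette-edge formulation keeps the 0.5 level set
exactly on the contour; the measured refinement error on the cube fixture
drops to ~10⁻³–10⁻⁴ of the diameter. Known limitation: for compound meshes
whose parts interpenetrate, a silhouette edge buried inside another part
still attracts the distance field, producing a shallow interior seam.

Pose refinement minimizes the rendering loss over the 6-dof pose with
L-BFGS (analytic gradients through the rasterizer), sweeping sharpness
5 → 15 px⁻¹ coarse-to-fine. The loss is evaluated on a window cropped to
the union of the observed and initial silhouettes (plus a 15% margin):
pixels far from both contours carry no gradient but dominate runtime.
Silhouette landscapes have shallow local minima a few degrees from the
true pose; when the refined silhouette's IOU against the mask stays below
0.98, the optimisation retries from six deterministic ±8° rotation
perturbations and keeps the lowest-loss result. The returned pose never
has a higher rendering loss than the initial one, and a non-overlapping
initialization is rejected with an error.

## Coordinate regression

The heatmap read-out is a temperature-weighted spatial expectation
(soft-argmax) computed inside a window of radius 8 heatmap cells around
each map's peak, with temperature τ = 10. The windowing removes the bias
the near-zero background of a large map exerts on a global expectation;
τ = 10 is small enough to interpolate between grid cells (a near-argmax
temperature such as τ = 100 quantizes the estimate to the grid, ~2 px
error at stride 4, violating the sub-half-pixel consistency the Gaussian
ground truth supports; measured max error at τ = 10 is 0.36 px). With
`window_radius=None` the expectation runs over the whole map, in which
case two equal peaks average to their midpoint; with the default window
the first (row-major) peak wins — both behaviours are documented and
tested. All-zero maps flag the keypoint invisible.

Heatmap MSE is computed on the raw head output by default (the Gaussian
targets are not normalized distributions); per-map spatial softmax
normalization is available as a config switch.

## Network implementation notes

Each backbone conv is followed by group normalization (8 groups) and ReLU;
the 1×1 head is un-normalized and zero-initialized so training starts from
the all-zero heatmap rather than from large random outputs (without
normalization, plain-Adam training at these widths collapsed to predicting
the zero map). One residual block (two 3×3 convs) per branch per stage
keeps the CPU cost of the scaled-down runs reasonable; the final fusion
feeds only the finest branch, which is the only input to the head. The
attention block forms two channel gates from height- and width-pooled
descriptors via softmax-weighted pooling, plus a spatial sigmoid gate from
a channel-collapsing 1×1 conv, each applied multiplicatively around a
residual connection.

## Evaluation metrics

* **ADD**: mean distance between model points (all mesh vertices up to
  10⁴, else a seeded subsample) under predicted vs true pose; a pose is
  correct when ADD < 0.1 × mesh diameter (max pairwise vertex distance).
* **ADD-S**: nearest-neighbour variant for rotationally symmetric
  instruments (KD-tree accelerated; the O(n²) scan is the test oracle).
  Which instruments count as symmetric is a per-instrument flag, default
  non-symmetric, echoed in every report header.
* **2D projection error**: mean pixel distance between keypoint
  projections under the two poses, with 5 px and 3 px accuracy
  thresholds; averaged over the 8 implicit keypoints by default.
* **IOU**: intersection-over-union between the silhouette re-rendered at
  the predicted pose and the observed mask; the only metric in the
  absence of pose ground truth. Both-empty is defined as 0 with a
  warning.

## Synthetic data: what it does and does not emulate

The generator emulates silhouettes of a rigid instrument under a pinhole
camera with known intrinsics, plus segmentation-style corruption
(boundary erosion/dilation ≤ 2 px, salt-and-pepper flips at rate 0.002,
Poisson-many disc speckles/holes; every component can be switched off).
Default ranges — uniform SO(3), depth 3–8 mesh diameters, lateral offsets
±0.3·Z — keep the built-in instruments in frame at 640×480 with the
default f = 800 px camera. It does **not** emulate: real segmentation
networks' structured errors, occlusion by tissue or other instruments,
articulated jaws, lens distortion, motion blur, or lighting (masks are
binary). Passing tests therefore demonstrate the geometric and learning
machinery on clean-to-mildly-noisy silhouettes, not robustness to real
endoscopic footage.

Built-in instrument stand-ins (the authors of reconstructed clinical
meshes being unavailable, these are parametric toys): a shaft with a bent
hook tip, a shaft with opened jaws, a plain tube (rotationally symmetric,
for exercising ADD-S), and a unit cube test fixture.

## Scaled-down study conditions

Full-scale training (50 000 images at 640×480, 130 epochs) is far beyond
a CPU run, so the end-to-end demonstrations use reduced problem sizes,
chosen once as the package's own test conditions:

* **Smoke training**: width ×0.25 network, 96×128 images (f = 160 px),
  200 samples, 30 epochs with the proportionally scaled staged schedule,
  base learning rate 3·10⁻³ and batch size 4 (neither batch size nor a
  CPU-scale learning rate is prescribed anywhere; both were chosen by a
  short sweep on the first training stage). The instrument is a chunkier
  hook (length 3, radius 0.35, hook 1.5) at depth 1.7–2.6 diameters
  filling much of the frame (lateral offsets ±0.07·Z keep every
  keypoint in view), with tilt sampled in ±50° and in-plane rotation in
  ±90°: with a thin instrument the eight farthest-point
  keypoints are nearly collinear (transverse spread a few pixels), and
  the PnP solve amplifies sub-pixel keypoint noise into tens of degrees
  of rotation error — a genuine conditioning property of keypoint-based
  pose estimation for thin elongated tools, worth knowing about the
  method; unrestricted SO(3) sampling additionally creates
  keypoint-identity ambiguity between near-mirror silhouettes that caps
  heatmap accuracy.
* **Refinement benchmark**: cube fixture at 640×480/f = 800, depth 3–5
  diameters, 10° rotation + 5% depth perturbations.
* **Gradient checks**: 160×120 camera (runtime), 50 PnP instances, step
  10⁻⁴.

## Numerical choices

* Pose optimization variable: axis-angle + translation; tolerances
  grad_tol 10⁻⁸, ≤ 200 LM iterations, MINPACK damping.
* Near-plane clipping at Z = 10⁻⁶ model units; partially-behind faces are
  clipped, not dropped.
* Segment distances carry a +10⁻¹² smoothing under the square root so the
  gradient is finite on the contour itself.
* Mesh diameter: exact O(V²) scan up to 5000 vertices, convex-hull vertex
  scan above (both paths agree on the test meshes).
* Degenerate inputs: empty masks, all-zero heatmaps, < 4 confident
  keypoints, behind-camera points, and both-empty IOU all have defined,
  tested behaviours (flagged or warned, never silent).

## Known limitations

* Silhouettes carry a near mirror ambiguity under weak perspective; the
  pipeline does not disambiguate tilt sign beyond what the asymmetric
  instrument shape provides.
* Thin instruments yield ill-conditioned PnP problems (see above);
  silhouette refinement partially compensates but needs an overlapping
  initialization.
* The soft rasterizer assumes consistently oriented, mostly closed
  meshes; open or inconsistently wound meshes degrade silhouette-edge
  detection to the conservative all-edges behaviour.
* Keypoint visibility is image-bounds based; self-occlusion is not
  modelled (a keypoint on the far side of the instrument still counts as
  visible if it projects inside the frame).
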