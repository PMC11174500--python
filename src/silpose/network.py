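"""Heatmap regression network and its staged training objective.

The front-end maps a binary silhouette image to one 2D likelihood map per
implicit keypoint.  It is a multi-resolution convolutional backbone: a
stride-4 stem followed by four cascaded stages whose parallel branches run
at strides 4/8/16/32 with channel widths doubling as resolution halves
(defaults 32/64/128/256); after each stage the branch features are fused
all-to-all (strided-conv downsampling, 1×1-conv + nearest-neighbour
upsampling, summation).  A channel–space tensor self-attention block
(CSTSA) refines the finest branch after stage 3.  A 1×1 head emits the
keypoint heatmaps at 1/4 of the input resolution.

Keypoint coordinates are read off the heatmaps by a differentiable spatial
soft-argmax (temperature-weighted expectation of grid positions), so that
reprojection-loss gradients from the PnP layer can reach the network
parameters.

The composite objective is

    l_final = l_h + alpha * l_p + beta * l_r

with the heatmap MSE l_h, reprojection loss l_p (alpha = 5e-5) and
silhouette rendering loss l_r (beta = 1.2); training is staged — heatmap
loss alone first, then + alpha*l_p, then the full loss — with stepped
learning rates, Adam (beta1 = 0.9) and decoupled weight decay 1e-3.

Everything runs on the package's numpy autodiff engine; parameters live in
a flat name -> Tensor dict and checkpoints are .npz archives of those
arrays plus a JSON config echo.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, conv2d
from .bpnp import bpnp_layer, reprojection_loss_t
from .data import (DEFAULT_N_KEYPOINTS, DEFAULT_SIGMA, DEFAULT_STRIDE,
                   Heatmap, load_manifest, make_heatmap_gt)
from .geometry import CameraIntrinsics, FeaturePoints3D, Projections2D
from .render import MaskImage, load_mask_png

__all__ = ["NetworkConfig", "LossWeights", "TrainSchedule", "HeatmapNetwork",
           "regress_coordinates", "soft_argmax_t", "heatmap_loss",
           "final_loss", "train", "load_checkpoint"]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyper-parameters.

    width_multiplier scales every branch width (0.25 gives the tiny test
    model); widths double as resolution halves.  input_hw is enforced
    strictly — the network never resizes silently.
    """

    base_width: int = 32
    width_multiplier: float = 1.0
    n_keypoints: int = DEFAULT_N_KEYPOINTS
    heatmap_stride: int = DEFAULT_STRIDE
    input_hw: tuple = (480, 640)
    attention: bool = True
    softmax_normalize: bool = False  # MSE is computed on raw maps by default
    tau: float = 10.0                # soft-argmax temperature

    def __post_init__(self):
        h, w = self.input_hw
        if h % 32 or w % 32:
            raise ValueError("input size must be divisible by 32 "
                             "(the coarsest branch runs at stride 32)")

    @property
    def widths(self) -> list[int]:
        w0 = max(int(round(self.base_width * self.width_multiplier)), 2)
        return [w0, 2 * w0, 4 * w0, 8 * w0]

    @property
    def heatmap_hw(self) -> tuple:
        h, w = self.input_hw
        if h % 32 or w % 32:
            raise ValueError("input size must be divisible by 32")
        return (h // self.heatmap_stride, w // self.heatmap_stride)

    def to_dict(self) -> dict:
        return {"base_width": self.base_width,
                "width_multiplier": self.width_multiplier,
                "n_keypoints": self.n_keypoints,
                "heatmap_stride": self.heatmap_stride,
                "input_hw": list(self.input_hw),
                "attention": self.attention,
                "softmax_normalize": self.softmax_normalize,
                "tau": self.tau}

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        d["input_hw"] = tuple(d["input_hw"])
        return cls(**d)


@dataclass(frozen=True)
class LossWeights:
    """Weights of the composite objective l_h + alpha*l_p + beta*l_r."""

    alpha: float = 5e-5
    beta: float = 1.2

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass(frozen=True)
class TrainSchedule:
    """Staged training plan.

    Defaults reproduce the reference schedule: 130 epochs split
    50 (heatmap only) / 70 (+ reprojection) / 10 (full loss), learning rate
    2e-5 stepped to 5e-6 at epoch 50, 2e-6 at 100 and 2e-7 at 120.
    :meth:`scaled` shrinks the plan proportionally for small runs.
    """

    total_epochs: int = 130
    heatmap_only_epochs: int = 50
    reprojection_epochs: int = 70
    full_loss_epochs: int = 10
    lr_steps: tuple = ((0, 2e-5), (50, 5e-6), (100, 2e-6), (120, 2e-7))
    batch_size: int = 8
    weight_decay: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999

    def __post_init__(self):
        if (self.heatmap_only_epochs + self.reprojection_epochs
                + self.full_loss_epochs) != self.total_epochs:
            raise ValueError("stage lengths must sum to total_epochs")

    def lr_at(self, epoch: int) -> float:
        lr = self.lr_steps[0][1]
        for e, v in self.lr_steps:
            if epoch >= e:
                lr = v
        return lr

    def stage_at(self, epoch: int) -> str:
        if epoch < self.heatmap_only_epochs:
            return "heatmap"
        if epoch < self.heatmap_only_epochs + self.reprojection_epochs:
            return "heatmap+reprojection"
        return "full"

    @classmethod
    def scaled(cls, total_epochs: int, base_lr: float = 2e-5,
               batch_size: int = 8) -> "TrainSchedule":
        """Proportionally scaled stages and learning-rate steps."""
        f = total_epochs / 130.0
        h = max(int(round(50 * f)), 1)
        fl = max(int(round(10 * f)), 1)
        r = total_epochs - h - fl
        steps = tuple((int(round(e * f)), base_lr * (v / 2e-5))
                      for e, v in ((0, 2e-5), (50, 5e-6), (100, 2e-6), (120, 2e-7)))
        return cls(total_epochs=total_epochs, heatmap_only_epochs=h,
                   reprojection_epochs=r, full_loss_epochs=fl,
                   lr_steps=steps, batch_size=batch_size)


# ---------------------------------------------------------------------------
# parameter initialisation
# ---------------------------------------------------------------------------

def _he(rng, *shape) -> np.ndarray:
    fan_in = int(np.prod(shape[1:])) if len(shape) > 1 else shape[0]
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class HeatmapNetwork:
    """The silhouette -> keypoint-heatmap network (flat parameter dict)."""

    def __init__(self, config: NetworkConfig, seed: int = 0,
                 params: dict | None = None):
        self.config = config
        self.params: dict[str, Tensor] = params if params is not None \
            else self._init_params(np.random.default_rng(seed))

    # -- parameters ---------------------------------------------------------
    def _conv(self, rng, name, ic, oc, k=3, norm=True, zero=False):
        init = np.zeros((oc, ic, k, k)) if zero else _he(rng, oc, ic, k, k)
        self.params[f"{name}.w"] = Tensor(init, requires_grad=True)
        self.params[f"{name}.b"] = Tensor(np.zeros(oc), requires_grad=True)
        if norm:
            self.params[f"{name}.g"] = Tensor(np.ones(oc), requires_grad=True)
            self.params[f"{name}.h"] = Tensor(np.zeros(oc), requires_grad=True)

    def _init_params(self, rng) -> dict:
        self.params = {}
        w = self.config.widths
        self._conv(rng, "stem.0", 1, w[0])
        self._conv(rng, "stem.1", w[0], w[0])
        # stages: one residual block (2 convs) per active branch
        for s in range(4):
            for b in range(s + 1):
                self._conv(rng, f"s{s}.b{b}.c0", w[b], w[b])
                self._conv(rng, f"s{s}.b{b}.c1", w[b], w[b])
            # transition: new branch from the previous lowest resolution
            if s < 3:
                self._conv(rng, f"t{s}", w[s], w[s + 1])
            # fusion convs; the last stage fuses into the finest branch only
            nb = s + 1
            targets = range(nb) if s < 3 else [0]
            for i in targets:            # target branch
                for j in range(nb):      # source branch
                    if i == j:
                        continue
                    if j < i:            # downsample chain j -> i
                        for step in range(i - j):
                            cin = w[j] if step == 0 else w[i]
                            self._conv(rng, f"f{s}.{j}->{i}.{step}", cin, w[i])
                    else:                # upsample: 1x1 then nearest
                        self._conv(rng, f"f{s}.{j}->{i}", w[j], w[i], k=1)
        if self.config.attention:
            self._init_cstsa(rng, w[0])
        # zero-initialised, un-normalised head: training starts from the
        # all-zero heatmap rather than from large random outputs
        self._conv(rng, "head", w[0], self.config.n_keypoints, k=1,
                   norm=False, zero=True)
        return self.params

    def _init_cstsa(self, rng, c):
        for br in ("u", "v"):
            self.params[f"att.{br}.q.w"] = Tensor(_he(rng, 1, c), requires_grad=True)
            self.params[f"att.{br}.g.w"] = Tensor(_he(rng, c, c), requires_grad=True)
            self.params[f"att.{br}.g.b"] = Tensor(np.zeros(c), requires_grad=True)
        self._conv(rng, "att.s", c, 1, k=1, norm=False)

    # -- forward ------------------------------------------------------------
    def _apply_conv(self, x, name, stride=1, relu=True, k=3):
        pad = 1 if k == 3 else 0
        y = conv2d(x, self.params[f"{name}.w"], self.params[f"{name}.b"],
                   stride=stride, pad=pad)
        if f"{name}.g" in self.params:
            y = self._group_norm(y, name)
        return y.relu() if relu else y

    def _group_norm(self, x, name, groups=8, eps=1e-5):
        b, c, h, w = x.shape
        g = groups if c % groups == 0 else 1
        xg = x.reshape(b, g, (c // g) * h * w)
        mu = xg.mean(axis=2, keepdims=True)
        var = ((xg - mu) ** 2.0).mean(axis=2, keepdims=True)
        xn = ((xg - mu) / (var + eps) ** 0.5).reshape(b, c, h, w)
        scale = self.params[f"{name}.g"].reshape(1, c, 1, 1)
        shift = self.params[f"{name}.h"].reshape(1, c, 1, 1)
        return xn * scale + shift

    def _block(self, x, name):
        y = self._apply_conv(x, f"{name}.c0")
        y = self._apply_conv(y, f"{name}.c1", relu=False)
        return (x + y).relu()

    def _fuse(self, feats, s):
        nb = len(feats)
        out = []
        targets = range(nb) if s < 3 else [0]
        for i in targets:
            acc = feats[i]
            for j in range(nb):
                if i == j:
                    continue
                if j < i:
                    y = feats[j]
                    for step in range(i - j):
                        last = step == i - j - 1
                        y = self._apply_conv(y, f"f{s}.{j}->{i}.{step}",
                                             stride=2, relu=not last)
                    acc = acc + y
                else:
                    y = self._apply_conv(feats[j], f"f{s}.{j}->{i}", k=1,
                                         relu=False)
                    acc = acc + y.upsample_nearest(2 ** (j - i))
            out.append(acc.relu())
        return out

    def cstsa(self, x: Tensor) -> Tensor:
        """Channel–space tensor self-attention with residual connection.

        Two channel-oriented branches build a global channel gate from
        height- resp. width-pooled descriptors via a softmax-weighted
        spatial pooling; a third, spatial-only branch gates per-pixel from
        a channel-collapsing 1×1 conv.  All three act multiplicatively and
        are summed onto the identity path.
        """
        out = x
        for br, axis in (("u", 2), ("v", 3)):
            d = x.mean(axis=axis)                      # (B,C,L)
            q = self.params[f"att.{br}.q.w"] @ d       # (B,1,L)
            attn = q.softmax(axis=-1)
            zvec = (d * attn).sum(axis=-1)             # (B,C)
            gate = (zvec @ self.params[f"att.{br}.g.w"].transpose()
                    + self.params[f"att.{br}.g.b"]).sigmoid()
            out = out + x * gate.reshape(gate.shape[0], gate.shape[1], 1, 1)
        smap = self._apply_conv(x, "att.s", k=1, relu=False).sigmoid()
        return out + x * smap

    def forward(self, masks: np.ndarray | Tensor) -> Tensor:
        """Batch of masks (B,H,W) or (B,1,H,W) -> raw heatmaps (B,N,h,w)."""
        if not isinstance(masks, Tensor):
            masks = Tensor(np.asarray(masks, np.float64))
        if masks.ndim == 3:
            masks = masks.reshape(masks.shape[0], 1, *masks.shape[1:])
        if masks.shape[2:] != tuple(self.config.input_hw):
            raise ValueError(
                f"input size {masks.shape[2:]} != configured "
                f"{tuple(self.config.input_hw)}; resize inputs explicitly")
        x = self._apply_conv(masks, "stem.0", stride=2)
        x = self._apply_conv(x, "stem.1", stride=2)
        feats = [x]
        for s in range(4):
            feats = [self._block(f, f"s{s}.b{b}") for b, f in enumerate(feats)]
            if len(feats) > 1:
                feats = self._fuse(feats, s)
            if s == 2 and self.config.attention:
                feats[0] = self.cstsa(feats[0])
            if s < 3:
                feats.append(self._apply_conv(feats[-1], f"t{s}", stride=2))
        out = self._apply_conv(feats[0], "head", k=1, relu=False)
        if self.config.softmax_normalize:
            b, n, h, w = out.shape
            out = out.reshape(b, n, h * w).softmax(axis=-1).reshape(b, n, h, w)
        return out

    def predict_heatmap(self, mask: MaskImage | np.ndarray) -> Heatmap:
        pix = mask.pixels if isinstance(mask, MaskImage) else np.asarray(mask)
        out = self.forward(pix[None])
        return Heatmap(out.data[0], stride=self.config.heatmap_stride)

    # -- persistence ---------------------------------------------------------
    def save(self, path, extra: dict | None = None) -> None:
        arrays = {k: v.data for k, v in self.params.items()}
        meta = {"config": self.config.to_dict()}
        if extra:
            meta.update(extra)
        np.savez(str(path), __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "HeatmapNetwork":
        with np.load(str(path)) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            params = {k: Tensor(z[k], requires_grad=True)
                      for k in z.files if k != "__meta__"}
        return cls(NetworkConfig.from_dict(meta["config"]), params=params)


def load_checkpoint(path) -> HeatmapNetwork:
    return HeatmapNetwork.load(path)


# ---------------------------------------------------------------------------
# coordinate regression (spatial soft-argmax)
# ---------------------------------------------------------------------------

def soft_argmax_t(maps: Tensor, stride: int = DEFAULT_STRIDE,
                  tau: float = 10.0, window_radius: int | None = 8) -> Tensor:
    """Differentiable coordinates from heatmaps.

    maps: (N,h,w) Tensor; returns (N,2) image-pixel coordinates
    x_i = stride * Σ_p p softmax(tau*map_i)(p), with the expectation taken
    over a window of ``window_radius`` heatmap cells around each map's peak
    (the default): restricting to the peak window removes the bias that the
    near-zero background of a large map otherwise exerts on the
    expectation.  ``window_radius=None`` uses the whole map, in which case
    equal twin peaks average to their midpoint; with a window the first
    (row-major) peak wins.  Differentiable in ``maps`` either way.
    """
    n, h, w = maps.shape
    if window_radius is None:
        flat = (maps * tau).reshape(n, h * w).softmax(axis=-1)
        gu = np.tile(np.arange(w, dtype=np.float64), h)
        gv = np.repeat(np.arange(h, dtype=np.float64), w)
        u = (flat * gu).sum(axis=-1) * float(stride)
        v = (flat * gv).sum(axis=-1) * float(stride)
        return ad.stack([u, v], axis=1)
    coords = []
    r = int(window_radius)
    for i in range(n):
        m = maps[i]
        pv, pu = np.unravel_index(int(np.argmax(m.data)), (h, w))
        v0, v1 = max(pv - r, 0), min(pv + r + 1, h)
        u0, u1 = max(pu - r, 0), min(pu + r + 1, w)
        win = m[v0:v1, u0:u1]
        wh, ww = win.shape
        weights = (win * tau).reshape(wh * ww).softmax(axis=-1)
        gu = np.tile(np.arange(u0, u1, dtype=np.float64), wh)
        gv = np.repeat(np.arange(v0, v1, dtype=np.float64), ww)
        u = (weights * gu).sum() * float(stride)
        v = (weights * gv).sum() * float(stride)
        coords.append(ad.stack([u, v]))
    return ad.stack(coords)


def regress_coordinates(heatmap: Heatmap, tau: float = 10.0,
                        window_radius: int | None = 8,
                        zero_tol: float = 1e-12) -> Projections2D:
    """Soft-argmax coordinate read-out with visibility flagging.

    All-zero maps mark the keypoint invisible.  Documented tie behaviour:
    with the default peak window, two equal peaks resolve to the first
    (row-major) one; with ``window_radius=None`` (whole-map expectation)
    they average to their midpoint.
    """
    maps = heatmap.maps
    vis = maps.reshape(len(maps), -1).max(axis=1) > zero_tol
    coords = soft_argmax_t(Tensor(maps), stride=heatmap.stride, tau=tau,
                           window_radius=window_radius).data
    return Projections2D(coords, vis)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def heatmap_loss(m, m_star) -> float:
    """Mean squared error between predicted and ground-truth heatmaps."""
    a = m.maps if isinstance(m, Heatmap) else np.asarray(m, float)
    b = m_star.maps if isinstance(m_star, Heatmap) else np.asarray(m_star, float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def final_loss(lh: float, lp: float, lr: float,
               w: LossWeights = LossWeights()) -> float:
    """Composite objective l_h + alpha*l_p + beta*l_r."""
    return float(lh) + w.alpha * float(lp) + w.beta * float(lr)


# ---------------------------------------------------------------------------
# Adam with decoupled weight decay
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params: dict[str, Tensor], schedule: TrainSchedule):
        self.params = params
        self.sched = schedule
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.t = 0

    def step(self, lr: float):
        self.t += 1
        b1, b2 = self.sched.beta1, self.sched.beta2
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p.data -= lr * (mhat / (np.sqrt(vhat) + 1e-8)
                            + self.sched.weight_decay * p.data)
            p.grad = None


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train(manifest_path, config: NetworkConfig,
          schedule: TrainSchedule, seed: int, out_dir,
          weights: LossWeights = LossWeights(),
          lambda_weight: float = 1.0,
          mesh=None, log_every: int = 1) -> Path:
    """Staged training on a generated dataset; returns the checkpoint path.

    Stage 1 minimises the heatmap MSE alone; stage 2 adds alpha times the
    reprojection loss through the PnP layer; stage 3 uses the full
    composite loss including the rendering term (requires ``mesh``).
    Writes ``checkpoint.npz``, ``train_log.jsonl`` and the resolved config
    next to it.  Aborts on NaN loss, keeping the last finite checkpoint.
    """
    from .render import soft_occupancy  # local import to avoid cycle at load

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header, records = load_manifest(manifest_path)
    root = Path(manifest_path).parent
    K = CameraIntrinsics.from_dict(header["intrinsics"])
    if (K.height, K.width) != tuple(config.input_hw):
        raise ValueError("dataset resolution does not match network input size")
    z = FeaturePoints3D(np.asarray(header["keypoints3d"]))
    sigma = header.get("sigma", DEFAULT_SIGMA)
    stride = config.heatmap_stride
    hm_hw = config.heatmap_hw

    masks = np.stack([load_mask_png(root / r.mask_path).pixels for r in records])
    gts = np.stack([make_heatmap_gt(r.keypoints2d, sigma=sigma,
                                    grid_hw=hm_hw, stride=stride).maps
                    for r in records])
    x_stars = [r.keypoints2d for r in records]

    net = HeatmapNetwork(config, seed=seed)
    opt = _Adam(net.params, schedule)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(1,)))
    log_path = out / "train_log.jsonl"
    ckpt_path = out / "checkpoint.npz"
    (out / "config.json").write_text(json.dumps(
        {"network": config.to_dict(), "schedule": vars(schedule) | {
            "lr_steps": [list(s) for s in schedule.lr_steps]},
         "weights": {"alpha": weights.alpha, "beta": weights.beta},
         "lambda": lambda_weight, "seed": seed}, indent=2, default=str))

    n = len(records)
    logf = open(log_path, "w")
    try:
        for epoch in range(schedule.total_epochs):
            stage = schedule.stage_at(epoch)
            lr = schedule.lr_at(epoch)
            order = rng.permutation(n)
            ep_lh = ep_lp = ep_lr = 0.0
            nb = 0
            t0 = time.time()
            for start in range(0, n, schedule.batch_size):
                idx = order[start:start + schedule.batch_size]
                out_maps = net.forward(masks[idx])
                diff = out_maps - Tensor(gts[idx])
                lh = (diff * diff).mean()
                loss = lh
                lp_val = lr_val = 0.0
                if stage != "heatmap":
                    lp_terms = []
                    for bi, si in enumerate(idx):
                        vis = x_stars[si].visibility
                        if vis.sum() < 4:
                            continue
                        coords = soft_argmax_t(out_maps[int(bi)],
                                               stride=stride, tau=config.tau)
                        y, sol = bpnp_layer(coords, z, K, visibility=vis)
                        if not sol.converged:
                            continue
                        lp_terms.append(reprojection_loss_t(
                            coords, x_stars[si].points, y, z, K,
                            visibility=vis, lambda_weight=lambda_weight))
                        if stage == "full" and mesh is not None:
                            occ = soft_occupancy(mesh, y, K)
                            rdiff = occ - Tensor(masks[si])
                            lr_t = (rdiff * rdiff).mean()
                            loss = loss + (weights.beta / len(idx)) * lr_t
                            lr_val += lr_t.item()
                    if lp_terms:
                        lp_sum = lp_terms[0]
                        for t in lp_terms[1:]:
                            lp_sum = lp_sum + t
                        loss = loss + (weights.alpha / len(idx)) * lp_sum
                        lp_val = lp_sum.item() / len(idx)
                if not np.isfinite(loss.item()):
                    logf.write(json.dumps({"epoch": epoch, "event": "nan-abort"})
                               + "\n")
                    return ckpt_path
                loss.backward()
                opt.step(lr)
                ep_lh += lh.item()
                ep_lp += lp_val
                ep_lr += lr_val / max(len(idx), 1)
                nb += 1
            rec = {"epoch": epoch, "stage": stage, "lr": lr,
                   "heatmap_loss": ep_lh / nb, "reproj_loss": ep_lp / nb,
                   "render_loss": ep_lr / nb,
                   "seconds": round(time.time() - t0, 2)}
            if epoch % log_every == 0 or epoch == schedule.total_epochs - 1:
                logf.write(json.dumps(rec) + "\n")
                logf.flush()
            net.save(ckpt_path, extra={"epoch": epoch})
    finally:
        logf.close()
    return ckpt_path
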