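"""Reproducible fixture generation: toy meshes, intrinsics, a mini dataset
and canonical gradient-check instances for the PnP layer.

Everything is derived deterministically from one seed so two runs produce
byte-identical trees; the gradient-check instances store the expected
backward output so they can be re-verified on load.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import bpnp as B
from .data import (NoiseConfig, PoseSamplingRanges, default_intrinsics,
                   generate_dataset, toy_instrument, _sample_one_pose)
from .geometry import (FeaturePoints3D, Projections2D, farthest_point_sampling,
                       project, save_intrinsics, save_mesh, CameraIntrinsics)

__all__ = ["make_fixtures", "load_gradient_check_instances"]


def make_fixtures(out_dir, seed: int = 0, n_samples: int = 50,
                  n_grad_instances: int = 3) -> Path:
    """Write the canonical fixture tree used by tests and examples.

    out_dir/
      meshes/{hook,jaws,tube,cube}.obj
      intrinsics.yaml                     (640x480 default camera)
      mini_dataset/manifest.jsonl + masks (n_samples, instrument 'hook')
      bpnp_grad_checks.json               (instances + expected gradients)
    """
    out = Path(out_dir)
    (out / "meshes").mkdir(parents=True, exist_ok=True)
    for name in ("hook", "jaws", "tube", "cube"):
        save_mesh(toy_instrument(name), out / "meshes" / f"{name}.obj")

    K = default_intrinsics()
    save_intrinsics(K, out / "intrinsics.yaml")

    mesh = toy_instrument("hook")
    generate_dataset(mesh, K, PoseSamplingRanges.for_mesh(mesh),
                     n=n_samples, seed=seed, out_dir=out / "mini_dataset",
                     instrument_id="hook", noise=NoiseConfig())

    _write_grad_checks(out / "bpnp_grad_checks.json", seed, n_grad_instances, K)
    return out


def _write_grad_checks(path: Path, seed: int, n_instances: int,
                       K: CameraIntrinsics) -> None:
    cube = toy_instrument("cube")
    z = farthest_point_sampling(cube, 8)
    instances = []
    for i in range(n_instances):
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=seed, spawn_key=(900, i)))
        pose = _sample_one_pose(PoseSamplingRanges(depth=(3.0, 8.0)), rng)
        x = project(z, pose, K).points + rng.normal(0.0, 1.0, (8, 2))
        gw = rng.normal(size=6)
        prob = B.PnPProblem(Projections2D(x), z, K)
        sol = B.solve_pnp(prob)
        grad = B.implicit_backward(sol, prob, gw)
        instances.append({
            "x": x.tolist(), "z": z.points.tolist(),
            "grad_wrt_pose": gw.tolist(),
            "pose_params": sol.pose.as_params().tolist(),
            "expected_grad_wrt_x": grad.tolist(),
        })
    path.write_text(json.dumps({"intrinsics": K.to_dict(),
                                "instances": instances}, indent=2) + "\n")


def load_gradient_check_instances(path):
    """Load and re-verify the stored PnP backward instances.

    Recomputes the implicit gradient for each instance and checks it
    against the stored expectation (1e-9 absolute); returns the parsed
    structure.  Raises if any instance fails re-verification.
    """
    d = json.loads(Path(path).read_text())
    K = CameraIntrinsics.from_dict(d["intrinsics"])
    for k, inst in enumerate(d["instances"]):
        prob = B.PnPProblem(Projections2D(np.asarray(inst["x"])),
                            FeaturePoints3D(np.asarray(inst["z"])), K)
        sol = B.solve_pnp(prob)
        grad = B.implicit_backward(sol, prob, np.asarray(inst["grad_wrt_pose"]))
        if not np.allclose(grad, np.asarray(inst["expected_grad_wrt_x"]),
                           atol=1e-9):
            raise ValueError(f"gradient-check instance {k} failed re-verification")
    return d
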