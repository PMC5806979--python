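"""End-to-end orchestration: simulate -> depth -> grid -> pca -> stats.

Every stage writes inspectable files into its own subdirectory and never
mutates an earlier stage's outputs; a manifest records the package version,
seed, config hash and per-stage output hashes, so a rerun with the same
config is bit-identical.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .camera import save_rig
from .errors import PipelineConfigError
from .grid import (
    build_grid_trajectory,
    cog_trajectory,
    make_virtual_grid,
    save_roi,
    trajectory_to_frame,
)
from .io import write_manifest, write_pfm, write_png
from .matching import MatchParams
from .ranging import VideoSequence, build_range_sequence
from .stats import build_motion_matrix, fit_pca, save_pca
from .synthetic import (
    RenderParams,
    default_rig,
    default_roi,
    default_scene,
    ground_truth_trajectory,
    render_stereo_pair,
    scene_max_disparity,
    small_scene,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration for the full synthetic pipeline.

    ``preset='paper'`` is the named paper-mode configuration: 5x5 grid
    (36 intersections), 12 principal components, rest frame 0, 30 frames
    at 30 fps.
    """

    preset: str = "paper"  # "paper" | "small"
    seed: int = 0
    frames: int | None = None
    amplitude: float = 4.7
    n: int = 5
    k: int = 12
    rest_frame: int = 0
    noise_sd: float = 2.0
    kappa_occ: float = 25.0
    kappa_r: float = 5.0
    max_disparity: int | None = None

    def validate(self) -> None:
        if self.n < 1 or self.k < 1:
            raise PipelineConfigError("n and k must be >= 1")
        if self.preset not in ("paper", "small"):
            raise PipelineConfigError(f"unknown preset {self.preset!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _scene_for(config: PipelineConfig):
    if config.preset == "small":
        params, rig = small_scene(amplitude=config.amplitude,
                                  frames=config.frames or 6)
    else:
        params = default_scene(amplitude=config.amplitude,
                               frames=config.frames or 30)
        rig = default_rig()
    return params, rig


def _hash_dir(d: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(d.rglob("*")):
        if p.is_file():
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()[:16]


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run all five stages and return the manifest (also written to disk)."""
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages = []

    params, rig = _scene_for(config)
    render = RenderParams(rig=rig, noise_sd=config.noise_sd, seed=config.seed)
    roi = default_roi(params, rig)

    # 1. simulate ----------------------------------------------------------
    sim = out / "simulate"
    sim.mkdir(exist_ok=True)
    left_frames, right_frames = [], []
    for f in range(params.frames):
        lf, rf, depth, disp = render_stereo_pair(params, render, f)
        left_frames.append(lf)
        right_frames.append(rf)
        write_png(sim / f"left_{f:03d}.png", lf)
        write_png(sim / f"right_{f:03d}.png", rf)
    save_rig(rig, sim / "rig.yaml")
    save_roi(roi, sim / "roi.json")
    truth = ground_truth_trajectory(params, rig, roi, n=config.n)
    trajectory_to_frame(truth).to_csv(sim / "truth_trajectory.csv", index=False)
    stages.append("simulate")

    # 2. depth -------------------------------------------------------------
    dep = out / "depth"
    dep.mkdir(exist_ok=True)
    dmax = config.max_disparity or scene_max_disparity(params, rig)
    mp = MatchParams(max_disparity=dmax, kappa_occ=config.kappa_occ,
                     kappa_r=config.kappa_r)
    lseq = VideoSequence(left_frames, fps=params.fps, camera="left")
    rseq = VideoSequence(right_frames, fps=params.fps, camera="right")
    seq = build_range_sequence(lseq, rseq, rig, mp)
    for im in seq:
        write_pfm(dep / f"range_{im.frame_index:03d}.pfm",
                  np.nan_to_num(im.points, nan=0.0))
        write_png(dep / f"valid_{im.frame_index:03d}.png", im.valid)
    stages.append("depth")

    # 3. grid --------------------------------------------------------------
    gr = out / "grid"
    gr.mkdir(exist_ok=True)
    grid = make_virtual_grid(roi, n=config.n)
    traj = build_grid_trajectory(seq, grid)
    trajectory_to_frame(traj).to_csv(gr / "trajectory.csv", index=False)
    stages.append("grid")

    # 4. pca ---------------------------------------------------------------
    pc = out / "pca"
    mm = build_motion_matrix(traj, rest_frame=config.rest_frame)
    pca = fit_pca(mm, k=config.k)
    save_pca(pca, pc)
    stages.append("pca")

    # 5. stats -------------------------------------------------------------
    st = out / "stats"
    st.mkdir(exist_ok=True)
    cog = cog_trajectory(traj, rest_frame=config.rest_frame)
    truth_cog = cog_trajectory(truth, rest_frame=config.rest_frame)
    summary = {
        "max_cog_shift_mm": float(cog.shifts.max()),
        "truth_max_cog_shift_mm": float(truth_cog.shifts.max()),
        "n_frames": int(traj.n_frames),
        "n_nodes": int(traj.n_nodes),
        "k": int(pca.k),
        "explained_variance_ratio": pca.explained_variance_ratio.tolist(),
    }
    (st / "summary.json").write_text(json.dumps(summary, indent=2))
    stages.append("stats")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.digest(),
        "stages": stages,
        "outputs": {s: _hash_dir(out / s) for s in stages},
    }
    write_manifest(out / "manifest.json", manifest)
    return manifest
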