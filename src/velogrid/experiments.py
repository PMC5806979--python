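"""Desk-scale study routines combining the pipeline stages.

These functions run the complete measurement chain on synthetic scenes with
known ground truth and report the quantities the analysis is about: maximum
center-of-gravity shift, dominant-mode alignment, mode-variance ratios, and
the group statistics of a simulated two-group cohort.  They are the
programmatic counterparts of the CLI stages and are what the acceptance
script executes.
"""
from __future__ import annotations

import numpy as np

from .camera import rectification_maps
from .grid import (
    QuadrangleROI,
    build_grid_trajectory,
    cog_trajectory,
    make_virtual_grid,
)
from .matching import MatchParams, compute_disparity_map
from .ranging import RangeSequence, disparity_to_range
from .stats import (
    build_motion_matrix,
    discriminant_classify,
    fit_pca,
    mann_whitney,
    subject_scores,
)
from .synthetic import (
    RenderParams,
    SceneRenderer,
    default_rig,
    default_roi,
    default_scene,
    ground_truth_trajectory,
    scene_disparity_band,
    simulate_cohort,
    two_mode_scene,
)

__all__ = ["end_to_end_metrology", "two_mode_recovery", "cohort_study"]


def _roi_row_band(roi: QuadrangleROI, height: int,
                  up: int = 90, down: int = 30) -> tuple[int, int]:
    """Image-row band covering the ROI plus headroom for upward motion."""
    ys = roi.corners[:, 1]
    return max(int(ys.min()) - up, 0), min(int(ys.max()) + down, height)


def end_to_end_metrology(
    seed: int,
    amplitude: float = 4.7,
    frames: int = 30,
    noise_sd: float = 2.0,
    n: int = 5,
    k: int = 12,
) -> dict:
    """Render the canonical scene, run the full pipeline, compare with truth.

    Returns recovered and analytic maximum CoG shift (mm), their absolute
    difference, the |cosine| between the pipeline's first motion mode and the
    ground-truth trajectory's first mode, and PC1's explained variance.
    """
    rig = default_rig()
    params = default_scene(amplitude=amplitude, frames=frames)
    render = RenderParams(rig=rig, noise_sd=noise_sd, seed=seed)
    roi = default_roi(params, rig)
    rows = _roi_row_band(roi, rig.rect_intrinsics.height)
    dmin, dmax = scene_disparity_band(params, rig)
    mp = MatchParams(max_disparity=dmax, min_disparity=dmin)
    renderer = SceneRenderer(params, render, with_truth_maps=False,
                             rows=(max(rows[0] - 25, 0), min(rows[1] + 25,
                                   rig.rect_intrinsics.height)))
    from scipy.ndimage import map_coordinates

    coords = {}
    for side in ("left", "right"):
        m = rectification_maps(rig, side)
        coords[side] = np.nan_to_num(
            np.stack([m[..., 1].ravel(), m[..., 0].ravel()]), nan=-1e6
        )
    shape = (rig.rect_intrinsics.height, rig.rect_intrinsics.width)
    images = []
    for f in range(frames):
        L, R, _, _ = renderer.frame(f)
        Lw = map_coordinates(L, coords["left"], order=1).reshape(shape)
        Rw = map_coordinates(R, coords["right"], order=1).reshape(shape)
        dm = compute_disparity_map(Lw, Rw, mp, rows=rows)
        images.append(disparity_to_range(dm, rig, frame_index=f, fps=params.fps))
    grid = make_virtual_grid(roi, n=n)
    traj = build_grid_trajectory(RangeSequence(images=images), grid)
    truth = ground_truth_trajectory(params, rig, roi, n=n)

    rec_shift = float(cog_trajectory(traj).shifts.max())
    tru_shift = float(cog_trajectory(truth).shifts.max())
    pca = fit_pca(build_motion_matrix(traj), k=k)
    pca_truth = fit_pca(build_motion_matrix(truth), k=k)
    cos1 = float(abs(pca.loadings[0] @ pca_truth.loadings[0]))
    return {
        "recovered_max_cog_shift_mm": rec_shift,
        "truth_max_cog_shift_mm": tru_shift,
        "cog_shift_error_mm": abs(rec_shift - tru_shift),
        "pc1_cosine": cos1,
        "pc1_explained_variance": float(pca.explained_variance_ratio[0]),
        "n_scores": int(pca.scores.shape[1]),
        "n_frames": frames,
    }


def two_mode_recovery(
    seed: int,
    amplitude1: float = 4.0,
    amplitude2: float = 2.0,
    noise_sd: float = 0.05,
    frames: int = 30,
) -> dict:
    """Fit PCA to a two-mode node trajectory and compare with the injection.

    The scene injects a dominant posterior-upper mode and a weaker
    (orthogonalized) upper mode with orthogonal equal-variance temporal
    profiles, so PCA should recover both directions and an eigenvalue ratio
    equal to the squared amplitude ratio.
    """
    from .synthetic import synthetic_node_trajectories

    scene = two_mode_scene(amplitude1=amplitude1, amplitude2=amplitude2,
                           frames=frames)
    traj = synthetic_node_trajectories(scene.modes, frames=frames,
                                       noise_sd=noise_sd, seed=seed,
                                       weighting="bump")
    mm = build_motion_matrix(traj)
    pca = fit_pca(mm, k=2)
    N = mm.n_nodes
    # injected spatial patterns: weight profile times the mode direction
    side = traj.n + 1
    g = np.linspace(0, 1, side)
    S, T = np.meshgrid(g, g, indexing="ij")
    w = (np.sin(np.pi * S) * np.sin(np.pi * T)).ravel()
    cosines = []
    for mode in scene.modes:
        pattern = (w[:, None] * mode.direction).ravel()
        pattern /= np.linalg.norm(pattern)
        cosines.append([float(abs(pattern @ pca.loadings[i])) for i in range(2)])
    ratio = float(pca.eigenvalues[0] / pca.eigenvalues[1])
    return {
        "cos_mode1_pc1": cosines[0][0],
        "cos_mode2_pc2": cosines[1][1],
        "variance_ratio": ratio,
        "injected_ratio": (amplitude1 / amplitude2) ** 2,
        "ordering_correct": cosines[0][0] > cosines[0][1],
    }


def cohort_study(seed: int, n_male: int = 10, n_female: int = 10) -> dict:
    """Simulated 20-subject study: group shifts, Mann-Whitney, discriminant.

    Generates a cohort at the reported group conditions, measures each
    subject's maximum CoG shift, tests for a sex difference, and classifies
    frames from per-subject (PCS1, PCS2) with a linear discriminant.
    """
    cohort = simulate_cohort(n_male=n_male, n_female=n_female, seed=seed)
    shifts = {
        sid: float(cog_trajectory(traj).shifts.max())
        for sid, (traj, _) in cohort.items()
    }
    male = [v for sid, v in shifts.items() if sid.startswith("M")]
    female = [v for sid, v in shifts.items() if sid.startswith("F")]
    mw = mann_whitney(male, female)
    table = subject_scores(cohort, k=2)
    disc = discriminant_classify(
        table[["pcs1", "pcs2"]].to_numpy(),
        table["group"].to_numpy(),
        subject_ids=table["subject"].to_numpy(),
    )
    return {
        "male_mean_shift_mm": float(np.mean(male)),
        "female_mean_shift_mm": float(np.mean(female)),
        "mann_whitney_U": mw.U,
        "mann_whitney_p": mw.p_value,
        "discriminant_accuracy_pct": disc.accuracy_pct,
        "discriminant_loso_accuracy_pct": disc.loso_accuracy_pct,
        "n_subjects": n_male + n_female,
    }
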