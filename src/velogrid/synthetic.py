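"""Synthetic deforming-surface stereo fixtures with analytic ground truth.

Emulates the measurement situation end-to-end: a smooth textured patch at
endoscopic working distance (20-60 mm) deforms a few millimetres in a
dominant direction over ~1 s at 30 fps, is imaged by a calibrated stereo
rig through the Tsai distortion model, and every derived quantity (depth,
disparity, grid trajectory) is also available analytically from the same
geometry.  The projected lattice of the physical device is modelled as
surface-attached texture: the matcher treats the pattern purely as texture,
and attaching it to the surface gives exact ground-truth correspondence.

Rendering is by per-pixel ray/surface intersection (vectorized Newton on the
patch parameters), so images contain no splatting holes and ground truth is
exact to solver tolerance.  Gaussian pixel noise is added last, seeded; two
seeds differ only in noise while ground truth is identical.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np

from .camera import (
    Camera,
    CameraIntrinsics,
    CameraPose,
    StereoRig,
    project,
    rectify,
    undistort_pixel,
)
from .errors import EmptyRenderError
from .grid import GridTrajectory, QuadrangleROI, make_virtual_grid

__all__ = [
    "DeformationMode",
    "SurfaceParams",
    "RenderParams",
    "rise_hold_fall",
    "surface_point",
    "render_stereo_pair",
    "SceneRenderer",
    "raycast_surface",
    "scene_disparity_band",
    "ground_truth_trajectory",
    "default_rig",
    "default_scene",
    "small_scene",
    "two_mode_scene",
    "default_roi",
    "synthetic_node_trajectories",
    "simulate_cohort",
    "POSTERIOR_SUPERIOR",
    "SUPERIOR_ORTHOGONAL",
]

_S45 = np.sin(np.pi / 4)

#: Dominant motion analogue in the camera frame (y down, z away): posterior-upper.
POSTERIOR_SUPERIOR = np.array([0.0, -_S45, -_S45])

#: Upper direction with its posterior-superior component removed, so the two
#: canonical modes are orthogonal and separable by PCA.
SUPERIOR_ORTHOGONAL = np.array([0.0, -_S45, _S45])


def rise_hold_fall(frames: int = 30, rise: int | None = None,
                   hold: int | None = None) -> np.ndarray:
    """Smoothstep rise-hold-fall envelope in [0, 1] with envelope(0) = 0.

    Defaults split the sequence into roughly equal thirds.
    """
    if frames < 4:
        raise ValueError("need at least 4 frames for a rise-hold-fall profile")
    rise = frames // 3 if rise is None else rise
    hold = frames // 3 if hold is None else hold
    t = np.arange(frames, dtype=float)
    fall = frames - 1 - rise - hold
    if fall < 1:
        raise ValueError("frames too few for the requested rise/hold")

    def smoothstep(x):
        x = np.clip(x, 0.0, 1.0)
        return 3 * x**2 - 2 * x**3

    env = np.where(
        t < rise,
        smoothstep(t / rise),
        np.where(t < rise + hold, 1.0, smoothstep((frames - 1 - t) / fall)),
    )
    return env


@dataclass(frozen=True)
class DeformationMode:
    """One motion mode: unit direction, peak amplitude (mm), temporal profile."""

    direction: np.ndarray
    amplitude: float
    profile: np.ndarray  # (frames,) values in [0, 1]

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("zero deformation direction")
        object.__setattr__(self, "direction", d / n)
        object.__setattr__(self, "profile", np.asarray(self.profile, dtype=float))
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


@dataclass(frozen=True)
class SurfaceParams:
    """Deforming-patch geometry.

    The base patch is a plane of ``extent`` (mm) centered at ``center`` (mm,
    world = left camera frame), parameterized by (s, t) in [0, 1]^2 with
    s along +x and t along +y.  Displacement at frame f is
    ``sum_m profile_m[f] * weight(s, t) * amplitude_m * direction_m`` with a
    smooth in-patch bump weight (or uniform weighting).
    """

    extent: tuple[float, float] = (22.0, 22.0)
    center: tuple[float, float, float] = (6.0, 0.0, 40.0)
    frames: int = 30
    fps: float = 30.0
    modes: tuple[DeformationMode, ...] = ()
    weighting: str = "bump"  # "bump" | "uniform"

    def __post_init__(self) -> None:
        if not (20.0 <= self.center[2] <= 60.0):
            warnings.warn(
                f"base depth {self.center[2]:.1f} mm outside the validated "
                "endoscope range 20-60 mm"
            )
        for m in self.modes:
            if len(m.profile) != self.frames:
                raise ValueError("mode profile length must equal frame count")

    @property
    def z0(self) -> float:
        return self.center[2]

    def weight(self, s: np.ndarray, t: np.ndarray) -> np.ndarray:
        if self.weighting == "uniform":
            return np.ones(np.broadcast(s, t).shape)
        return np.sin(np.pi * np.clip(s, 0, 1)) * np.sin(np.pi * np.clip(t, 0, 1))

    def weight_grad(self, s, t):
        if self.weighting == "uniform":
            z = np.zeros(np.broadcast(s, t).shape)
            return z, z.copy()
        ws = np.pi * np.cos(np.pi * s) * np.sin(np.pi * t)
        wt = np.pi * np.sin(np.pi * s) * np.cos(np.pi * t)
        inside = (s >= 0) & (s <= 1) & (t >= 0) & (t <= 1)
        return np.where(inside, ws, 0.0), np.where(inside, wt, 0.0)


@dataclass(frozen=True)
class RenderParams:
    """Rendering configuration: rig, lattice texture, pixel noise, seed."""

    rig: StereoRig
    texture_period: float = 22.0  # lattice periods across the patch
    texture_contrast: float = 35.0
    noise_sd: float = 2.0  # intensity units on the 0-255 scale
    background: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.texture_period < 2:
            raise ValueError("texture period must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


def surface_point(
    params: SurfaceParams, s: np.ndarray, t: np.ndarray, frame: int
) -> np.ndarray:
    """Deterministic surface position(s) (mm) at patch parameters (s, t)."""
    s = np.asarray(s, dtype=float)
    t = np.asarray(t, dtype=float)
    ex, ey = params.extent
    cx, cy, cz = params.center
    base = np.stack(
        [cx + (s - 0.5) * ex, cy + (t - 0.5) * ey, np.broadcast_to(cz, np.broadcast(s, t).shape).copy()],
        axis=-1,
    )
    w = params.weight(s, t)
    for m in params.modes:
        base = base + (m.profile[frame] * m.amplitude) * w[..., None] * m.direction
    return base


def _surface_jacobian(params: SurfaceParams, s, t, frame):
    """d(surface)/ds and d(surface)/dt at (s, t)."""
    ex, ey = params.extent
    shape = np.broadcast(s, t).shape
    Ps = np.zeros(shape + (3,))
    Pt = np.zeros(shape + (3,))
    Ps[..., 0] = ex
    Pt[..., 1] = ey
    ws, wt = params.weight_grad(s, t)
    for m in params.modes:
        amp = m.profile[frame] * m.amplitude
        Ps += amp * ws[..., None] * m.direction
        Pt += amp * wt[..., None] * m.direction
    return Ps, Pt


def _cramer_solve(J, r):
    """Batched 3x3 solve J @ x = r by Cramer's rule (vectorized)."""
    a, b, c = J[..., 0, 0], J[..., 0, 1], J[..., 0, 2]
    d, e, f = J[..., 1, 0], J[..., 1, 1], J[..., 1, 2]
    g, h, i = J[..., 2, 0], J[..., 2, 1], J[..., 2, 2]
    det = a * (e * i - f * h) - b * (d * i - f * g) + c * (d * h - e * g)
    r0, r1, r2 = r[..., 0], r[..., 1], r[..., 2]
    x0 = r0 * (e * i - f * h) - b * (r1 * i - f * r2) + c * (r1 * h - e * r2)
    x1 = a * (r1 * i - f * r2) - r0 * (d * i - f * g) + c * (d * r2 - r1 * g)
    x2 = a * (e * r2 - r1 * h) - b * (d * r2 - r1 * g) + r0 * (d * h - e * g)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.stack([x0, x1, x2], axis=-1) / det[..., None]


def raycast_surface(
    params: SurfaceParams,
    origin: np.ndarray,
    directions: np.ndarray,
    frame: int,
    max_iter: int = 20,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Intersect rays ``origin + lam * d`` with the frame-``frame`` surface.

    Newton iteration on (s, t, lam), initialized from the base-plane
    intersection.  Returns ``(lam, s, t, hit)``; ``lam`` is in units of the
    (unnormalized) direction vectors.
    """
    o = np.asarray(origin, dtype=float).reshape(3)
    d = np.asarray(directions, dtype=float)
    flat = d.reshape(-1, 3)
    ex, ey = params.extent
    cx, cy, cz = params.center
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = (cz - o[2]) / flat[:, 2]
    s = (o[0] + lam * flat[:, 0] - cx) / ex + 0.5
    t = (o[1] + lam * flat[:, 1] - cy) / ey + 0.5
    active = np.isfinite(lam) & (lam > 0) & (s > -0.6) & (s < 1.6) & (t > -0.6) & (t < 1.6)
    idx = np.flatnonzero(active)
    s_a, t_a, lam_a, d_a = s[idx], t[idx], lam[idx], flat[idx]
    # Newton with active-set shrinking: converged rays drop out each sweep
    for _ in range(max_iter):
        if idx.size == 0:
            break
        P = surface_point(params, s_a, t_a, frame)
        r = P - o - lam_a[:, None] * d_a
        live = np.abs(r).max(axis=-1) >= tol
        s[idx], t[idx], lam[idx] = s_a, t_a, lam_a
        if not live.any():
            break
        idx = idx[live]
        s_a, t_a, lam_a, d_a, r = s_a[live], t_a[live], lam_a[live], d_a[live], r[live]
        Ps, Pt = _surface_jacobian(params, s_a, t_a, frame)
        J = np.stack([Ps, Pt, -d_a], axis=-1)  # columns: dP/ds, dP/dt, -d
        step = _cramer_solve(J, -r)
        ok = np.all(np.isfinite(step), axis=-1)
        s_a = np.where(ok, s_a + step[:, 0], s_a)
        t_a = np.where(ok, t_a + step[:, 1], t_a)
        lam_a = np.where(ok, lam_a + step[:, 2], lam_a)
        s[idx], t[idx], lam[idx] = s_a, t_a, lam_a
    with np.errstate(invalid="ignore"):
        hit = (
            active & (s >= 0) & (s <= 1) & (t >= 0) & (t <= 1) & (lam > 0)
            & np.isfinite(s) & np.isfinite(t)
        )
    shape = d.shape[:-1]
    return lam.reshape(shape), s.reshape(shape), t.reshape(shape), hit.reshape(shape)


def _texture(rp: RenderParams, s: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Surface-attached lattice texture (plus a slow diagonal component)."""
    p = rp.texture_period
    c = rp.texture_contrast
    return (
        110.0
        + c * (np.sin(2 * np.pi * p * s) + np.sin(2 * np.pi * p * t))
        + 0.6 * c * np.sin(2 * np.pi * (p / 2.3) * (s + 0.6 * t))
    )


def _camera_rays(cam: Camera) -> tuple[np.ndarray, np.ndarray]:
    """World-frame origin and per-pixel ray directions of an original camera."""
    ci = cam.intrinsics
    H, W = ci.height, ci.width
    u, v = np.meshgrid(np.arange(W, dtype=float), np.arange(H, dtype=float))
    px = np.stack([u.ravel(), v.ravel()], axis=-1)
    ideal = undistort_pixel(ci, px)
    Xu = (ideal[:, 0] - ci.cx) * ci.dx / ci.sx
    Yu = (ideal[:, 1] - ci.cy) * ci.dy
    dirs_cam = np.stack([Xu / ci.f, Yu / ci.f, np.ones(len(Xu))], axis=-1)
    dirs_world = dirs_cam @ cam.pose.R  # R.T applied row-wise
    return cam.pose.center, dirs_world.reshape(H, W, 3)


def _rect_left_rays(rig: StereoRig, pixels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """World origin and directions of rectified-left pixel rays (lam = z_rect)."""
    ri = rig.rect_intrinsics
    pose = rig.rect_pose("left")
    px = np.atleast_2d(np.asarray(pixels, dtype=float))
    Xu = (px[:, 0] - ri.cx) * ri.dx
    Yu = (px[:, 1] - ri.cy) * ri.dy
    dirs_rect = np.stack([Xu / ri.f, Yu / ri.f, np.ones(len(px))], axis=-1)
    dirs_world = dirs_rect @ pose.R
    return pose.center, dirs_world


def render_stereo_pair(
    params: SurfaceParams, render: RenderParams, frame: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Render one frame: (left, right, true_depth, true_disparity).

    Left/right are the *original* (distorted) camera images with seeded
    Gaussian noise added last.  ``true_depth`` (mm) and ``true_disparity``
    (px) are noise-free ground truth on the left *rectified* raster, NaN
    where the surface is not seen.
    """
    return SceneRenderer(params, render, with_truth_maps=True).frame(frame)


class SceneRenderer:
    """Renders a scene repeatedly with the per-camera rays precomputed.

    Equivalent to calling :func:`render_stereo_pair` per frame (same images,
    same ground truth) but amortizes the ray setup over a sequence.
    ``with_truth_maps=False`` skips the dense truth rasters when only the
    images and the analytic grid trajectory are needed.
    """

    def __init__(self, params: SurfaceParams, render: RenderParams,
                 with_truth_maps: bool = True,
                 rows: tuple[int, int] | None = None):
        self.params = params
        self.render = render
        self.rig = render.rig if render.rig.is_rectified else rectify(render.rig)
        self.with_truth_maps = with_truth_maps
        H = self.rig.left.intrinsics.height
        self.rows = (0, H) if rows is None else (max(rows[0], 0), min(rows[1], H))
        self._rays = []
        for cam in (self.rig.left, self.rig.right):
            o, dirs = _camera_rays(cam)
            self._rays.append((o, dirs[self.rows[0]:self.rows[1]]))
        if with_truth_maps:
            ri = self.rig.rect_intrinsics
            u, v = np.meshgrid(np.arange(ri.width, dtype=float),
                               np.arange(ri.height, dtype=float))
            px = np.stack([u.ravel(), v.ravel()], axis=-1)
            self._rect_rays = _rect_left_rays(self.rig, px)

    def frame(self, frame: int):
        """Render one frame -> (left, right, true_depth, true_disparity)."""
        rp = self.render
        H = self.rig.left.intrinsics.height
        y0, y1 = self.rows
        images = []
        any_hit = False
        for ci, (o, dirs) in enumerate(self._rays):
            lam, s, t, hit = raycast_surface(self.params, o, dirs, frame)
            band = np.full(hit.shape, rp.background, dtype=float)
            band[hit] = _texture(rp, s[hit], t[hit])
            any_hit = any_hit or bool(hit.any())
            rng = np.random.default_rng((rp.seed, frame, ci))
            if rp.noise_sd > 0:
                band = band + rng.normal(0.0, rp.noise_sd, band.shape)
            img = np.full((H,) + band.shape[1:], rp.background, dtype=float)
            img[y0:y1] = band
            images.append(np.clip(img, 0.0, 255.0))
        if not any_hit:
            raise EmptyRenderError("empty render: surface outside the field of view")
        depth = disp = None
        if self.with_truth_maps:
            ri = self.rig.rect_intrinsics
            o, dirs = self._rect_rays
            lam, s, t, hit = raycast_surface(self.params, o, dirs, frame)
            depth = np.where(hit, lam, np.nan).reshape(ri.height, ri.width)
            disp = ri.f * self.rig.baseline / (depth * ri.dx)
        return images[0], images[1], depth, disp


def ground_truth_trajectory(
    params: SurfaceParams,
    rig: StereoRig,
    roi: QuadrangleROI,
    n: int = 5,
) -> GridTrajectory:
    """Analytic trajectory of the fixed-pixel grid nodes (rectified-left mm).

    Matches the pipeline's measurement semantics exactly: each node is the
    intersection of its fixed rectified-left viewing ray with the deforming
    surface, expressed in the left rectified camera frame.
    """
    rig = rig if rig.is_rectified else rectify(rig)
    grid = make_virtual_grid(roi, n=n)
    o, dirs_world = _rect_left_rays(rig, grid.flat_nodes)
    pose = rig.rect_pose("left")
    dirs_rect = dirs_world @ pose.R.T
    pts, vld = [], []
    for f in range(params.frames):
        lam, s, t, hit = raycast_surface(params, o, dirs_world, f)
        pts.append(dirs_rect * lam[:, None])
        vld.append(hit)
    return GridTrajectory(
        points=np.stack(pts),
        valid=np.stack(vld),
        timestamps=np.arange(params.frames) / params.fps,
        n=n,
    )


# ---------------------------------------------------------------------------
# canonical scenes
# ---------------------------------------------------------------------------

def _rot_y(deg: float) -> np.ndarray:
    th = np.deg2rad(deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def default_rig(
    width: int = 640,
    height: int = 480,
    f: float = 6.0,
    pitch: float = 0.01,
    baseline: float = 12.0,
    kappa1: float = 5e-4,
    toe_in_deg: float = 1.5,
) -> StereoRig:
    """Canonical synthetic rig: left at origin, right toed in on the baseline.

    The geometry is chosen so depth quantization from integer disparity is
    ~0.2 mm at the 40 mm working depth (f*B/dx = 7200 px*mm).
    """
    intr = CameraIntrinsics(
        f=f, kappa1=kappa1, cx=(width - 1) / 2, cy=(height - 1) / 2,
        dx=pitch, dy=pitch, width=width, height=height, sx=1.0,
    )
    left = Camera(intr, CameraPose(np.eye(3), np.zeros(3)))
    Rr = _rot_y(toe_in_deg)
    Cr = np.array([baseline, 0.0, 0.0])
    right = Camera(intr, CameraPose(Rr, -Rr @ Cr))
    return rectify(StereoRig(left=left, right=right))


def default_scene(
    amplitude: float = 4.7,
    frames: int = 30,
    direction: np.ndarray = POSTERIOR_SUPERIOR,
) -> SurfaceParams:
    """The canonical single-mode scene: z0 = 40 mm, A = 4.7 mm, 30 frames."""
    return SurfaceParams(
        modes=(
            DeformationMode(direction, amplitude, rise_hold_fall(frames)),
        ),
        frames=frames,
    )


def two_mode_scene(
    amplitude1: float = 4.0,
    amplitude2: float = 2.0,
    frames: int = 30,
) -> SurfaceParams:
    """Two-mode scene: dominant posterior-upper plus weaker (orthogonalized)
    upper mode, with orthogonal equal-variance temporal harmonics so the
    PC1/PC2 eigenvalue ratio equals the squared amplitude ratio."""
    # sampling over one full discrete period makes the two harmonics exactly
    # orthogonal with equal variance, so eigenvalues scale as amplitude^2
    tau = np.arange(frames) / frames
    p1 = np.sin(np.pi * tau) ** 2
    p2 = np.sin(2 * np.pi * tau) ** 2
    return SurfaceParams(
        modes=(
            DeformationMode(POSTERIOR_SUPERIOR, amplitude1, p1),
            DeformationMode(SUPERIOR_ORTHOGONAL, amplitude2, p2),
        ),
        frames=frames,
    )


def small_scene(amplitude: float = 4.7, frames: int = 6) -> tuple[SurfaceParams, StereoRig]:
    """A small-raster variant for smoke tests and CLI examples."""
    rig = default_rig(width=160, height=120, pitch=0.04)
    params = SurfaceParams(
        modes=(DeformationMode(POSTERIOR_SUPERIOR, amplitude,
                               rise_hold_fall(frames)),),
        frames=frames,
    )
    return params, rig


def default_roi(
    params: SurfaceParams, rig: StereoRig, margin: float = 0.18
) -> QuadrangleROI:
    """ROI from the rest-frame patch corners shrunk by ``margin`` in (s, t)."""
    rig = rig if rig.is_rectified else rectify(rig)
    m = margin
    st = np.array([[m, m], [1 - m, m], [1 - m, 1 - m], [m, 1 - m]])
    world = surface_point(params, st[:, 0], st[:, 1], 0)
    px = project(rig.rect_intrinsics, rig.rect_pose("left"), world)
    return QuadrangleROI(px)


def scene_disparity_band(
    params: SurfaceParams, rig: StereoRig, slack_mm: float = 3.0
) -> tuple[int, int]:
    """(min, max) disparity search band covering the scene depth range.

    The band spans the signed z-excursion of the deformation modes, widened
    by ``slack_mm`` of depth on both sides.
    """
    rig = rig if rig.is_rectified else rectify(rig)
    dz_neg = sum(min(0.0, m.amplitude * m.direction[2]) for m in params.modes)
    dz_pos = sum(max(0.0, m.amplitude * m.direction[2]) for m in params.modes)
    zmin = max(params.z0 + dz_neg - slack_mm, 1e-3)
    zmax = params.z0 + dz_pos + slack_mm
    ri = rig.rect_intrinsics
    fb = ri.f * rig.baseline / ri.dx
    return max(int(np.floor(fb / zmax)), 0), int(np.ceil(fb / zmin))


def scene_max_disparity(params: SurfaceParams, rig: StereoRig, slack: float = 1.1) -> int:
    """Disparity search upper bound covering the scene's depth range."""
    rig = rig if rig.is_rectified else rectify(rig)
    amp = sum(m.amplitude for m in params.modes)
    zmin = max(params.z0 - amp, 1e-3)
    ri = rig.rect_intrinsics
    return int(np.ceil(slack * ri.f * rig.baseline / (zmin * ri.dx)))


# ---------------------------------------------------------------------------
# trajectory-level generators (no rendering)
# ---------------------------------------------------------------------------

def synthetic_node_trajectories(
    modes: Sequence[DeformationMode],
    frames: int = 30,
    n: int = 5,
    spacing_mm: float = 3.0,
    z0: float = 40.0,
    noise_sd: float = 0.05,
    seed: int = 0,
    weighting: str = "uniform",
    fps: float = 30.0,
) -> GridTrajectory:
    """Material-point node trajectories (mm) without the imaging chain.

    Nodes form an (n+1)^2 planar lattice at depth ``z0``; each moves by
    ``sum_m profile_m[f] * weight * amplitude_m * direction_m`` plus isotropic
    Gaussian measurement noise.  Used for statistics-level experiments where
    the optical chain is not under test.
    """
    rng = np.random.default_rng(seed)
    side = n + 1
    g = np.linspace(0, 1, side)
    S, T = np.meshgrid(g, g, indexing="ij")
    base = np.stack(
        [(S - 0.5) * n * spacing_mm, (T - 0.5) * n * spacing_mm,
         np.full_like(S, z0)], axis=-1
    ).reshape(-1, 3)
    if weighting == "uniform":
        w = np.ones(side * side)
    else:
        w = (np.sin(np.pi * S) * np.sin(np.pi * T)).ravel()
    pts = np.empty((frames, side * side, 3))
    for f in range(frames):
        p = base.copy()
        for m in modes:
            p = p + (m.profile[f] * m.amplitude) * w[:, None] * m.direction
        pts[f] = p
    pts += rng.normal(0.0, noise_sd, pts.shape)
    return GridTrajectory(
        points=pts,
        valid=np.ones(pts.shape[:2], dtype=bool),
        timestamps=np.arange(frames) / fps,
        n=n,
    )


def simulate_cohort(
    n_male: int = 10,
    n_female: int = 10,
    male_mean_shift: float = 4.74,
    female_mean_shift: float = 4.66,
    between_subject_sd: float = 0.8,
    direction_jitter_deg: float = 5.0,
    noise_sd: float = 0.05,
    frames: int = 30,
    seed: int = 0,
) -> dict[str, tuple[GridTrajectory, str]]:
    """Desk-scale cohort emulating the reported study conditions.

    Each subject gets a per-subject peak shift drawn from the group mean
    (4.74 mm males, 4.66 mm females) with between-subject SD 0.8 mm, a
    slightly jittered posterior-upper motion direction, uniform spatial
    weighting (so the peak CoG shift equals the drawn amplitude), and
    isotropic 0.05 mm measurement noise on every node sample.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, tuple[GridTrajectory, str]] = {}
    specs = [("M", male_mean_shift, n_male), ("F", female_mean_shift, n_female)]
    for label, mean, count in specs:
        for i in range(count):
            amp = max(float(rng.normal(mean, between_subject_sd)), 0.5)
            ang = np.deg2rad(rng.normal(0.0, direction_jitter_deg, 2))
            d = POSTERIOR_SUPERIOR.copy()
            # small rotations about x then z jitter the subject's direction
            cx_, sx_ = np.cos(ang[0]), np.sin(ang[0])
            cz_, sz_ = np.cos(ang[1]), np.sin(ang[1])
            Rx = np.array([[1, 0, 0], [0, cx_, -sx_], [0, sx_, cx_]])
            Rz = np.array([[cz_, -sz_, 0], [sz_, cz_, 0], [0, 0, 1]])
            d = Rz @ Rx @ d
            traj = synthetic_node_trajectories(
                [DeformationMode(d, amp, rise_hold_fall(frames))],
                frames=frames,
                noise_sd=noise_sd,
                seed=int(rng.integers(0, 2**31 - 1)),
                weighting="uniform",
            )
            out[f"{label}{i:02d}"] = (traj, label)
    return out
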