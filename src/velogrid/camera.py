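"""Tsai pinhole camera model with first-order radial distortion.

Implements the classic two-stage Tsai calibration (radial alignment constraint
followed by nonlinear refinement), forward projection through the distortion
model, closed-form undistortion, and planar stereo rectification.

Conventions
-----------
* Pixel coordinates: origin at the top-left corner, ``x`` (``u``) rightward,
  ``y`` (``v``) downward, pixel centers at integer coordinates.
* Camera frame: ``x`` right, ``y`` down, ``z`` away from the camera; a world
  point ``X`` maps to camera coordinates ``p = R @ X + T``.
* Distortion model (Tsai): the *distorted* sensor position ``(Xd, Yd)`` (mm)
  relates to the ideal pinhole position ``(Xu, Yu)`` by
  ``Xu = Xd (1 + kappa1 rd^2)``, ``rd^2 = Xd^2 + Yd^2``.  Undistortion is
  therefore closed-form and projection inverts the cubic by Newton iteration.
* All lengths in millimetres.
"""
from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
import numpy as np
import yaml
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .errors import (
    CalibrationError,
    DistortionInversionError,
    UnprojectablePointError,
)

__all__ = [
    "CameraIntrinsics",
    "CameraPose",
    "Camera",
    "StereoRig",
    "CalibrationTarget",
    "project",
    "undistort_pixel",
    "distort_pixel",
    "calibrate_tsai",
    "rectify",
    "rectification_maps",
    "load_rig",
    "save_rig",
    "load_correspondences",
]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class CameraIntrinsics:
    """Tsai intrinsic parameters.

    Parameters
    ----------
    f : effective focal length (mm).
    kappa1 : first-order radial distortion coefficient (mm^-2).
    cx, cy : image center (pixels).
    sx : horizontal scale (uncertainty) factor, dimensionless.
    dx, dy : pixel pitch (mm/pixel).
    width, height : sensor raster size (pixels).
    """

    f: float
    kappa1: float
    cx: float
    cy: float
    dx: float
    dy: float
    width: int
    height: int
    sx: float = 1.0

    def __post_init__(self) -> None:
        if not self.f > 0:
            raise ValueError("focal length must be positive")
        if not (self.dx > 0 and self.dy > 0 and self.sx > 0):
            raise ValueError("pixel pitch and scale factor must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("image center must lie inside the raster")

    @property
    def fx_px(self) -> float:
        """Focal length expressed in horizontal pixels."""
        return self.f * self.sx / self.dx

    @property
    def fy_px(self) -> float:
        """Focal length expressed in vertical pixels."""
        return self.f / self.dy


@dataclass(frozen=True)
class CameraPose:
    """World-to-camera rigid transform ``p_cam = R @ p_world + T``."""

    R: np.ndarray
    T: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float).reshape(3, 3)
        T = np.asarray(self.T, dtype=float).reshape(3)
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "T", T)
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-6:
            raise ValueError("R is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValueError("R must be a proper rotation (det = +1)")

    @property
    def center(self) -> np.ndarray:
        """Optical center in world coordinates."""
        return -self.R.T @ self.T


@dataclass(frozen=True)
class Camera:
    intrinsics: CameraIntrinsics
    pose: CameraPose


@dataclass
class StereoRig:
    """A calibrated stereo pair, optionally with rectifying rotations.

    ``rect_left`` / ``rect_right`` rotate *camera-frame* coordinates into the
    common rectified frame; ``rect_intrinsics`` is the shared distortion-free
    intrinsic model of both rectified views (taken from the left camera, with
    ``sx = 1`` and ``kappa1 = 0``).
    """

    left: Camera
    right: Camera
    rect_left: np.ndarray | None = None
    rect_right: np.ndarray | None = None
    rect_intrinsics: CameraIntrinsics | None = None

    @property
    def baseline(self) -> float:
        """Inter-camera distance (mm)."""
        b = float(
            np.linalg.norm(self.right.pose.center - self.left.pose.center)
        )
        if b <= 0:
            raise ValueError("coincident optical centers: baseline is zero")
        return b

    @property
    def is_rectified(self) -> bool:
        return self.rect_left is not None

    def rect_pose(self, which: str) -> CameraPose:
        """World-to-rectified-camera pose for ``which`` in {'left','right'}."""
        if not self.is_rectified:
            raise ValueError("rig has no rectifying rotations; call rectify()")
        cam = self.left if which == "left" else self.right
        S = self.rect_left if which == "left" else self.rect_right
        R_new = S @ cam.pose.R
        T_new = -R_new @ cam.pose.center
        return CameraPose(R_new, T_new)


@dataclass(frozen=True)
class CalibrationTarget:
    """Calibration correspondences (world mm, image px)."""

    world: np.ndarray  # (N, 3)
    image: np.ndarray  # (N, 2)

    def __post_init__(self) -> None:
        world = np.asarray(self.world, dtype=float).reshape(-1, 3)
        image = np.asarray(self.image, dtype=float).reshape(-1, 2)
        if len(world) != len(image):
            raise ValueError("world/image correspondence count mismatch")
        object.__setattr__(self, "world", world)
        object.__setattr__(self, "image", image)

    @property
    def planar(self) -> bool:
        centered = self.world - self.world.mean(axis=0)
        s = np.linalg.svd(centered, compute_uv=False)
        return bool(s[-1] < 1e-9 * max(s[0], 1.0))

    def validate(self) -> None:
        n = len(self.world)
        centered = self.world - self.world.mean(axis=0)
        s = np.linalg.svd(centered, compute_uv=False)
        if s[1] < 1e-9 * max(s[0], 1.0):
            raise CalibrationError("calibration underdetermined: collinear target")
        if self.planar and n < 7:
            raise CalibrationError("planar target needs >= 7 correspondences")
        if not self.planar and n < 11:
            raise CalibrationError("non-coplanar target needs >= 11 correspondences")


# ---------------------------------------------------------------------------
# distortion helpers
# ---------------------------------------------------------------------------

def _solve_rd(ru: np.ndarray, kappa1: float, max_iter: int = 50) -> np.ndarray:
    """Solve ``rd + kappa1 rd^3 = ru`` for ``rd >= 0`` by Newton iteration."""
    ru = np.asarray(ru, dtype=float)
    if kappa1 == 0.0:
        return ru.copy()
    rd = ru.copy()
    for _ in range(max_iter):
        g = rd + kappa1 * rd**3 - ru
        gp = 1.0 + 3.0 * kappa1 * rd**2
        step = g / gp
        rd = rd - step
        if np.max(np.abs(step)) < 1e-13:
            break
    else:
        raise DistortionInversionError("distortion inversion failed")
    if not np.all(np.isfinite(rd)):
        raise DistortionInversionError("distortion inversion failed")
    return rd


def _distort_sensor(
    intr: CameraIntrinsics, Xu: np.ndarray, Yu: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Map ideal sensor coords (mm) to distorted sensor coords (mm)."""
    ru = np.hypot(Xu, Yu)
    rd = _solve_rd(ru, intr.kappa1)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(ru > 0, rd / np.where(ru > 0, ru, 1.0), 1.0)
    return Xu * scale, Yu * scale


def project(
    intrinsics: CameraIntrinsics, pose: CameraPose, world_point: np.ndarray
) -> np.ndarray:
    """Project world point(s) (mm) to distorted pixel coordinates.

    Rigid transform -> perspective divide -> radial distortion -> pixel map.
    With ``kappa1 = 0`` this is the ideal pinhole projection.

    Raises
    ------
    UnprojectablePointError
        if any point has camera-frame depth ``z <= 0``.
    """
    pts = np.asarray(world_point, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    cam = pts @ pose.R.T + pose.T
    z = cam[:, 2]
    if np.any(z <= 0):
        raise UnprojectablePointError("unprojectable point: z <= 0 in camera frame")
    Xu = intrinsics.f * cam[:, 0] / z
    Yu = intrinsics.f * cam[:, 1] / z
    Xd, Yd = _distort_sensor(intrinsics, Xu, Yu)
    u = intrinsics.sx * Xd / intrinsics.dx + intrinsics.cx
    v = Yd / intrinsics.dy + intrinsics.cy
    px = np.stack([u, v], axis=-1)
    return px[0] if single else px


def undistort_pixel(intrinsics: CameraIntrinsics, pixel: np.ndarray) -> np.ndarray:
    """Map distorted pixel(s) to the ideal (pinhole) pixel position.

    Closed form under the Tsai model: the undistorted sensor position is
    ``(Xd, Yd) * (1 + kappa1 rd^2)``.  With ``kappa1 = 0`` this is the
    identity, and the image center maps to itself for any ``kappa1``.
    """
    px = np.asarray(pixel, dtype=float)
    single = px.ndim == 1
    px = np.atleast_2d(px)
    Xd = (px[:, 0] - intrinsics.cx) * intrinsics.dx / intrinsics.sx
    Yd = (px[:, 1] - intrinsics.cy) * intrinsics.dy
    factor = 1.0 + intrinsics.kappa1 * (Xd**2 + Yd**2)
    Xu = Xd * factor
    Yu = Yd * factor
    u = intrinsics.sx * Xu / intrinsics.dx + intrinsics.cx
    v = Yu / intrinsics.dy + intrinsics.cy
    out = np.stack([u, v], axis=-1)
    return out[0] if single else out


def distort_pixel(intrinsics: CameraIntrinsics, pixel: np.ndarray) -> np.ndarray:
    """Inverse of :func:`undistort_pixel`: ideal pixel -> distorted pixel."""
    px = np.asarray(pixel, dtype=float)
    single = px.ndim == 1
    px = np.atleast_2d(px)
    Xu = (px[:, 0] - intrinsics.cx) * intrinsics.dx / intrinsics.sx
    Yu = (px[:, 1] - intrinsics.cy) * intrinsics.dy
    Xd, Yd = _distort_sensor(intrinsics, Xu, Yu)
    u = intrinsics.sx * Xd / intrinsics.dx + intrinsics.cx
    v = Yd / intrinsics.dy + intrinsics.cy
    out = np.stack([u, v], axis=-1)
    return out[0] if single else out


# ---------------------------------------------------------------------------
# Tsai calibration
# ---------------------------------------------------------------------------

def _orthonormalize(R: np.ndarray) -> np.ndarray:
    U, _, Vt = np.linalg.svd(R)
    R2 = U @ Vt
    if np.linalg.det(R2) < 0:
        U[:, -1] *= -1
        R2 = U @ Vt
    return R2


def _sensor_coords(
    intr: CameraIntrinsics, image: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    Xd = (image[:, 0] - intr.cx) * intr.dx / intr.sx
    Yd = (image[:, 1] - intr.cy) * intr.dy
    return Xd, Yd


def _stage1_noncoplanar(world, Xd, Yd):
    A = np.column_stack(
        [
            Yd * world[:, 0],
            Yd * world[:, 1],
            Yd * world[:, 2],
            Yd,
            -Xd * world[:, 0],
            -Xd * world[:, 1],
            -Xd * world[:, 2],
        ]
    )
    a, *_ = np.linalg.lstsq(A, Xd, rcond=None)
    row2_scaled = a[4:7]
    norm2 = np.linalg.norm(row2_scaled)
    if norm2 < 1e-12:
        raise CalibrationError("calibration underdetermined")
    Ty_abs = 1.0 / norm2
    candidates = []
    for Ty in (Ty_abs, -Ty_abs):
        r1 = a[0:3] * Ty
        Tx = a[3] * Ty
        r2 = a[4:7] * Ty
        # sign check: predicted sensor coords must match observed quadrant
        i = int(np.argmax(Xd**2 + Yd**2))
        x = r1 @ world[i] + Tx
        y = r2 @ world[i] + Ty
        if x * Xd[i] >= 0 and y * Yd[i] >= 0:
            r3 = np.cross(r1, r2)
            R = _orthonormalize(np.vstack([r1, r2, r3]))
            candidates.append((R, Tx, Ty))
    if not candidates:
        raise CalibrationError("radial alignment stage failed")
    return candidates


def _stage1_planar(world, Xd, Yd):
    A = np.column_stack(
        [Yd * world[:, 0], Yd * world[:, 1], Yd, -Xd * world[:, 0], -Xd * world[:, 1]]
    )
    a, *_ = np.linalg.lstsq(A, Xd, rcond=None)
    r1p, r2p, txp, r4p, r5p = a
    S = r1p**2 + r2p**2 + r4p**2 + r5p**2
    det = r1p * r5p - r4p * r2p
    if abs(det) > 1e-12:
        Ty2 = (S - np.sqrt(max(S * S - 4 * det * det, 0.0))) / (2 * det * det)
    else:
        Ty2 = 1.0 / S
    Ty_abs = float(np.sqrt(Ty2))
    candidates = []
    for Ty in (Ty_abs, -Ty_abs):
        r1a, r2a = r1p * Ty, r2p * Ty
        r4a, r5a = r4p * Ty, r5p * Ty
        Tx = txp * Ty
        i = int(np.argmax(Xd**2 + Yd**2))
        x = r1a * world[i, 0] + r2a * world[i, 1] + Tx
        y = r4a * world[i, 0] + r5a * world[i, 1] + Ty
        if not (x * Xd[i] >= 0 and y * Yd[i] >= 0):
            continue
        r3a = np.sqrt(max(1.0 - r1a**2 - r2a**2, 0.0))
        r6mag = np.sqrt(max(1.0 - r4a**2 - r5a**2, 0.0))
        # orthogonality of the two rows fixes the relative sign of r3, r6
        for s3 in (1.0, -1.0):
            r3 = s3 * r3a
            s6 = -np.sign(r1a * r4a + r2a * r5a) * s3 if r3a > 1e-12 else 1.0
            r6 = s6 * r6mag
            row1 = np.array([r1a, r2a, r3])
            row2 = np.array([r4a, r5a, r6])
            row3 = np.cross(row1, row2)
            R = _orthonormalize(np.vstack([row1, row2, row3]))
            candidates.append((R, Tx, Ty))
    if not candidates:
        raise CalibrationError("radial alignment stage failed")
    return candidates


def _linear_f_tz(world, Yd, R, Ty):
    y = world @ R[1] + Ty
    w = world @ R[2]
    A = np.column_stack([y, -Yd])
    b = Yd * w
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return float(sol[0]), float(sol[1])


def calibrate_tsai(
    target: CalibrationTarget, intrinsics_init: CameraIntrinsics
) -> tuple[CameraIntrinsics, CameraPose]:
    """Two-stage Tsai calibration from world/image correspondences.

    Stage 1 solves the radial alignment constraint (linear, distortion-free)
    for the rotation and the in-plane translation; stage 2 initializes
    ``f, Tz`` linearly and then refines ``R, T, f, kappa1`` jointly by
    Levenberg–Marquardt on the reprojection residual.  ``cx, cy, sx, dx, dy``
    are taken from ``intrinsics_init`` and held fixed, per the classic model.

    Returns the refined intrinsics and pose minimizing reprojection RMS.
    """
    target.validate()
    world, image = target.world, target.image
    Xd, Yd = _sensor_coords(intrinsics_init, image)

    if target.planar:
        stage1 = _stage1_planar(world, Xd, Yd)
    else:
        stage1 = _stage1_noncoplanar(world, Xd, Yd)

    def residual(p):
        rot = Rotation.from_rotvec(p[0:3]).as_matrix()
        T = p[3:6]
        f, kappa1 = p[6], p[7]
        cam = world @ rot.T + T
        z = cam[:, 2]
        if np.any(z <= 1e-9) or f <= 0:
            return np.full(2 * len(world), 1e6)
        Xu = f * cam[:, 0] / z
        Yu = f * cam[:, 1] / z
        try:
            Xd_p, Yd_p = _distort_sensor(
                replace(intrinsics_init, f=f, kappa1=kappa1), Xu, Yu
            )
        except DistortionInversionError:
            return np.full(2 * len(world), 1e6)
        return np.concatenate([(Xd_p - Xd) / intrinsics_init.dx,
                               (Yd_p - Yd) / intrinsics_init.dy])

    best = None
    for R0, Tx, Ty in stage1:
        f0, Tz0 = _linear_f_tz(world, Yd, R0, Ty)
        if f0 <= 0 or Tz0 <= 0:
            continue
        p0 = np.concatenate(
            [Rotation.from_matrix(R0).as_rotvec(), [Tx, Ty, Tz0], [f0, 0.0]]
        )
        sol = least_squares(
            residual, p0, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14,
            max_nfev=200 * len(p0),
        )
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise CalibrationError("calibration failed: no admissible initialization")

    p = best.x
    R = _orthonormalize(Rotation.from_rotvec(p[0:3]).as_matrix())
    pose = CameraPose(R, p[3:6])
    intr = replace(intrinsics_init, f=float(p[6]), kappa1=float(p[7]))
    return intr, pose


def reprojection_rms(
    intr: CameraIntrinsics, pose: CameraPose, target: CalibrationTarget
) -> float:
    """Root-mean-square reprojection error (px) over the correspondences."""
    pred = project(intr, pose, target.world)
    return float(np.sqrt(np.mean(np.sum((pred - target.image) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# rectification
# ---------------------------------------------------------------------------

def rectify(rig: StereoRig) -> StereoRig:
    """Compute rectifying rotations so epipolar lines become image rows.

    Uses the standard construction: the new (shared) camera orientation has
    its x-axis along the baseline, its y-axis orthogonal to the baseline and
    to the old left optical axis, and its z-axis completing the frame.  For a
    fronto-parallel rig with baseline along +x this reduces to the identity.
    Both rectified views share the left camera's focal length and pixel pitch
    with ``kappa1 = 0``.
    """
    Cl = rig.left.pose.center
    Cr = rig.right.pose.center
    b = Cr - Cl
    B = np.linalg.norm(b)
    if B <= 0:
        raise ValueError("optical centers coincide; cannot rectify")
    r1 = b / B
    # keep the baseline direction consistent with the left camera's +x axis
    if r1 @ rig.left.pose.R[0] < 0:
        warnings.warn("baseline opposes left camera x-axis; disparity sign may flip")
    z_old = rig.left.pose.R[2]  # left optical axis in world coords
    r2 = np.cross(z_old, r1)
    n2 = np.linalg.norm(r2)
    if n2 < 1e-12:
        raise ValueError("degenerate rig: baseline parallel to optical axis")
    r2 /= n2
    r3 = np.cross(r1, r2)
    R_rect_world = np.vstack([r1, r2, r3])

    S_l = R_rect_world @ rig.left.pose.R.T
    S_r = R_rect_world @ rig.right.pose.R.T
    li = rig.left.intrinsics
    rect_intr = replace(li, kappa1=0.0, sx=1.0)
    return StereoRig(
        left=rig.left,
        right=rig.right,
        rect_left=S_l,
        rect_right=S_r,
        rect_intrinsics=rect_intr,
    )


def rectification_maps(rig: StereoRig, which: str) -> np.ndarray:
    """Source-pixel sampling map for warping one view into the rectified frame.

    Returns an ``(H, W, 2)`` array giving, for every rectified pixel, the
    (u, v) position in the *original* (distorted) image to sample.  Pixels
    whose rectified ray points behind the original camera get NaN.
    """
    if not rig.is_rectified:
        raise ValueError("call rectify() first")
    cam = rig.left if which == "left" else rig.right
    S = rig.rect_left if which == "left" else rig.rect_right
    ri = rig.rect_intrinsics
    H, W = ri.height, ri.width
    u, v = np.meshgrid(np.arange(W, dtype=float), np.arange(H, dtype=float))
    Xu = (u - ri.cx) * ri.dx
    Yu = (v - ri.cy) * ri.dy
    dirs = np.stack([Xu / ri.f, Yu / ri.f, np.ones_like(Xu)], axis=-1)
    cam_dirs = dirs @ S  # S.T applied to each vector: (d @ S) == S.T d per row
    z = cam_dirs[..., 2]
    good = z > 1e-9
    ci = cam.intrinsics
    with np.errstate(invalid="ignore", divide="ignore"):
        Xu_c = ci.f * cam_dirs[..., 0] / z
        Yu_c = ci.f * cam_dirs[..., 1] / z
    Xd, Yd = _distort_sensor(ci, np.where(good, Xu_c, 0.0), np.where(good, Yu_c, 0.0))
    su = ci.sx * Xd / ci.dx + ci.cx
    sv = Yd / ci.dy + ci.cy
    out = np.stack([su, sv], axis=-1)
    out[~good] = np.nan
    return out


def warp_to_rectified(rig: StereoRig, image: np.ndarray, which: str) -> np.ndarray:
    """Bilinearly resample ``image`` into the rectified frame of ``which``."""
    from scipy.ndimage import map_coordinates

    m = rectification_maps(rig, which)
    coords = np.stack([m[..., 1].ravel(), m[..., 0].ravel()])
    coords = np.nan_to_num(coords, nan=-1e6)
    out = map_coordinates(
        image.astype(float), coords, order=1, mode="constant", cval=0.0
    )
    return out.reshape(m.shape[:2])


# ---------------------------------------------------------------------------
# config I/O
# ---------------------------------------------------------------------------

def _camera_to_dict(cam: Camera) -> dict:
    i = cam.intrinsics
    return {
        "f": i.f, "kappa1": i.kappa1, "cx": i.cx, "cy": i.cy, "sx": i.sx,
        "dx": i.dx, "dy": i.dy, "width": i.width, "height": i.height,
        "R": [float(x) for x in cam.pose.R.ravel()],
        "T": [float(x) for x in cam.pose.T],
    }


def _camera_from_dict(d: dict) -> Camera:
    intr = CameraIntrinsics(
        f=float(d["f"]), kappa1=float(d.get("kappa1", 0.0)),
        cx=float(d["cx"]), cy=float(d["cy"]), sx=float(d.get("sx", 1.0)),
        dx=float(d["dx"]), dy=float(d["dy"]),
        width=int(d["width"]), height=int(d["height"]),
    )
    pose = CameraPose(np.array(d["R"], dtype=float).reshape(3, 3),
                      np.array(d["T"], dtype=float))
    return Camera(intr, pose)


def save_rig(rig: StereoRig, path: str | Path) -> None:
    """Persist a stereo rig to YAML (or JSON, by extension)."""
    data = {"left": _camera_to_dict(rig.left), "right": _camera_to_dict(rig.right)}
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data))


def load_rig(path: str | Path) -> StereoRig:
    """Load a stereo rig from a YAML/JSON calibration config."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return StereoRig(left=_camera_from_dict(data["left"]),
                     right=_camera_from_dict(data["right"]))


def load_correspondences(path: str | Path) -> CalibrationTarget:
    """Read a calibration-target table (CSV columns X,Y,Z,u,v)."""
    world, image = [], []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            world.append([float(row["X"]), float(row["Y"]), float(row["Z"])])
            image.append([float(row["u"]), float(row["v"])])
    return CalibrationTarget(np.array(world), np.array(image))
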