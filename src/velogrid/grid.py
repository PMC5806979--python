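"""Virtual-grid parameterization of a landmark-free surface patch.

Because the velopharynx offers no reliable anatomical landmarks, a
quadrangle ROI is drawn on the soft palate in the reference frame and divided
equally into an n x n grid (n = 5 gives the standard 36 intersections).  The
grid is defined once in image coordinates and held fixed; each frame's 3D
samples are taken from the range image at those pixel positions, so the
trajectory measures apparent surface motion along the fixed viewing rays.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyFrameError, GridOutOfBoundsError, InvalidROIError
from .ranging import RangeImage, RangeSequence

__all__ = [
    "QuadrangleROI",
    "VirtualGrid",
    "GridTrajectory",
    "CoGTrajectory",
    "make_virtual_grid",
    "sample_grid_3d",
    "build_grid_trajectory",
    "grid_centroid",
    "cog_trajectory",
    "cog_shift",
    "load_roi",
    "save_roi",
]

log = logging.getLogger(__name__)


def _canonical_corners(corners: np.ndarray) -> np.ndarray:
    """Order corners TL, TR, BR, BL by angular sort around the centroid.

    In image coordinates (y down) ascending ``atan2`` angle runs
    right -> down -> left -> up, i.e. clockwise on screen; sorting from the
    upper-left diagonal direction yields the canonical order.
    """
    c = corners.mean(axis=0)
    ang = np.arctan2(corners[:, 1] - c[1], corners[:, 0] - c[0])
    return corners[np.argsort(ang)]


@dataclass(frozen=True)
class QuadrangleROI:
    """Four ordered pixel corners (TL, TR, BR, BL) on the reference frame."""

    corners: np.ndarray
    reference_frame: int = 0

    def __post_init__(self) -> None:
        corners = np.asarray(self.corners, dtype=float).reshape(4, 2)
        corners = _canonical_corners(corners)
        object.__setattr__(self, "corners", corners)
        # convexity/simplicity: consecutive edge cross products share sign
        e = np.roll(corners, -1, axis=0) - corners
        nxt = np.roll(e, -1, axis=0)
        cross = e[:, 0] * nxt[:, 1] - e[:, 1] * nxt[:, 0]
        if not (np.all(cross > 1e-12) or np.all(cross < -1e-12)):
            raise InvalidROIError("invalid ROI: corners not strictly convex")
        area = 0.5 * abs(
            np.sum(corners[:, 0] * np.roll(corners[:, 1], -1)
                   - np.roll(corners[:, 0], -1) * corners[:, 1])
        )
        if area <= 1e-9:
            raise InvalidROIError("invalid ROI: degenerate quadrangle")


@dataclass(frozen=True)
class VirtualGrid:
    """(n+1) x (n+1) pixel node lattice from equal bilinear subdivision."""

    n: int
    nodes: np.ndarray  # (n+1, n+1, 2), row-major from top-left

    @property
    def n_nodes(self) -> int:
        return (self.n + 1) ** 2

    @property
    def flat_nodes(self) -> np.ndarray:
        return self.nodes.reshape(-1, 2)


@dataclass
class GridTrajectory:
    """Per-frame 3D samples (mm) of the grid nodes, row-major node order."""

    points: np.ndarray  # (T, N, 3)
    valid: np.ndarray  # (T, N) bool
    timestamps: np.ndarray  # (T,)
    n: int = 5

    @property
    def n_frames(self) -> int:
        return self.points.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.points.shape[1]


@dataclass
class CoGTrajectory:
    """Centroid time series and displacement magnitudes from rest."""

    centroids: np.ndarray  # (T, 3)
    shifts: np.ndarray  # (T,)
    rest_frame: int = 0
    timestamps: np.ndarray | None = None


def make_virtual_grid(roi: QuadrangleROI, n: int = 5) -> VirtualGrid:
    """Divide the quadrangle equally into an n x n grid of (n+1)^2 nodes.

    Node (i, j) is the bilinear blend of the four corners at parameters
    (i/n, j/n); for n = 5 this yields the 36 grid intersections.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    tl, tr, br, bl = roi.corners
    s = np.linspace(0.0, 1.0, n + 1)  # vertical parameter (rows)
    t = np.linspace(0.0, 1.0, n + 1)  # horizontal parameter (cols)
    S, T = np.meshgrid(s, t, indexing="ij")
    nodes = (
        (1 - S)[..., None] * ((1 - T)[..., None] * tl + T[..., None] * tr)
        + S[..., None] * ((1 - T)[..., None] * bl + T[..., None] * br)
    )
    return VirtualGrid(n=n, nodes=nodes)


def sample_grid_3d(
    range_image: RangeImage, grid: VirtualGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the range image at the grid nodes by bilinear interpolation.

    Interpolation runs over the valid pixels of each node's 2x2 neighborhood
    with renormalized bilinear weights; a node is invalid when fewer than two
    of its four neighbors are valid.

    Returns ``(points, valid)`` with shapes ``(N, 3)`` and ``(N,)``.
    """
    H, W = range_image.valid.shape
    nodes = grid.flat_nodes
    if np.any(nodes[:, 0] < 0) or np.any(nodes[:, 0] > W - 1) or np.any(
        nodes[:, 1] < 0
    ) or np.any(nodes[:, 1] > H - 1):
        raise GridOutOfBoundsError("grid out of bounds for the image raster")
    x0 = np.clip(np.floor(nodes[:, 0]).astype(int), 0, W - 2)
    y0 = np.clip(np.floor(nodes[:, 1]).astype(int), 0, H - 2)
    fx = nodes[:, 0] - x0
    fy = nodes[:, 1] - y0
    # 2x2 neighborhood weights (bilinear)
    wts = np.stack(
        [(1 - fx) * (1 - fy), fx * (1 - fy), (1 - fx) * fy, fx * fy], axis=1
    )
    pts = np.stack(
        [
            range_image.points[y0, x0],
            range_image.points[y0, x0 + 1],
            range_image.points[y0 + 1, x0],
            range_image.points[y0 + 1, x0 + 1],
        ],
        axis=1,
    )  # (N, 4, 3)
    vals = np.stack(
        [
            range_image.valid[y0, x0],
            range_image.valid[y0, x0 + 1],
            range_image.valid[y0 + 1, x0],
            range_image.valid[y0 + 1, x0 + 1],
        ],
        axis=1,
    )  # (N, 4)
    w = wts * vals
    wsum = w.sum(axis=1)
    node_valid = (vals.sum(axis=1) >= 2) & (wsum > 1e-12)
    with np.errstate(invalid="ignore", divide="ignore"):
        points = np.einsum("nk,nkc->nc", w, np.nan_to_num(pts)) / wsum[:, None]
    points[~node_valid] = np.nan
    return points, node_valid


def build_grid_trajectory(
    sequence: RangeSequence, grid: VirtualGrid, fill: bool = True
) -> GridTrajectory:
    """Sample every frame at the fixed grid nodes and assemble a trajectory.

    With ``fill=True`` an invalid node sample is replaced by the same node's
    nearest valid frame in time; a node that is valid in no frame remains
    invalid throughout (downstream analysis drops it, with a log message).
    """
    pts, vld, ts = [], [], []
    for im in sequence:
        p, v = sample_grid_3d(im, grid)
        pts.append(p)
        vld.append(v)
        ts.append(im.timestamp)
    points = np.stack(pts)
    valid = np.stack(vld)
    if fill and points.size:
        T = points.shape[0]
        for node in range(points.shape[1]):
            good = np.flatnonzero(valid[:, node])
            if good.size == 0:
                log.warning("grid node %d valid in no frame; dropped downstream", node)
                continue
            if good.size < T:
                missing = np.flatnonzero(~valid[:, node])
                nearest = good[np.argmin(np.abs(missing[:, None] - good[None, :]), axis=1)]
                points[missing, node] = points[nearest, node]
                valid[missing, node] = True
    return GridTrajectory(points=points, valid=valid, timestamps=np.asarray(ts),
                          n=grid.n)


def grid_centroid(points: np.ndarray, valid: np.ndarray | None = None) -> np.ndarray:
    """Unweighted mean (center of gravity) of the valid grid nodes."""
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if valid is None:
        valid = np.ones(len(points), dtype=bool)
    valid = np.asarray(valid, dtype=bool).reshape(-1)
    if not valid.any():
        raise EmptyFrameError("empty frame: no valid grid node")
    return points[valid].mean(axis=0)


def cog_trajectory(traj: GridTrajectory, rest_frame: int = 0) -> CoGTrajectory:
    """Centroid per frame and Euclidean displacement from the rest frame."""
    if traj.n_frames < 1:
        raise EmptyFrameError("empty trajectory")
    cents = np.stack(
        [grid_centroid(traj.points[t], traj.valid[t]) for t in range(traj.n_frames)]
    )
    shifts = np.linalg.norm(cents - cents[rest_frame], axis=1)
    return CoGTrajectory(centroids=cents, shifts=shifts, rest_frame=rest_frame,
                         timestamps=traj.timestamps)


def cog_shift(traj: CoGTrajectory | GridTrajectory, rest_frame: int | None = None) -> float:
    """Maximum centroid displacement (mm) from the rest frame."""
    if isinstance(traj, GridTrajectory):
        traj = cog_trajectory(traj, rest_frame=rest_frame or 0)
    elif rest_frame is not None and rest_frame != traj.rest_frame:
        traj = CoGTrajectory(
            centroids=traj.centroids,
            shifts=np.linalg.norm(traj.centroids - traj.centroids[rest_frame], axis=1),
            rest_frame=rest_frame,
            timestamps=traj.timestamps,
        )
    if len(traj.shifts) < 2:
        raise ValueError("need at least 2 frames to measure a shift")
    return float(traj.shifts.max())


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_roi(roi: QuadrangleROI, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {"corners": roi.corners.tolist(), "reference_frame": roi.reference_frame}
        )
    )


def load_roi(path: str | Path) -> QuadrangleROI:
    d = json.loads(Path(path).read_text())
    return QuadrangleROI(np.array(d["corners"]), d.get("reference_frame", 0))


def trajectory_to_frame(traj: GridTrajectory) -> pd.DataFrame:
    """Tidy export: one row per (frame, node) with mm coordinates."""
    T, N, _ = traj.points.shape
    side = traj.n + 1
    frames = np.repeat(np.arange(T), N)
    nodes = np.tile(np.arange(N), T)
    return pd.DataFrame(
        {
            "frame": frames,
            "node_row": nodes // side,
            "node_col": nodes % side,
            "x_mm": traj.points[:, :, 0].ravel(),
            "y_mm": traj.points[:, :, 1].ravel(),
            "z_mm": traj.points[:, :, 2].ravel(),
            "valid": traj.valid.ravel(),
        }
    )


def trajectory_from_frame(df: pd.DataFrame, fps: float = 30.0) -> GridTrajectory:
    """Inverse of :func:`trajectory_to_frame`."""
    T = int(df["frame"].max()) + 1
    side = int(df["node_row"].max()) + 1
    N = side * side
    df = df.sort_values(["frame", "node_row", "node_col"])
    points = df[["x_mm", "y_mm", "z_mm"]].to_numpy().reshape(T, N, 3)
    valid = df["valid"].to_numpy(dtype=bool).reshape(T, N)
    return GridTrajectory(points=points, valid=valid,
                          timestamps=np.arange(T) / fps, n=side - 1)
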