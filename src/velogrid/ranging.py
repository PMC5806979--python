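"""Range-image production: video splitting, deinterlacing, triangulation.

Captured composite stereo video is split into per-camera sequences,
deinterlaced to full vertical resolution by linear interpolation, rectified,
matched, and triangulated into per-frame range images whose pixels carry 3D
coordinates (mm) in the left rectified camera frame (x right, y down,
z away from the camera).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .camera import StereoRig, warp_to_rectified
from .errors import (
    UnknownPackingError,
    UnrectifiedInputError,
    UnsynchronizedSequencesError,
)
from .matching import DisparityMap, MatchParams, compute_disparity_map

__all__ = [
    "VideoSequence",
    "RangeImage",
    "RangeSequence",
    "split_stereo_video",
    "deinterlace",
    "disparity_to_range",
    "build_range_sequence",
    "WORKING_RANGE_MM",
]

log = logging.getLogger(__name__)

#: Validated working envelope of the endoscopic system (mm from the tip).
WORKING_RANGE_MM = (20.0, 60.0)


@dataclass
class VideoSequence:
    frames: list[np.ndarray]
    fps: float = 30.0
    camera: str = "left"

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        shapes = {f.shape for f in self.frames}
        if len(shapes) > 1:
            raise ValueError("all frames must share one shape")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class RangeImage:
    """Per-pixel 3D coordinates (mm) in the left rectified camera frame."""

    points: np.ndarray  # (H, W, 3)
    valid: np.ndarray  # (H, W) bool
    frame_index: int = 0
    timestamp: float = 0.0


@dataclass
class RangeSequence:
    images: list[RangeImage] = field(default_factory=list)
    rig: StereoRig | None = None

    def __post_init__(self) -> None:
        idx = [im.frame_index for im in self.images]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("frame_index must be strictly increasing")

    def __len__(self) -> int:
        return len(self.images)

    def __iter__(self):
        return iter(self.images)


def split_stereo_video(
    composite_frames: list[np.ndarray],
    packing: str = "side_by_side",
    fps: float = 30.0,
) -> tuple[VideoSequence, VideoSequence]:
    """Separate composite stereo frames into left and right sequences.

    ``packing='side_by_side'`` splits each frame at half width (left half is
    the left camera); ``'over_under'`` splits at half height (top half left).
    """
    left, right = [], []
    for frame in composite_frames:
        if packing == "side_by_side":
            if frame.shape[1] % 2:
                raise UnknownPackingError("unknown packing: odd composite width")
            w = frame.shape[1] // 2
            left.append(frame[:, :w].copy())
            right.append(frame[:, w:].copy())
        elif packing == "over_under":
            if frame.shape[0] % 2:
                raise UnknownPackingError("unknown packing: odd composite height")
            h = frame.shape[0] // 2
            left.append(frame[:h].copy())
            right.append(frame[h:].copy())
        else:
            raise UnknownPackingError(f"unknown packing: {packing!r}")
    return (
        VideoSequence(left, fps=fps, camera="left"),
        VideoSequence(right, fps=fps, camera="right"),
    )


def deinterlace(frame: np.ndarray) -> np.ndarray:
    """Double the vertical resolution by linear interpolation.

    The stored field occupies the even output rows; each missing (odd) row is
    the arithmetic mean of its vertical neighbors, and the bottom boundary row
    is replicated from the row above.
    """
    frame = np.asarray(frame, dtype=float)
    h, w = frame.shape[:2]
    out_shape = (2 * h, w) + frame.shape[2:]
    out = np.empty(out_shape, dtype=float)
    out[0::2] = frame
    out[1:-1:2] = 0.5 * (frame[:-1] + frame[1:])
    out[-1] = frame[-1]
    return out


def disparity_to_range(
    disparity: DisparityMap, rig: StereoRig, frame_index: int = 0, fps: float = 30.0
) -> RangeImage:
    """Triangulate a disparity map on the rectified rig.

    For valid pixels ``z = f*B / (d*dx)`` (equivalently ``f_px * B / d``),
    ``x = (u - cx) z dx / f``, ``y = (v - cy) z dy / f``.  Pixels with
    ``d <= 0`` marked valid are masked invalid (count logged).
    """
    if not rig.is_rectified:
        raise ValueError("rig must be rectified before triangulation")
    ri = rig.rect_intrinsics
    B = rig.baseline
    d = disparity.values
    valid = disparity.valid.copy()
    bad = valid & ~(d > 0)
    if bad.any():
        log.warning("masking %d pixels with non-positive disparity", int(bad.sum()))
        valid &= d > 0
    H, W = d.shape
    u, v = np.meshgrid(np.arange(W, dtype=float), np.arange(H, dtype=float))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = ri.f * B / (d * ri.dx)
    z = np.where(valid, z, np.nan)
    x = (u - ri.cx) * z * ri.dx / ri.f
    y = (v - ri.cy) * z * ri.dy / ri.f
    points = np.stack([x, y, z], axis=-1)
    med = np.nanmedian(z) if valid.any() else np.nan
    if np.isfinite(med) and not (WORKING_RANGE_MM[0] <= med <= WORKING_RANGE_MM[1]):
        warnings.warn(
            f"median depth {med:.1f} mm outside the validated working range "
            f"{WORKING_RANGE_MM[0]:.0f}-{WORKING_RANGE_MM[1]:.0f} mm"
        )
    return RangeImage(points=points, valid=valid, frame_index=frame_index,
                      timestamp=frame_index / fps)


def build_range_sequence(
    left_seq: VideoSequence,
    right_seq: VideoSequence,
    rig: StereoRig,
    params: MatchParams,
    rectified_input: bool = False,
) -> RangeSequence:
    """Rectify, match, and triangulate every synchronized frame pair.

    Set ``rectified_input=True`` when the frames are already in the rectified
    geometry (e.g. rendered there) to skip the warp.
    """
    if len(left_seq) != len(right_seq):
        raise UnsynchronizedSequencesError(
            f"unsynchronized sequences: {len(left_seq)} vs {len(right_seq)} frames"
        )
    if not rig.is_rectified:
        raise ValueError("rig must carry rectifying rotations")
    images = []
    for k, (lf, rf) in enumerate(zip(left_seq.frames, right_seq.frames)):
        if lf.shape != rf.shape:
            raise UnrectifiedInputError("unrectified input: frame shapes differ")
        if rectified_input:
            lw, rw = np.asarray(lf, dtype=float), np.asarray(rf, dtype=float)
        else:
            lw = warp_to_rectified(rig, lf, "left")
            rw = warp_to_rectified(rig, rf, "right")
        disp = compute_disparity_map(lw, rw, params)
        images.append(disparity_to_range(disp, rig, frame_index=k, fps=left_seq.fps))
    return RangeSequence(images=images, rig=rig)
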