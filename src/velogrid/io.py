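"""Raster and table I/O: PFM float rasters, PNG images, sequence manifests.

PFM (portable float map) stores range/disparity rasters losslessly as text
header + little-endian float32 payload; validity masks ride along as PNG.
"""
from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["write_pfm", "read_pfm", "write_png", "read_png",
           "write_manifest", "read_manifest"]


def write_pfm(path: str | Path, data: np.ndarray) -> None:
    """Write a 1- or 3-channel float32 raster as PFM (scale -1, little endian).

    PFM stores rows bottom-to-top; this writer flips accordingly.
    """
    data = np.asarray(data, dtype=np.float32)
    if data.ndim == 2:
        header = "Pf"
    elif data.ndim == 3 and data.shape[2] == 3:
        header = "PF"
    else:
        raise ValueError("PFM supports HxW or HxWx3 rasters")
    h, w = data.shape[:2]
    with open(path, "wb") as fh:
        fh.write(f"{header}\n{w} {h}\n-1.0\n".encode("ascii"))
        fh.write(np.flipud(data).tobytes())


def read_pfm(path: str | Path) -> np.ndarray:
    with open(path, "rb") as fh:
        header = fh.readline().strip().decode("ascii")
        if header not in ("Pf", "PF"):
            raise ValueError(f"not a PFM file: {path}")
        w, h = map(int, fh.readline().split())
        scale = float(fh.readline())
        count = w * h * (3 if header == "PF" else 1)
        data = np.frombuffer(fh.read(count * 4),
                             dtype="<f4" if scale < 0 else ">f4", count=count)
    shape = (h, w, 3) if header == "PF" else (h, w)
    return np.flipud(data.reshape(shape)).copy()


def write_png(path: str | Path, image: np.ndarray) -> None:
    img = np.asarray(image)
    if img.dtype == bool:
        img = img.astype(np.uint8) * 255
    elif img.dtype != np.uint8:
        img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), img)


def read_png(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path)))


def write_manifest(path: str | Path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
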