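"""Reading and writing of images and sinograms.

Grayscale rasters travel as 8-bit PNG/TIFF; sinograms as 32-bit float TIFF
with a JSON sidecar carrying the acquisition configuration.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile


def read_gray(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale image as a float array in [0, 255]."""
    img = iio.imread(path)
    if img.ndim == 3:  # collapse RGB(A) written by other tools
        img = img[..., :3].mean(axis=-1)
    return np.asarray(img, dtype=float)


def write_gray(path: str | Path, image: np.ndarray) -> None:
    """Write a [0, 255] float image as 8-bit PNG/TIFF (rounded, clipped)."""
    arr = np.clip(np.rint(np.asarray(image, dtype=float)), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), arr)


def to_uint8(image: np.ndarray, vmin: float | None = None, vmax: float | None = None) -> np.ndarray:
    """Min-max rescale a float image to the 8-bit range."""
    img = np.asarray(image, dtype=float)
    lo = float(img.min()) if vmin is None else vmin
    hi = float(img.max()) if vmax is None else vmax
    if hi <= lo:
        return np.zeros(img.shape, dtype=np.uint8)
    out = (img - lo) / (hi - lo) * 255.0
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def write_sinogram(path: str | Path, sino) -> None:
    """Write a Sinogram as float32 TIFF plus a ``.json`` config sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(sino.values, dtype=np.float32))
    meta = dataclasses.asdict(sino.config) if sino.config is not None else {}
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_sinogram(path: str | Path):
    from .raytrace import OpticalConfig, Sinogram

    path = Path(path)
    values = np.asarray(tifffile.imread(path), dtype=float)
    sidecar = path.with_suffix(path.suffix + ".json")
    config = None
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if meta:
            config = OpticalConfig(**meta)
    return Sinogram(values=values, config=config)
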