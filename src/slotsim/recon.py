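"""Tomographic reconstruction by filtered back projection.

Parallel-beam FBP over a full rotation, plus the straight-ray forward
projector that serves as the refraction-free oracle for the simulator. The
frequency-domain filtering and back projection are delegated to
scikit-image's inverse Radon transform, which follows the same conventions
as the simulator (see :mod:`slotsim.raytrace`): zero-padded FFT ramp
filtering per projection row, bilinear back-projection accumulation, and the
standard pi/(2P) inverse-Radon weighting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import iradon

from .io import to_uint8
from .raytrace import Sinogram, rotate_image

_FILTERS = {"ramp": "ramp", "shepp_logan": "shepp-logan", "none": None}


@dataclass
class ReconImage:
    """Reconstructed N x N cross-section with its provenance."""

    pixels: np.ndarray
    filter_name: str = "ramp"
    n_projections: int = 0


def fbp(sino: Sinogram, filter: str = "ramp") -> ReconImage:
    """Filtered back projection of a full-rotation parallel-beam sinogram.

    All 360 degrees of data are used directly (no 180-degree folding:
    refraction breaks the conjugate-ray symmetry of uncorrected data). The
    output is ``W x W`` where ``W`` is the sinogram width.
    """
    if filter not in _FILTERS:
        raise ValueError(f"unknown filter {filter!r}; choose from {sorted(_FILTERS)}")
    values = np.asarray(sino.values, dtype=float)
    P, W = values.shape
    if P < 4:
        raise ValueError("at least 4 projections are required for FBP")
    theta = sino.angles_deg
    pixels = iradon(values.T, theta=theta, filter_name=_FILTERS[filter],
                    output_size=W, circle=False)
    return ReconImage(pixels=pixels, filter_name=filter, n_projections=P)


def recon_to_uint8(recon: ReconImage) -> np.ndarray:
    """Export scaling: min-max over the inscribed circle to 8 bits.

    The corner region outside the inscribed circle carries the usual FBP ring
    artifacts and is excluded from the scaling window.
    """
    img = recon.pixels
    n = img.shape[0]
    yy, xx = np.mgrid[0:n, 0:n]
    c = (n - 1) / 2.0
    mask = (xx - c) ** 2 + (yy - c) ** 2 <= (n / 2.0) ** 2
    return to_uint8(img, vmin=float(img[mask].min()), vmax=float(img[mask].max()))


def straight_projector(image: np.ndarray, n_projections: int,
                       center=None) -> Sinogram:
    """Refraction-free line-integral projections (rotate + column sum).

    Uses the same rotation convention, angular sampling and rotation center
    defaults as the ray-tracing simulator, with refraction disabled — the
    independent oracle for the matched-index case.
    """
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    out = np.zeros((n_projections, w))
    angles = np.arange(n_projections) * 360.0 / n_projections
    for p, theta in enumerate(angles):
        out[p] = rotate_image(img, theta, center).sum(axis=0)
    return Sinogram(values=out, config=None)
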