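"""Image-quality metrics: SSIM and absolute pixel difference (APD).

Both metrics are evaluated over regions of interest derived from the sample
boundary: the whole-sample ROI (filled silhouette plus a few pixels of
background) and a central ROI (the silhouette scaled down about the rotation
center). Restricting to these regions keeps the corner ring artifacts of
filtered back projection out of the scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation, binary_fill_holes, map_coordinates
from skimage.metrics import structural_similarity
from skimage.morphology import disk as disk_selem


@dataclass
class ROI:
    """Binary evaluation mask with its role label."""

    mask: np.ndarray
    label: str  # "whole_sample" or "central"

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("ROI mask is empty")


def _check_pair(a, b, roi: ROI | None):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    if roi is not None and roi.mask.shape != a.shape:
        raise ValueError("ROI shape does not match the images")
    return a, b


def apd(a: np.ndarray, b: np.ndarray, roi: ROI | None = None) -> float:
    """Mean absolute per-pixel brightness difference over the ROI.

    On 8-bit images the score runs from 0 (perfect match) to 255 (white
    against black, the largest possible value).
    """
    a, b = _check_pair(a, b, roi)
    diff = np.abs(a - b)
    return float(diff[roi.mask].mean() if roi is not None else diff.mean())


def ssim(a: np.ndarray, b: np.ndarray, roi: ROI | None = None,
         data_range: float = 255.0) -> float:
    """Mean structural similarity over the ROI (1 = identical, ~0 = unrelated).

    The canonical formulation: Gaussian window sigma=1.5, K1=0.01, K2=0.03,
    8-bit dynamic range by default. The windowed SSIM map is computed over
    the full frame and averaged over the ROI.
    """
    a, b = _check_pair(a, b, roi)
    _, smap = structural_similarity(
        a, b, data_range=data_range, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, K1=0.01, K2=0.03, full=True)
    return float(smap[roi.mask].mean() if roi is not None else smap.mean())


def make_rois(boundary: np.ndarray, dilation_px: int = 5,
              central_fraction: float = 0.5,
              center=None) -> tuple[ROI, ROI]:
    """Whole-sample and central ROIs from a closed boundary image.

    The whole-sample ROI is the filled silhouette dilated by ``dilation_px``
    ("a few pixels around it"); the central ROI is the silhouette scaled by
    ``central_fraction`` about the rotation center. The central ROI is always
    contained in the whole-sample ROI.
    """
    mask = np.asarray(boundary) > 0
    if not mask.any():
        raise ValueError("boundary image is empty")
    silhouette = binary_fill_holes(mask)
    if silhouette.sum() <= mask.sum():
        raise ValueError("boundary is open: no enclosed silhouette")
    h, w = mask.shape
    if center is None:
        center = ((w - 1) / 2.0, (h - 1) / 2.0)
    cx, cy = center

    whole = binary_dilation(silhouette, disk_selem(dilation_px)) \
        if dilation_px > 0 else silhouette
    if not 0.0 < central_fraction <= 1.0:
        raise ValueError("central_fraction must lie in (0, 1]")
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    sx = cx + (xx - cx) / central_fraction
    sy = cy + (yy - cy) / central_fraction
    central = map_coordinates(silhouette.astype(np.uint8), [sy, sx],
                              order=0, mode="constant", cval=0).astype(bool)
    central &= whole
    return ROI(whole, "whole_sample"), ROI(central, "central")
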