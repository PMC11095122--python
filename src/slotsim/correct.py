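"""Sinogram rearrangement: digital correction of refraction distortion.

When the refractive index (RI) of the specimen (n2) differs from that of the
immersion medium (n1), each scan ray refracts at the sample boundary and the
recorded value belongs to a chord other than the expected vertical one.
Because the sample is rotated over a full turn, the information of the
expected (unrefracted) chord at projection angle theta_0 *was* recorded — as
the refracted real path of a different projection angle theta_1. The
correction therefore moves every sinogram sample from where an unrefracted
ray would have needed it to where the refracted ray actually recorded it:

    delta_theta = arcsin((n2 / n1) * sin(alpha_1)) - alpha_1,

where alpha_1 is the incident angle of the expected vertical ray against the
local surface normal. Rotating the sample by delta_theta makes the refracted
path at theta_1 = theta_0 + delta_theta coincide with the expected path at
theta_0. The angle maps to a (fractional) vertical row offset of
``n_projections / 360`` rows per degree, and rotating the entry point about
the rotation center by the same angle gives the horizontal column offset;
bilinear interpolation at the offset position fills the rearranged sinogram.

The geometry (entry points and incident angles) is obtained by ray
propagation on the boundary rotated to every projection angle; the boundary
may come from the known input surface or from a "preemptive surface"
extracted from an uncorrected transmission reconstruction, since the shape
of the specimen always reconstructs correctly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_closing, binary_erosion, binary_fill_holes
from skimage.filters import threshold_otsu
from skimage.measure import label

from .raytrace import (
    GeometryError,
    OpticalConfig,
    Sinogram,
    entry_geometry,
    rotate_points,
    rotate_vectors,
    trace_contour,
)
from .recon import ReconImage, fbp


@dataclass
class EntryPointTable:
    """Per-(projection, column) entry data of the expected vertical rays.

    All arrays are ``(P, W)``. ``alpha`` is the signed incident angle in
    radians (sign encodes the side of the outward normal the ray arrives on);
    ``delta_theta`` the signed digital rotation in degrees; ``tir`` flags
    rays lost to total internal reflection in the physical measurement;
    ``valid`` flags samples for which the refraction correspondence exists.
    """

    entry_x: np.ndarray
    entry_y: np.ndarray
    alpha: np.ndarray
    delta_theta: np.ndarray
    tir: np.ndarray
    valid: np.ndarray
    config: OpticalConfig
    center: tuple[float, float] | None = None  # rotation center, (x, y)

    @property
    def shape(self):
        return self.alpha.shape

    def invalid_fraction(self) -> float:
        """Fraction of sample-hitting rays whose data are unrecoverable.

        For n2 > n1 the outermost incident points have no refraction
        correspondence (their data were never recorded); for n2 < n1 rays
        can be lost to TIR. Either way the information is gone, and this
        reports how much.
        """
        hit = np.isfinite(self.alpha)
        if not hit.any():
            return 0.0
        return float((hit & ~self.valid).sum() / hit.sum())

    def to_csv(self, path) -> None:
        import pandas as pd

        P, W = self.shape
        p, w = np.mgrid[0:P, 0:W]
        pd.DataFrame({
            "projection": p.ravel(), "column": w.ravel(),
            "entry_x": self.entry_x.ravel(), "entry_y": self.entry_y.ravel(),
            "alpha_rad": self.alpha.ravel(),
            "delta_theta_deg": self.delta_theta.ravel(),
            "tir": self.tir.ravel(), "valid": self.valid.ravel(),
        }).to_csv(path, index=False)


def delta_theta(n1: float, n2: float, alpha1, *, invert_ratio: bool = False):
    """Digital rotation angle (degrees) for one incident angle (radians).

    ``arcsin((n2/n1) sin alpha1) - alpha1``: the angle by which the sample
    must be digitally rotated so that the refracted real beam path coincides
    with the unrefracted expected path. NaN where the correspondence does not
    exist (``(n2/n1) sin alpha1 > 1``; those samples were never recorded).

    ``invert_ratio`` is a debug switch that evaluates the formula with the
    reciprocal index ratio instead; it is wrong (it fails the geometric
    rotation-search cross-check) and exists only for comparison.
    """
    alpha1 = np.asarray(alpha1, dtype=float)
    if n1 == n2:  # matched media: exactly zero, not arcsin(sin(a)) - a noise
        out = np.where(np.isnan(alpha1), np.nan, 0.0)
        return float(out) if out.ndim == 0 else out
    r = (n1 / n2) if invert_ratio else (n2 / n1)
    s = r * np.sin(alpha1)
    with np.errstate(invalid="ignore"):
        out = np.degrees(np.where(np.abs(s) <= 1.0,
                                  np.arcsin(np.clip(s, -1.0, 1.0)) - alpha1,
                                  np.nan))
    return float(out) if out.ndim == 0 else out


def vertical_offset(delta_theta_deg, n_projections: int,
                    angular_range_deg: float = 360.0):
    """Fractional sinogram-row offset for a digital rotation in degrees.

    One degree of rotation corresponds to ``n_projections / angular_range``
    rows (2.2... rows for the typical 800 projections over 360 degrees). The
    offset is applied modulo ``n_projections``: a full-rotation acquisition
    is periodic in angle.
    """
    return np.asarray(delta_theta_deg, dtype=float) * n_projections / angular_range_deg


def horizontal_offset(entry_point, delta_theta_deg, center):
    """Fractional column offset: rotate the entry point about the center.

    As the sample is digitally rotated by delta_theta, the incident position
    rotates with it; the offset is the change of its x-coordinate.
    """
    entry = np.atleast_2d(np.asarray(entry_point, dtype=float))
    dt = np.atleast_1d(np.asarray(delta_theta_deg, dtype=float))
    out = np.empty(len(entry))
    for i, (pt, d) in enumerate(zip(entry, dt)):
        out[i] = rotate_points(pt, d, center)[0] - pt[0]
    return float(out[0]) if np.asarray(entry_point).ndim == 1 else out


def build_entry_table_from_geometry(hit, entry_x, entry_y, psi, tir_entry,
                                    config: OpticalConfig,
                                    center=None) -> EntryPointTable:
    """Assemble the table from per-projection entry geometry.

    ``psi`` is the signed incident angle of the expected vertical ray. The
    signed digital rotation applied per sample is ``-sign(psi) *
    delta_theta(|psi|)``: the entry side of the normal decides which way the
    sample must turn (the two halves of a convex silhouette rotate opposite
    ways).
    """
    alpha = np.where(hit, psi, np.nan)
    dt_mag = delta_theta(config.n_medium, config.n_sample, np.abs(alpha))
    sgn = np.sign(alpha)
    sgn[sgn == 0] = 1.0
    dt = -sgn * dt_mag
    valid = hit & np.isfinite(dt)
    # TIR in the physical acquisition: the *real* ray never entered, so the
    # recorded value at the source position is dark, not wrong; the sample
    # the correction would fetch for a TIR-lossy pair is still resampled.
    dt = np.where(valid, dt, np.nan)
    return EntryPointTable(entry_x=entry_x, entry_y=entry_y, alpha=alpha,
                           delta_theta=dt, tir=np.asarray(tir_entry, bool),
                           valid=valid, config=config, center=center)


def build_entry_table(surface: np.ndarray, config: OpticalConfig,
                      center=None, width: int | None = None) -> EntryPointTable:
    """Entry-point table by ray propagation on the rotated surface.

    The input surface (known or preemptive) is traced once; its contour and
    normals are rotated to every projection angle and each column's vertical
    ray is intersected with it, exactly as in the simulator.
    """
    surface = np.asarray(surface, dtype=float)
    h, w = surface.shape
    if width is None:
        width = w
    if center is None:
        center = ((w - 1) / 2.0, (h - 1) / 2.0)
    contour = trace_contour(surface, config.slope_order, config.slope_neighbors)
    eta_in = config.n_medium / config.n_sample  # for the TIR flag

    P = config.n_projections
    hit_t = np.zeros((P, width), dtype=bool)
    ex_t = np.full((P, width), np.nan)
    ey_t = np.full((P, width), np.nan)
    psi_t = np.full((P, width), np.nan)
    tir_t = np.zeros((P, width), dtype=bool)
    cols = np.arange(width, dtype=float)
    for p, theta in enumerate(config.angles_deg):
        pts = rotate_points(contour.points, theta, center)
        nrms = rotate_vectors(contour.normals, theta)
        hit, entry_y, psi, _ = entry_geometry(pts, nrms, width)
        hit_t[p] = hit
        ex_t[p] = np.where(hit, cols, np.nan)
        ey_t[p] = entry_y
        psi_t[p] = psi
        with np.errstate(invalid="ignore"):
            tir_t[p] = hit & (eta_in * np.sin(np.abs(psi)) > 1.0)
    return build_entry_table_from_geometry(hit_t, ex_t, ey_t, psi_t, tir_t,
                                           config, center=center)


def rearrange_sinogram(sino: Sinogram, table: EntryPointTable,
                       center=None) -> Sinogram:
    """Move every sinogram sample to where its information was recorded.

    ``out[p, w]`` is the bilinear sample of the input at row
    ``p + vertical_offset`` (wrapped modulo P) and column
    ``w + horizontal_offset``; samples without a valid correspondence, or
    whose source column falls outside the sinogram, are set to 0.
    """
    values = np.asarray(sino.values, dtype=float)
    P, W = values.shape
    if table.shape != (P, W):
        raise ValueError(f"entry table shape {table.shape} does not match "
                         f"sinogram shape {(P, W)}")
    if center is None:
        center = table.center if table.center is not None \
            else ((W - 1) / 2.0, (W - 1) / 2.0)

    dt = np.where(table.valid, table.delta_theta, 0.0)
    v = vertical_offset(dt, P, table.config.angular_range_deg)
    rows = (np.arange(P)[:, None] + v) % P

    # horizontal offset: rotate each entry point about the center by dt
    rad = np.deg2rad(dt)
    ex = np.where(table.valid, table.entry_x, 0.0) - center[0]
    ey = np.where(table.valid, table.entry_y, 0.0) - center[1]
    x_rot = np.cos(rad) * ex - np.sin(rad) * ey + center[0]
    cols = np.arange(W)[None, :] + (x_rot - (ex + center[0]))

    inside = (cols >= 0.0) & (cols <= W - 1.0)
    ok = table.valid & inside

    r0 = np.floor(rows).astype(int)
    fr = rows - r0
    r0 %= P
    r1 = (r0 + 1) % P
    c0 = np.floor(np.clip(cols, 0, W - 2)).astype(int)
    fc = np.clip(cols, 0, W - 1) - c0
    c1 = c0 + 1
    out = ((1 - fr) * (1 - fc) * values[r0, c0]
           + (1 - fr) * fc * values[r0, c1]
           + fr * (1 - fc) * values[r1, c0]
           + fr * fc * values[r1, c1])
    out[~ok] = 0.0
    return Sinogram(values=out, config=table.config)


def surface_from_reconstruction(recon: ReconImage | np.ndarray) -> np.ndarray:
    """Extract a preemptive surface from an (uncorrected) reconstruction.

    The silhouette of the specimen reconstructs correctly even from a
    distorted sinogram; Otsu thresholding, largest-component selection and
    hole filling yield the filled silhouette, whose one-pixel inner rim is
    returned as a boundary image usable as an input surface.
    """
    img = recon.pixels if hasattr(recon, "pixels") else np.asarray(recon, float)
    if not np.any(img > 0) or np.ptp(img) == 0:
        raise GeometryError("reconstruction is empty; cannot extract a surface")
    thr = threshold_otsu(img)
    mask = binary_closing(img > thr, np.ones((3, 3)))
    lab = label(mask, connectivity=2)
    if lab.max() == 0:
        raise GeometryError("no foreground component found; "
                            "try thresholding manually")
    largest = lab == np.argmax(np.bincount(lab.ravel())[1:]) + 1
    filled = binary_fill_holes(largest)
    boundary = filled & ~binary_erosion(filled, np.ones((3, 3)))
    out = np.where(boundary, 255.0, 0.0)
    trace_contour(out)  # validates closure; raises GeometryError otherwise
    return out


@dataclass
class SweepResult:
    n_sample: float
    recon: ReconImage
    score: float  # conjugate-symmetry consistency; higher (closer to 0) is better


def conjugate_consistency(sino: Sinogram) -> float:
    """How well a sinogram satisfies parallel-beam conjugate symmetry.

    In a refraction-free parallel acquisition over a full rotation, the
    projection at angle theta + 180 degrees is the mirror image of the one
    at theta. Refraction (or a correction with the wrong specimen RI) breaks
    this symmetry, so the negative RMS difference between each row and its
    mirrored conjugate row — normalized by the sinogram maximum, over samples
    lit in both — scores a candidate correction: 0 is perfect, more negative
    is worse.
    """
    v = np.asarray(sino.values, dtype=float)
    P = v.shape[0]
    flipped = v[(np.arange(P) + P // 2) % P][:, ::-1]
    both = (v > 0) & (flipped > 0)
    if not both.any() or v.max() <= 0:
        return -np.inf
    return float(-np.sqrt(np.mean((v[both] - flipped[both]) ** 2)) / v.max())


def ri_sweep(sino: Sinogram, surface: np.ndarray, n_medium: float,
             candidates, config: OpticalConfig | None = None,
             center=None) -> list[SweepResult]:
    """Correct and reconstruct with a list of candidate specimen RIs.

    Used when the specimen RI is not known exactly: the user compares the
    reconstructions by eye. Each result also carries an advisory
    machine-readable score (see :func:`conjugate_consistency`) that peaks at
    the true specimen RI; the visual comparison remains the method of
    choice.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("at least one candidate RI is required")
    base = config if config is not None else sino.config
    if base is None:
        raise ValueError("no optical configuration available")
    results = []
    for n2 in candidates:
        cfg = OpticalConfig(
            n_medium=n_medium, n_sample=n2,
            n_projections=base.n_projections,
            angular_range_deg=base.angular_range_deg,
            slope_order=base.slope_order,
            slope_neighbors=base.slope_neighbors,
            step_px=base.step_px)
        table = build_entry_table(surface, cfg, center=center,
                                  width=sino.width)
        corrected = rearrange_sinogram(sino, table, center=center)
        results.append(SweepResult(n_sample=float(n2), recon=fbp(corrected),
                                   score=conjugate_consistency(corrected)))
    return results
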