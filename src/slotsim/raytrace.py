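"""Snell's-law ray propagation through a 2D sample cross-section.

Simulates one SLOT acquisition: the sample (a closed boundary plus an interior
fluorescence pattern) is digitally rotated to each projection angle; a vertical
scan ray per image column is refracted once at the boundary and then marched in
one-pixel steps through the interior, summing bilinear samples of the structure
image. One projection per angle assembles the (possibly distorted) sinogram.

Coordinate conventions
----------------------
Pixels are addressed as (x, y) = (column, row), origin top-left, y increasing
downward; rays travel in +y. Sample rotation by an angle ``theta`` moves a
material point ``m`` to ``c + R(theta) (m - c)`` with
``R = [[cos, -sin], [sin, cos]]`` about the rotation center ``c``. This is the
same convention as :func:`skimage.transform.radon`, so a matched-index
simulation agrees with the classical Radon transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import binary_fill_holes, gaussian_filter, map_coordinates
from skimage.measure import find_contours, label


class GeometryError(ValueError):
    """Raised when a surface image does not describe a single closed curve."""


@dataclass(frozen=True)
class OpticalConfig:
    """Acquisition parameters of a simulated SLOT measurement.

    n_medium / n_sample are the refractive indices n1 (immersion medium) and
    n2 (specimen); both accepted in (1, 99]. ``n_projections`` projections are
    spread uniformly over a full rotation. ``slope_order`` and
    ``slope_neighbors`` control the local polynomial regression that estimates
    the boundary slope at each entry point; ``step_px`` is the ray-marching
    step length in pixels.
    """

    n_medium: float = 1.4
    n_sample: float = 1.4
    n_projections: int = 800
    angular_range_deg: float = 360.0
    slope_order: int = 2
    slope_neighbors: int = 7
    step_px: float = 1.0

    def __post_init__(self):
        for name in ("n_medium", "n_sample"):
            n = getattr(self, name)
            if not (1.0 < n <= 99.0):
                raise ValueError(f"{name}={n} outside the accepted range (1, 99]")
        if self.n_projections < 4:
            raise ValueError("at least 4 projections are required")
        if self.slope_neighbors < 3 or self.slope_neighbors % 2 == 0:
            raise ValueError("slope_neighbors must be an odd integer >= 3")
        if self.slope_order < 1:
            raise ValueError("slope_order must be >= 1")

    @property
    def angles_deg(self) -> np.ndarray:
        p = np.arange(self.n_projections)
        return p * self.angular_range_deg / self.n_projections


@dataclass
class SurfaceContour:
    """Ordered subpixel trace of the sample boundary.

    ``points`` is an (N, 2) array of (x, y) vertices with consistent winding;
    ``normals`` are per-vertex outward unit normals, ``slopes`` the tangent
    slopes dy/dx (inf for vertical tangents). ``interior`` is the filled
    even-odd interior mask of the boundary.
    """

    points: np.ndarray
    normals: np.ndarray
    slopes: np.ndarray
    interior: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class RayResult:
    """Outcome of propagating one vertical scan ray."""

    entry_point: tuple[float, float] | None
    incident_angle: float | None  # alpha_1, radians, vs. outward normal
    refracted_angle: float | None  # beta, radians; None when TIR or miss
    exit_direction: tuple[float, float] | None  # unit vector inside sample
    intensity: float
    tir: bool = False


@dataclass
class Sinogram:
    """P x W projection stack: row p is the projection at angle p*360/P."""

    values: np.ndarray
    config: OpticalConfig | None = None

    @property
    def n_projections(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def angles_deg(self) -> np.ndarray:
        rng = self.config.angular_range_deg if self.config else 360.0
        return np.arange(self.n_projections) * rng / self.n_projections


# ---------------------------------------------------------------------------
# rotation primitives
# ---------------------------------------------------------------------------

def _rot_matrix(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s], [s, c]])


def rotate_points(points: np.ndarray, angle_deg: float, center) -> np.ndarray:
    """Rotate (x, y) points about ``center`` by ``angle_deg`` (sample-rotation sense)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    c = np.asarray(center, dtype=float)
    out = (pts - c) @ _rot_matrix(angle_deg).T + c
    return out if np.asarray(points).ndim > 1 else out[0]


def rotate_vectors(vectors: np.ndarray, angle_deg: float) -> np.ndarray:
    vec = np.atleast_2d(np.asarray(vectors, dtype=float))
    out = vec @ _rot_matrix(angle_deg).T
    return out if np.asarray(vectors).ndim > 1 else out[0]


def rotate_image(image: np.ndarray, angle_deg: float, center=None) -> np.ndarray:
    """Bilinear rotation of image content by ``angle_deg`` about ``center``.

    The content moves in the sample-rotation sense of :func:`rotate_points`;
    samples falling outside the frame read as 0.
    """
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    if center is None:
        center = ((w - 1) / 2.0, (h - 1) / 2.0)
    cx, cy = center
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    rot = _rot_matrix(-angle_deg)
    sx = cx + rot[0, 0] * (xx - cx) + rot[0, 1] * (yy - cy)
    sy = cy + rot[1, 0] * (xx - cx) + rot[1, 1] * (yy - cy)
    return map_coordinates(img, [sy, sx], order=1, mode="constant", cval=0.0)


# ---------------------------------------------------------------------------
# contour tracing and slope estimation
# ---------------------------------------------------------------------------

def trace_contour(surface: np.ndarray, slope_order: int = 2,
                  slope_neighbors: int = 7) -> SurfaceContour:
    """Extract the ordered boundary contour of a surface image.

    The surface must contain exactly one closed, non-degenerate curve. The
    raster is filled (even-odd), lightly smoothed, and the 0.5 level set is
    traced to subpixel precision; per-vertex slopes and outward normals come
    from local polynomial regression (see :func:`estimate_slope`).
    """
    img = np.asarray(surface, dtype=float)
    mask = img > img.max() / 2.0 if img.max() > 0 else img > 0
    if not mask.any():
        raise GeometryError("surface image is empty")
    n_comp = int(label(mask, connectivity=2).max())
    if n_comp != 1:
        raise GeometryError(
            f"surface must contain exactly one boundary component, found {n_comp}")
    filled = binary_fill_holes(mask)
    interior_area = int(filled.sum() - mask.sum())
    if interior_area < 16:
        raise GeometryError(
            "boundary is open or degenerate (no enclosed interior)")
    smooth = gaussian_filter(filled.astype(float), sigma=2.0)
    contours = find_contours(smooth, 0.5)
    contours = [c for c in contours if len(c) >= 8]
    if len(contours) != 1:
        raise GeometryError(
            f"expected one closed contour, traced {len(contours)}")
    rc = contours[0]
    if np.allclose(rc[0], rc[-1]):
        rc = rc[:-1]
    points = rc[:, ::-1].copy()  # (row, col) -> (x, y)

    # enforce consistent winding via the shoelace sign
    area2 = np.sum(points[:, 0] * np.roll(points[:, 1], -1)
                   - np.roll(points[:, 0], -1) * points[:, 1])
    if area2 < 0:
        points = points[::-1].copy()

    slopes, normals = _all_slopes(points, slope_order, slope_neighbors, filled)
    return SurfaceContour(points=points, normals=normals, slopes=slopes,
                          interior=filled)


def estimate_slope(contour: SurfaceContour, index: int, order: int = 2,
                   n_neighbors: int = 7):
    """Tangent slope and outward normal at one contour vertex.

    A polynomial of the given order is least-squares fitted to ``n_neighbors``
    contour points centered at ``index`` in a locally rotated frame (secant
    aligned with the abscissa) so vertical tangents stay well conditioned.
    Returns ``(slope, normal)``: dy/dx in image coordinates (``inf`` for a
    vertical tangent) and the outward unit normal.
    """
    pts = contour.points
    n = len(pts)
    if n_neighbors > n:
        raise ValueError("n_neighbors exceeds contour length")
    tangent = _local_tangent(pts, index, order, n_neighbors)
    normal = _orient_outward(pts[index], _perp(tangent), contour.interior)
    slope = np.inf if abs(tangent[0]) < 1e-12 else tangent[1] / tangent[0]
    return slope, normal


def _perp(v: np.ndarray) -> np.ndarray:
    return np.array([-v[1], v[0]])


def _local_tangent(points: np.ndarray, index: int, order: int,
                   n_neighbors: int) -> np.ndarray:
    n = len(points)
    half = n_neighbors // 2
    idx = (np.arange(index - half, index + half + 1)) % n
    local = points[idx] - points[index]
    secant = local[-1] - local[0]
    norm = np.hypot(*secant)
    if norm < 1e-12:
        return np.array([1.0, 0.0])
    u = secant / norm
    # rotate into the secant frame: abscissa t, ordinate s
    t = local @ u
    s = local @ _perp(u)
    eff_order = min(order, n_neighbors - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("error", np.exceptions.RankWarning)
        try:
            coeffs = np.polyfit(t, s, eff_order)
        except np.exceptions.RankWarning:
            warnings.warn("rank-deficient slope fit; falling back to order 1",
                          stacklevel=2)
            coeffs = np.polyfit(t, s, 1)
    ds_dt = np.polyval(np.polyder(coeffs), 0.0)
    tangent = u + ds_dt * _perp(u)
    return tangent / np.hypot(*tangent)


def _orient_outward(point: np.ndarray, normal: np.ndarray,
                    interior: np.ndarray) -> np.ndarray:
    normal = normal / np.hypot(*normal)
    probe = point + 2.0 * normal
    h, w = interior.shape
    xi = int(round(probe[0])); yi = int(round(probe[1]))
    inside = 0 <= xi < w and 0 <= yi < h and interior[yi, xi]
    return -normal if inside else normal


def _all_slopes(points: np.ndarray, order: int, n_neighbors: int,
                interior: np.ndarray):
    n = len(points)
    tangents = np.empty_like(points)
    for i in range(n):
        tangents[i] = _local_tangent(points, i, order, n_neighbors)
    normals = np.stack([_perp(t) for t in tangents])
    # orient all normals outward in one interior lookup
    probes = points + 2.0 * normals
    h, w = interior.shape
    xi = np.clip(np.rint(probes[:, 0]).astype(int), 0, w - 1)
    yi = np.clip(np.rint(probes[:, 1]).astype(int), 0, h - 1)
    inside = interior[yi, xi]
    normals[inside] *= -1.0
    with np.errstate(divide="ignore"):
        slopes = np.where(np.abs(tangents[:, 0]) < 1e-12, np.inf,
                          tangents[:, 1] / np.where(tangents[:, 0] == 0, 1,
                                                    tangents[:, 0]))
    return slopes, normals


# ---------------------------------------------------------------------------
# refraction
# ---------------------------------------------------------------------------

def snell_refract(n1: float, n2: float, alpha: float):
    """Refraction angle beta with n1 sin(alpha) = n2 sin(beta).

    Returns the refracted angle in radians, or ``None`` for total internal
    reflection (the ray does not enter). ``alpha`` is measured from the
    surface normal, 0 <= alpha <= pi/2.
    """
    if not 0.0 <= alpha <= np.pi / 2 + 1e-12:
        raise ValueError("incident angle must lie in [0, pi/2]")
    s = (n1 / n2) * np.sin(alpha)
    if s > 1.0:
        return None
    return float(np.arcsin(s))


def _refract_directions(psi: np.ndarray, normals: np.ndarray, eta: float):
    """Vector Snell refraction of vertical rays d0=(0,1).

    ``psi`` is the signed incident angle (sign = side of the normal the ray
    arrives on), ``normals`` the outward unit normals. Returns unit transmitted
    directions and a TIR mask (directions are NaN where TIR).
    """
    sin_b = eta * np.sin(np.abs(psi))
    tir = sin_b > 1.0
    beta = np.arcsin(np.clip(sin_b, -1.0, 1.0))
    # transmitted direction: rotate the inward normal by the signed beta
    inward = -normals
    sgn = np.sign(psi)
    sgn[sgn == 0] = 1.0
    c, s = np.cos(beta), sgn * np.sin(beta)
    dirs = np.stack([c * inward[:, 0] - s * inward[:, 1],
                     s * inward[:, 0] + c * inward[:, 1]], axis=1)
    dirs[tir] = np.nan
    return dirs, tir, beta


# ---------------------------------------------------------------------------
# entry geometry and ray marching
# ---------------------------------------------------------------------------

def entry_geometry(points: np.ndarray, normals: np.ndarray, width: int):
    """First intersection of each vertical scan ray with a contour polyline.

    For each column w the topmost crossing of the closed polyline with the
    line x = w is found by segment intersection; the incident data are taken
    at the nearer segment endpoint. Returns (hit, entry_y, psi, normal) arrays
    where ``psi`` is the signed angle from the outward normal to the reversed
    ray direction (sign = which side of the normal the ray arrives on).
    """
    x0 = points[:, 0]
    y0 = points[:, 1]
    x1 = np.roll(x0, -1)
    y1 = np.roll(y0, -1)
    cols = np.arange(width, dtype=float)

    dx = x1 - x0
    straddle = ((x0[None, :] <= cols[:, None]) & (cols[:, None] < x1[None, :])) | \
               ((x1[None, :] <= cols[:, None]) & (cols[:, None] < x0[None, :]))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (cols[:, None] - x0[None, :]) / dx[None, :]
    t = np.where(np.abs(dx)[None, :] < 1e-12, 0.5, t)
    ycross = y0[None, :] + t * (y1 - y0)[None, :]
    ycross = np.where(straddle, ycross, np.inf)
    seg = np.argmin(ycross, axis=1)
    entry_y = ycross[np.arange(width), seg]
    hit = np.isfinite(entry_y)

    tseg = t[np.arange(width), seg]
    near = np.where(tseg < 0.5, seg, (seg + 1) % len(points))
    nrm = normals[near]
    # signed angle from outward normal to -d0 = (0, -1)
    psi = np.arctan2(nrm[:, 0] * (-1.0) - nrm[:, 1] * 0.0,
                     nrm[:, 1] * (-1.0))
    psi = np.where(hit, psi, np.nan)
    return hit, entry_y, psi, nrm


def _march_intensities(entry_x, entry_y, dirs, active, structure_rot,
                       interior_rot, step_px: float) -> np.ndarray:
    """Sum bilinear structure samples along straight rays until exit.

    Rays start at the entry points and advance ``step_px`` pixels per step;
    marching for a ray ends at the first sample outside the interior
    (bilinearly sampled filled-silhouette field below one half).
    """
    h, w = structure_rot.shape
    n = len(entry_x)
    out = np.zeros(n)
    if not active.any():
        return out
    ex = entry_x[active]; ey = entry_y[active]; dv = dirs[active]
    n_steps = int(np.ceil(np.hypot(h, w) / step_px)) + 2
    t = (np.arange(1, n_steps + 1) * step_px)[None, :]
    px = ex[:, None] + dv[:, 0:1] * t
    py = ey[:, None] + dv[:, 1:2] * t
    inside = map_coordinates(interior_rot, [py, px],
                             order=1, mode="constant", cval=0.0) >= 0.5
    exited = ~inside
    first_exit = np.where(exited.any(axis=1), np.argmax(exited, axis=1),
                          n_steps)
    vals = map_coordinates(structure_rot, [py, px], order=1,
                           mode="constant", cval=0.0)
    keep = np.arange(n_steps)[None, :] < first_exit[:, None]
    out[active] = (vals * keep).sum(axis=1) * step_px
    return out


def trace_ray(pair, contour: SurfaceContour, scan_x: float,
              config: OpticalConfig) -> RayResult:
    """Propagate the single vertical scan ray at column ``scan_x``.

    ``pair`` and ``contour`` must be expressed in the same (already rotated)
    frame. A ray that misses the sample returns zero intensity with null entry
    fields; total internal reflection returns zero intensity with the TIR
    flag set.
    """
    width = pair.structure.shape[1]
    hit, entry_y, psi, nrm = entry_geometry(contour.points, contour.normals,
                                            width)
    w = int(round(scan_x))
    if not (0 <= w < width) or not hit[w]:
        return RayResult(None, None, None, None, 0.0)
    eta = config.n_medium / config.n_sample
    dirs, tir, beta = _refract_directions(psi[[w]], nrm[[w]], eta)
    alpha1 = float(abs(psi[w]))
    entry = (float(w), float(entry_y[w]))
    if tir[0]:
        return RayResult(entry, alpha1, None, None, 0.0, tir=True)
    intensity = _march_intensities(
        np.array([float(w)]), np.array([entry_y[w]]), dirs,
        np.array([True]), np.asarray(pair.structure, dtype=float),
        contour.interior.astype(float), config.step_px)[0]
    return RayResult(entry, alpha1, float(beta[0]),
                     (float(dirs[0, 0]), float(dirs[0, 1])),
                     float(intensity))


def simulate_sinogram(pair, config: OpticalConfig, return_table: bool = False):
    """Simulate a full rotation: one refracted projection per angle.

    For each projection angle the surface contour and the structure image are
    rotated about ``pair.rotation_center``; every column's vertical ray is
    refracted at its entry point and integrated through the interior. Returns
    the sinogram, and with ``return_table=True`` also the per-(projection,
    column) entry-point table used by the rearrangement correction.
    """
    surface = np.asarray(pair.surface, dtype=float)
    structure = np.asarray(pair.structure, dtype=float)
    h, w = structure.shape
    center = pair.rotation_center
    contour = trace_contour(surface, config.slope_order, config.slope_neighbors)
    eta = config.n_medium / config.n_sample

    P = config.n_projections
    sino = np.zeros((P, w))
    ent_x = np.full((P, w), np.nan)
    ent_y = np.full((P, w), np.nan)
    psi_t = np.full((P, w), np.nan)
    tir_t = np.zeros((P, w), dtype=bool)
    hit_t = np.zeros((P, w), dtype=bool)

    interior_f = contour.interior.astype(float)
    for p, theta in enumerate(config.angles_deg):
        pts = rotate_points(contour.points, theta, center)
        nrms = rotate_vectors(contour.normals, theta)
        structure_rot = rotate_image(structure, theta, center)
        interior_rot = rotate_image(interior_f, theta, center)
        hit, entry_y, psi, nrm = entry_geometry(pts, nrms, w)
        dirs, tir, _ = _refract_directions(np.where(hit, psi, 0.0), nrm, eta)
        active = hit & ~tir
        cols = np.arange(w, dtype=float)
        sino[p] = _march_intensities(cols, entry_y, dirs, active,
                                     structure_rot, interior_rot,
                                     config.step_px)
        ent_x[p] = np.where(hit, cols, np.nan)
        ent_y[p] = entry_y
        psi_t[p] = psi
        tir_t[p] = hit & tir
        hit_t[p] = hit

    sinogram = Sinogram(values=sino, config=replace(config))
    if not return_table:
        return sinogram
    from .correct import build_entry_table_from_geometry

    table = build_entry_table_from_geometry(
        hit_t, ent_x, ent_y, psi_t, tir_t, config, center=center)
    return sinogram, table
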