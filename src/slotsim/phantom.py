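"""Digital phantom generation.

Produces input-surface / input-structure image pairs mimicking a cleared
specimen embedded in a cylindrical adhesive compound: the boundary is a
smooth "potato-shaped" closed curve (harmonically perturbed circle) and the
interior carries a fluorescence pattern — logo-like homogeneous patches with
fine line features, randomly placed fluorescent beads, or resolution bars.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import binary_dilation, binary_erosion, binary_fill_holes
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon
from skimage.draw import polygon_perimeter
from skimage.morphology import disk as disk_selem

from . import io as _io
from .raytrace import GeometryError, trace_contour

DEFAULT_SIZE = (650, 688)  # (H, W), the resolution of the reference phantom


@dataclass
class PhantomPair:
    """Surface (boundary-only) and structure (interior-only) image pair."""

    surface: np.ndarray
    structure: np.ndarray
    rotation_center: tuple[float, float] = field(default=None)  # (x, y)

    def __post_init__(self):
        if self.surface.shape != self.structure.shape:
            raise ValueError("surface and structure dimensions differ")
        if self.rotation_center is None:
            h, w = self.surface.shape
            self.rotation_center = ((w - 1) / 2.0, (h - 1) / 2.0)


def _check_size(size):
    h, w = size
    if h < 64 or w < 64:
        raise ValueError("phantom size must be at least 64x64")
    return int(h), int(w)


def generate_boundary(seed: int, size=DEFAULT_SIZE, mean_radius: float | None = None,
                      irregularity: float = 0.12, n_harmonics: int = 6,
                      center=None) -> np.ndarray:
    """One-pixel-wide closed boundary with harmonically perturbed radius.

    radius(phi) = mean_radius * (1 + sum_k a_k cos(k phi + phi_k)), with the
    harmonic amplitudes drawn from ``seed`` and normalized so their absolute
    sum equals ``irregularity`` (0 gives a discrete circle). The curve is
    rasterized at value 255, 8-connected and closed.
    """
    h, w = _check_size(size)
    if not 0.0 <= irregularity <= 0.3:
        raise ValueError("irregularity must lie in [0, 0.3]")
    if mean_radius is None:
        mean_radius = 0.40 * min(h, w)
    if mean_radius * (1 + irregularity) >= min(h, w) / 2.0:
        raise GeometryError("boundary radius exceeds the image frame")
    if center is None:
        center = ((w - 1) / 2.0, (h - 1) / 2.0)
    cx, cy = center

    rng = np.random.default_rng(seed)
    k = np.arange(1, n_harmonics + 1)
    amps = rng.uniform(0.3, 1.0, n_harmonics) / k  # low-order harmonics dominate
    phases = rng.uniform(0, 2 * np.pi, n_harmonics)
    if irregularity > 0 and amps.sum() > 0:
        amps *= irregularity / amps.sum()
    else:
        amps[:] = 0.0

    n_pts = max(256, int(np.ceil(4 * np.pi * mean_radius)))
    phi = np.linspace(0, 2 * np.pi, n_pts, endpoint=False)
    r = mean_radius * (1 + (amps[None, :] * np.cos(phi[:, None] * k[None, :]
                                                   + phases[None, :])).sum(axis=1))
    xs = cx + r * np.cos(phi)
    ys = cy + r * np.sin(phi)

    img = np.zeros((h, w))
    rr, cc = polygon_perimeter(ys, xs, shape=(h, w), clip=True)
    img[rr, cc] = 255.0
    return img


def _interior_mask(boundary: np.ndarray, margin: int = 2) -> np.ndarray:
    mask = boundary > 0
    filled = binary_fill_holes(mask)
    inner = filled & ~binary_dilation(mask, disk_selem(margin))
    return inner


def generate_structure(boundary: np.ndarray, pattern: str = "logo_like",
                       seed: int = 0, **params) -> np.ndarray:
    """Interior fluorescence pattern clipped strictly inside the boundary.

    Patterns:

    ``logo_like``
        Several filled homogeneous polygonal patches (upper half) plus thin
        2–3 px line and letter-like strokes (lower half) — large constant
        areas next to very small precise structures.
    ``beads``
        ``n`` disks of radius ``r`` at uniform-random interior positions,
        mimicking fluorescent polystyrene beads in an agarose cylinder.
    ``bars``
        Groups of parallel line pairs with decreasing spacing.
    """
    rng = np.random.default_rng(seed)
    h, w = boundary.shape
    inner = _interior_mask(boundary)
    if not inner.any():
        raise GeometryError("boundary encloses no interior")
    out = np.zeros((h, w))

    if pattern == "beads":
        n = int(params.get("n", 25))
        r = float(params.get("r", 4))
        value = float(params.get("value", 255))
        if n == 0:
            return out
        allowed = binary_erosion(inner, disk_selem(int(np.ceil(r)) + 1))
        ys, xs = np.nonzero(allowed)
        if len(ys) == 0:
            raise GeometryError("interior too small for the requested beads")
        pick = rng.integers(0, len(ys), n)
        for cy, cx in zip(ys[pick], xs[pick]):
            rr, cc = draw_disk((cy, cx), r + 0.5, shape=(h, w))
            out[rr, cc] = value
    elif pattern == "logo_like":
        out = _logo_like(rng, inner, **params)
    elif pattern == "bars":
        out = _bars(rng, inner, **params)
    else:
        raise ValueError(f"unknown pattern {pattern!r}")

    out[~inner] = 0.0
    return out


def _blob(rng, cx, cy, radius, n_vertices=12):
    phi = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    r = radius * (1 + rng.uniform(-0.25, 0.25, n_vertices))
    return cy + r * np.sin(phi), cx + r * np.cos(phi)


def _logo_like(rng, inner, n_blobs: int = 3, n_lines: int = 6,
               blob_value: float = 200.0, line_value: float = 255.0):
    h, w = inner.shape
    ys, xs = np.nonzero(inner)
    cy0, cx0 = ys.mean(), xs.mean()
    extent = 0.5 * (np.ptp(ys) + np.ptp(xs)) / 2.0
    out = np.zeros((h, w))

    # thin strokes and letter-like marks in the lower half
    lower = inner & (np.arange(h)[:, None] > cy0)
    lys, lxs = np.nonzero(binary_erosion(lower, disk_selem(4)))
    for _ in range(n_lines):
        if len(lys) == 0:
            break
        i = rng.integers(0, len(lys))
        y0, x0 = lys[i], lxs[i]
        length = rng.uniform(0.15, 0.45) * extent
        ang = rng.uniform(0, np.pi)
        y1 = y0 + length * np.sin(ang)
        x1 = x0 + length * np.cos(ang)
        t = np.linspace(0, 1, int(2 * length) + 2)
        yy = np.clip(np.rint(y0 + t * (y1 - y0)).astype(int), 0, h - 1)
        xx = np.clip(np.rint(x0 + t * (x1 - x0)).astype(int), 0, w - 1)
        stroke = np.zeros((h, w), dtype=bool)
        stroke[yy, xx] = True
        stroke = binary_dilation(stroke, disk_selem(1))  # 3 px wide
        out[stroke] = line_value

    # homogeneous patches in the upper half; the last one is guaranteed big
    radii = rng.uniform(0.12, 0.22, n_blobs) * extent
    radii[-1] = max(radii[-1], 0.25 * extent, 20.0)
    for bi, radius in enumerate(radii):
        allowed = binary_erosion(inner & (np.arange(h)[:, None] < cy0),
                                 disk_selem(int(np.ceil(radius * 1.3)) + 2))
        ays, axs = np.nonzero(allowed)
        if len(ays) == 0:  # fall back to anywhere the blob fits
            allowed = binary_erosion(inner, disk_selem(int(np.ceil(radius * 1.3)) + 2))
            ays, axs = np.nonzero(allowed)
        if len(ays) == 0:
            continue
        i = rng.integers(0, len(ays))
        py, px = _blob(rng, axs[i], ays[i], radius)
        rr, cc = draw_polygon(py, px, shape=(h, w))
        out[rr, cc] = blob_value + 10 * bi
    return out


def _bars(rng, inner, spacings=(2, 3, 4, 6, 8), bar_len_frac: float = 0.3,
          value: float = 255.0):
    h, w = inner.shape
    ys, xs = np.nonzero(inner)
    cy0, cx0 = int(ys.mean()), int(xs.mean())
    extent = int(0.5 * (np.ptp(ys) + np.ptp(xs)) / 2.0)
    bar_len = max(8, int(bar_len_frac * extent))
    out = np.zeros((h, w))
    x = cx0 - extent // 2
    for s in spacings:
        for rep in range(3):
            col = x + rep * 2 * s
            if col >= w:
                break
            out[max(0, cy0 - bar_len):cy0 + bar_len, col:col + s] = value
        x += 3 * 2 * s + 6
    out[~inner] = 0.0
    return out


# ---------------------------------------------------------------------------
# persistence and validation
# ---------------------------------------------------------------------------

def save_phantom(pair: PhantomPair, directory: str | Path) -> None:
    """Write ``surface.png``, ``structure.png`` and a metadata sidecar."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    _io.write_gray(d / "surface.png", pair.surface)
    _io.write_gray(d / "structure.png", pair.structure)
    (d / "phantom.json").write_text(json.dumps(
        {"rotation_center": list(pair.rotation_center)}))


def load_phantom(surface_path: str | Path, structure_path: str | Path,
                 rotation_center=None) -> PhantomPair:
    """Load and validate a phantom pair from 8-bit images.

    The surface must trace to a single closed curve and the structure support
    must lie strictly inside it; the rotation center defaults to the image
    center when not given (a ``phantom.json`` sidecar next to the surface
    image overrides the default).
    """
    surface = _io.read_gray(surface_path)
    structure = _io.read_gray(structure_path)
    if surface.shape != structure.shape:
        raise ValueError("surface and structure dimensions differ")
    trace_contour(surface)  # raises GeometryError on open/multiple curves
    filled = binary_fill_holes(surface > 0)
    if np.any((structure > 0) & ~filled):
        raise ValueError("structure has support outside the sample boundary")
    if rotation_center is None:
        sidecar = Path(surface_path).parent / "phantom.json"
        if sidecar.exists():
            rotation_center = tuple(json.loads(sidecar.read_text())["rotation_center"])
    return PhantomPair(surface=surface, structure=structure,
                       rotation_center=rotation_center)


def make_phantom(seed: int, size=DEFAULT_SIZE, pattern: str = "logo_like",
                 boundary_params: dict | None = None,
                 structure_params: dict | None = None) -> PhantomPair:
    """Convenience: boundary + structure with a shared seed."""
    boundary = generate_boundary(seed, size=size, **(boundary_params or {}))
    structure = generate_structure(boundary, pattern=pattern, seed=seed + 1,
                                   **(structure_params or {}))
    return PhantomPair(surface=boundary, structure=structure)
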