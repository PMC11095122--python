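# Methods

## The imaging model

Scanning laser optical tomography (SLOT) acquires parallel-beam projections
of a rotating specimen: a focused "needle" beam scans laterally across the
sample, the fluorescence excited along the beam path is collected without
directional selectivity, and the transmitted intensity is measured behind
the sample. Several hundred projections over a full rotation form a
sinogram per imaging plane, which filtered back projection (FBP) turns into
a cross-section. The model implemented here is strictly two-dimensional:
SLOT volumes are stacks of independently reconstructed thin planes, and
out-of-plane refraction (which occurs when the specimen wall is not
perpendicular to the imaging plane) is not representable, nor correctable,
in this geometry.

The specimen is described by two rasters: an *input surface* (a one-pixel
closed boundary curve) and an *input structure* (the fluorophore
distribution, nonzero only inside the boundary). The immersion medium has
refractive index `n1`, the specimen a homogeneous `n2`; both are accepted
anywhere in (1, 99].

### Ray propagation

For each projection angle the sample is digitally rotated (bilinear
resampling of the rasters; exact rotation of the traced boundary polyline
and its normals) and one vertical ray is cast per image column:

1. The entry point is the topmost intersection of the scan line with the
   boundary polyline (subpixel, by segment intersection). The incident
   angle `alpha_1` is measured between the ray and the outward surface
   normal at the nearer polyline vertex.
2. The surface normal comes from local polynomial regression: a polynomial
   of configurable order (default 2) is least-squares fitted to a
   configurable number of neighboring contour vertices (default 7) in a
   locally rotated frame, so vertical tangents remain well conditioned.
3. Snell's law `n1 sin(alpha_1) = n2 sin(beta)` refracts the ray once at
   entry. If `(n1/n2) sin(alpha_1) > 1` the ray undergoes total internal
   reflection (TIR), never enters, and contributes a dark sinogram sample.
4. Inside the specimen the ray runs straight (homogeneous `n2`; internal
   refraction is outside the model) in steps of one pixel, accumulating
   bilinear samples of the structure raster until the interior test fails
   at the backside. Exit-side deflection is irrelevant for the isotropically
   collected fluorescence signal and is not modeled.

The sum of samples is the sinogram value at (projection, column). With
`n1 = n2` this reduces exactly to a discrete Radon transform; the package
carries an independent straight-ray projector (rotate + column-sum) as an
oracle, and the matched-index simulator agrees with it to floating-point
accuracy because the one-pixel vertical marching sum telescopes into a
column sum.

### Sinogram rearrangement

Refraction does not destroy the information of the expected (unrefracted)
beam path — over a full rotation that chord *is* acquired, just at a
different projection angle and lateral position. For an entry point with
incident angle `alpha_1`, rotating the sample by

    delta_theta = arcsin((n2/n1) sin(alpha_1)) - alpha_1

brings the refracted real path at `theta_1 = theta_0 + delta_theta` into
coincidence with the expected vertical path at `theta_0`. Derivation: after
rotating the entry point (and its normal) by `delta`, the incident angle
becomes `alpha_1 - sign(psi) * delta` where `psi` is the signed incident
angle; requiring the refracted angle to equal `alpha_1` (the material-frame
direction of the expected chord) and applying Snell's law gives the closed
form above, with the rotation applied as `-sign(psi) * delta_theta` — the
two sides of a convex silhouette rotate opposite ways. Both the index ratio
and the sign convention are pinned by a brute-force oracle in the test
suite that scans sample rotations and ray-traces the real path until it
coincides with the expected one; the closed form matches the search to
better than 0.1 degrees over 200 random configurations with mismatch up to
0.15. A debug flag exposes the formula with the reciprocal ratio; it fails
the same oracle and exists only for comparison.

The rearranged sinogram is gathered by bilinear interpolation:
`out[p, w] = in[p + v, w + h]` with the vertical offset
`v = delta_theta * P / 360` rows (2.2... rows per degree at the typical 800
projections) wrapped modulo `P` — a full-rotation sinogram is periodic in
angle — and the horizontal offset `h` the x-displacement of the entry point
rotated by `delta_theta` about the rotation center. Samples without a
correspondence (`(n2/n1) sin(alpha_1) > 1`, which happens at the outer
columns when `n2 > n1`) or whose source column leaves the sinogram are
written as zero rather than clamped: clamping would fabricate data. The
entry-point table reports the fraction of such unrecoverable samples.

The per-projection entry geometry is computed by ray propagation on the
rotated surface, not analytically, so any closed boundary shape works. The
surface may be the known phantom boundary or a *preemptive surface*
extracted from an uncorrected reconstruction (Otsu threshold, largest
component, hole filling, one-pixel rim): the silhouette reconstructs
correctly even from a distorted sinogram.

What the correction cannot do: recover TIR-dark samples, recover the outer
columns lost when `n2 > n1`, or correct refraction *inside* an
inhomogeneous specimen.

### Reconstruction

FBP in parallel geometry via scikit-image's inverse Radon transform (ramp
filter by default, Shepp-Logan or unfiltered available): per-row
frequency-domain filtering with zero padding, bilinear back-projection,
standard `pi/(2P)` weighting. All 360 degrees are used directly without
180-degree folding, because refraction breaks conjugate-ray symmetry for
uncorrected data; one code path serves both. 8-bit export scales by min-max
over the inscribed circle, keeping the corner ring artifacts out of the
scaling window. For even sinogram widths the reconstruction grid center
sits half a pixel from the simulator's rotation center ((W-1)/2 vs W/2);
the offset is identical for every reconstruction of the same width, so all
image comparisons are unaffected.

### Choosing an unknown specimen RI

`ri_sweep` corrects one sinogram with a grid of candidate specimen RIs and
reconstructs each. The user comparison of the reconstructions is the
intended selection method; each result additionally carries an advisory
*conjugate-consistency* score: in a refraction-free parallel acquisition
the projection at `theta + 180 deg` is the mirror of the one at `theta`, so
the negative RMS row-vs-mirrored-conjugate-row difference of the corrected
sinogram peaks (approaches zero) at the true RI. In self-consistency
experiments on simulated data the score identifies the true RI within one
0.01 grid step in both mismatch directions. A focus-style score (variance
of the Laplacian) was evaluated first and rejected: corrections with a too
small candidate RI generate high-frequency streak artifacts that such a
score rewards, making it monotone in the candidate instead of peaked at
the truth.

## Metrics

* **APD** — mean absolute per-pixel 8-bit difference over a region of
  interest; 0 is a perfect match, 255 the maximum (white vs. black).
* **SSIM** — structural similarity with the canonical constants
  (K1 = 0.01, K2 = 0.03, Gaussian window sigma = 1.5, L = 255); the
  windowed map is averaged over the ROI. Cross-checked in the tests against
  an independently written Gaussian-weighted implementation to 1e-6.
* **ROIs** — the whole-sample ROI is the filled silhouette dilated by 5 px
  ("the object area and a few pixels around it"); the central ROI is the
  silhouette scaled to 0.5 of its size about the rotation center. Both
  keep FBP corner artifacts out of the scores. The exact dilation and
  central extent are not prescribed anywhere authoritative; 5 px and 0.5
  are this package's defaults and are configurable.
* Quality curves always use the matched-RI reconstruction of the same
  phantom as the reference image.

## Synthetic data

No real SLOT measurements are available, so all inputs are generated:

* **Boundary** — `radius(phi) = R (1 + sum_k a_k cos(k phi + phi_k))` with
  up to 6 harmonics, amplitudes drawn from the seed, decaying as `1/k` and
  normalized so their sum equals the irregularity parameter (default 0.12,
  giving the intended "potato" rather than a perfect circle). Default
  frame 650x688 to match the reference phantom resolution; desk-scale
  experiments use 256x256.
* **logo_like structure** — filled homogeneous polygonal patches (upper
  half) next to 2–3 px strokes (lower half): large constant areas plus
  small precise features, the two regimes that distinguish contrast loss
  from resolution loss.
* **beads structure** — disks at uniform-random interior positions,
  emulating fluorescent polystyrene beads in an agarose cylinder. The bead
  *demo* places beads deterministically on rings at 0.15/0.4/0.6/0.85 of
  the silhouette radius so per-bead shape statistics are well defined, uses
  bead radius 1.5 px inside a 160 px silhouette (tiny beads in a large
  cylinder, as in the real sample), the silicone-oil/agarose index pair
  1.422/1.335, and 800 projections.
* **bars structure** — line-pair groups with decreasing spacing, for
  resolution checks.

What the generator does not emulate: detector noise, Fresnel reflection
losses, surface scattering (the real-measurement intensity drop-off toward
the sample rim), beam-waist effects, or 3D out-of-plane geometry. Passing
tests therefore demonstrate the geometric correction under ideal 2D optics,
not end-to-end performance on a physical instrument.

## Study conditions and problem sizes

Desk-scale experiments run a 256x256 phantom at 400 projections (the sweep
over specimen RI 1.30–1.50 at medium 1.4 completes in about a minute per
grid point); the reference geometry 650x688 / 800 projections is available
as a preset. At 256x256, a mismatch of ±0.02 displaces rays by less than a
pixel, so the corrected and uncorrected reconstructions nearly tie there —
the correction's advantage grows with mismatch and with frame size. The
bead demo runs at 384x384 / 800 projections. Simulations are fully
deterministic given the seed; repeated sweeps produce byte-identical CSVs.

## Numerical choices

* Contour tracing: the filled boundary is smoothed (Gaussian sigma = 2) and
  the 0.5 level set traced to subpixel precision; this sigma reproduces the
  curvature of a radius-45 circle to better than 1% where sigma = 1 leaves
  more than 50% quantization-ripple bias in local curvature estimates.
  Winding is normalized; normals are oriented by an interior probe.
* Marching uses the rotated filled-silhouette field sampled bilinearly and
  thresholded at one half as the interior test (subpixel-stable exit); the
  final partial step is not fractionally weighted, matching the fixed-step
  scheme.
* Rank-deficient slope fits fall back to order 1 with a warning.
* Rearrangement interpolates bilinearly with row wraparound and column
  invalidation, as above; sinogram values stay float throughout and are
  quantized to 8 bits only at export or metric time.
* Degenerate inputs (empty surface, open or fragmented boundary, all-zero
  reconstruction, empty ROI) raise descriptive errors rather than
  propagating garbage.

## Known limitations

* Purely 2D; no out-of-plane refraction.
* One refraction event per ray (entry only); exit-side deflection of the
  transmission signal is not modeled.
* The correction presumes a homogeneous specimen RI and a correct surface.
* Raster rotation by bilinear resampling slightly smooths sharp features;
  at desk scale this is the dominant cost of the rearrangement at very
  small mismatches.
* The conjugate-consistency score is advisory; with very sparse structure
  or heavy TIR loss its peak flattens.
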