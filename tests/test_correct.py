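"""Tests of the sinogram-rearrangement correction.

The closed-form digital-rotation angle is validated against a brute-force
geometric search oracle: trace the refracted real beam path on a circle at
scanned sample rotations and find the rotation at which it coincides with
the unrefracted expected path.
"""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from slotsim import (
    GeometryError,
    OpticalConfig,
    PhantomPair,
    build_entry_table,
    delta_theta,
    fbp,
    generate_boundary,
    horizontal_offset,
    rearrange_sinogram,
    ri_sweep,
    simulate_sinogram,
    surface_from_reconstruction,
    trace_contour,
    vertical_offset,
)
from slotsim.correct import conjugate_consistency
from slotsim.raytrace import rotate_points, rotate_vectors

# ---------------------------------------------------------------------------
# brute-force geometric oracle
# ---------------------------------------------------------------------------

CENTER = np.array([63.5, 63.5])
RADIUS = 40.0


def _refract(d0, normal, n1, n2):
    # vector Snell, written independently of the package's refraction code
    c1 = -np.dot(d0, normal)
    eta = n1 / n2
    s2 = eta ** 2 * (1 - c1 ** 2)
    if s2 > 1:
        return None
    return eta * np.asarray(d0) + (eta * c1 - np.sqrt(1 - s2)) * np.asarray(normal)


def _residual_deg(rot_deg, entry, n1, n2):
    """Angle between the real refracted path at a candidate sample rotation
    (mapped back to the reference frame) and the expected vertical path."""
    moved = rotate_points(entry, rot_deg, CENTER)
    normal = (moved - CENTER) / np.linalg.norm(moved - CENTER)
    d_t = _refract((0.0, 1.0), normal, n1, n2)
    if d_t is None:
        return None
    back = rotate_vectors(d_t, -rot_deg)
    return np.degrees(np.arctan2(back[0], back[1]))


def search_delta_theta(entry, n1, n2, span=12.0, tol=1e-4):
    """Scan-and-bisect the sample rotation that straightens the real path."""
    grid = np.linspace(-span, span, 481)
    vals = np.array([np.inf if (r := _residual_deg(g, entry, n1, n2)) is None
                     else r for g in grid])
    finite = np.isfinite(vals)
    sign_change = finite[:-1] & finite[1:] & (np.sign(vals[:-1]) != np.sign(vals[1:]))
    if not sign_change.any():
        return None
    i = int(np.argmax(sign_change))
    lo, hi = grid[i], grid[i + 1]
    flo = _residual_deg(lo, entry, n1, n2)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        fmid = _residual_deg(mid, entry, n1, n2)
        if fmid is None:
            break
        if np.sign(fmid) == np.sign(flo):
            lo, flo = mid, fmid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def signed_formula_delta(psi, n1, n2):
    """The package's signed digital rotation for a signed incident angle."""
    mag = delta_theta(n1, n2, abs(psi))
    return None if not np.isfinite(mag) else -np.sign(psi) * mag


class TestDeltaTheta:
    def test_matched_media_and_normal_incidence_are_zero(self):
        assert delta_theta(1.4, 1.4, 0.73) == 0.0
        assert delta_theta(1.5, 1.2, 0.0) == 0.0

    def test_nonexistent_correspondence_flags_invalid(self):
        # n2 > n1 at steep incidence: the datum was never recorded
        assert np.isnan(delta_theta(1.0 + 1e-9, 1.5, 1.4))

    def test_formula_matches_geometric_search_oracle(self):
        rng = np.random.default_rng(42)
        checked = 0
        worst = 0.0
        while checked < 200:
            n1 = rng.uniform(1.25, 1.55)
            n2 = n1 + rng.uniform(-0.15, 0.15)
            if n2 <= 1.0:
                continue
            phi = rng.uniform(np.pi + 0.2, 2 * np.pi - 0.2)  # upper semicircle
            entry = CENTER + RADIUS * np.array([np.cos(phi), np.sin(phi)])
            normal = (entry - CENTER) / RADIUS
            psi = np.arctan2(-normal[0], -normal[1])
            predicted = signed_formula_delta(psi, n1, n2)
            if predicted is None or abs(predicted) > 10:
                continue
            searched = search_delta_theta(entry, n1, n2)
            if searched is None:
                continue
            worst = max(worst, abs(searched - predicted))
            checked += 1
        assert worst <= 0.1

    def test_inverted_ratio_debug_variant_disagrees(self):
        a1 = np.deg2rad(30)
        good = delta_theta(1.4, 1.3, a1)
        bad = delta_theta(1.4, 1.3, a1, invert_ratio=True)
        entry = CENTER + RADIUS * np.array(
            [np.sin(a1), -np.cos(a1)])  # upper-right, psi = -a1
        searched = search_delta_theta(entry, 1.4, 1.3)
        assert searched == pytest.approx(good, abs=0.01)
        assert abs(searched - bad) > 0.5

    @given(st.floats(1.05, 2.0), st.floats(0.0, 1.2))
    def test_matched_is_exactly_zero(self, n, alpha):
        assert delta_theta(n, n, alpha) == 0.0


class TestOffsets:
    def test_typical_sampling_rate_factor(self):
        # 800 projections over 360 degrees: 1 degree = 2.2... rows
        assert vertical_offset(1.0, 800, 360.0) == pytest.approx(20 / 9,
                                                                 abs=1e-12)

    def test_zero_angle_zero_offset(self):
        assert vertical_offset(0.0, 800) == 0.0

    def test_linearity_and_wrap_rule(self):
        off = vertical_offset(-1.0, 400, 360.0)
        assert off == pytest.approx(-10 / 9, abs=1e-12)
        assert off % 400 == pytest.approx(400 - 10 / 9, abs=1e-9)

    def test_horizontal_offset_fixed_point_and_quarter_turn(self):
        assert horizontal_offset((50.0, 50.0), 73.0, (50.0, 50.0)) == 0.0
        assert horizontal_offset((80.0, 50.0), 90.0, (50.0, 50.0)) == \
            pytest.approx(-30.0, abs=1e-9)
        assert horizontal_offset((80.0, 50.0), 0.0, (50.0, 50.0)) == 0.0


class TestRearrangement:
    def test_zero_mismatch_is_identity(self, logo_pair_small):
        cfg = OpticalConfig(n_medium=1.4, n_sample=1.4, n_projections=60)
        sino = simulate_sinogram(logo_pair_small, cfg)
        table = build_entry_table(logo_pair_small.surface, cfg,
                                  center=logo_pair_small.rotation_center)
        assert np.all(table.delta_theta[table.valid] == 0.0)
        out = rearrange_sinogram(sino, table)
        scale = 255.0 / sino.values.max()
        assert np.max(np.abs(out.values - sino.values)) * scale <= 1.0

    def test_simulator_table_matches_surface_built_table(self, logo_pair_small):
        cfg = OpticalConfig(1.4, 1.3, n_projections=12)
        _, table = simulate_sinogram(logo_pair_small, cfg, return_table=True)
        ref = build_entry_table(logo_pair_small.surface, cfg,
                                center=logo_pair_small.rotation_center)
        assert np.array_equal(table.valid, ref.valid)
        assert np.allclose(table.delta_theta, ref.delta_theta,
                           equal_nan=True, atol=1e-9)
        assert np.allclose(table.entry_y, ref.entry_y, equal_nan=True,
                           atol=1e-9)

    def test_shape_mismatch_rejected(self, logo_pair_small):
        cfg = OpticalConfig(n_projections=60)
        sino = simulate_sinogram(logo_pair_small, cfg)
        cfg2 = OpticalConfig(n_projections=50)
        table = build_entry_table(logo_pair_small.surface, cfg2,
                                  center=logo_pair_small.rotation_center)
        with pytest.raises(ValueError, match="shape"):
            rearrange_sinogram(sino, table)

    def test_correction_improves_similarity_to_matched(self, logo_pair_small):
        from slotsim import make_rois, ssim
        from slotsim.recon import recon_to_uint8

        P = 120
        matched = recon_to_uint8(fbp(simulate_sinogram(
            logo_pair_small, OpticalConfig(1.4, 1.4, P)))).astype(float)
        cfg = OpticalConfig(1.4, 1.3, P)
        sino = simulate_sinogram(logo_pair_small, cfg)
        table = build_entry_table(logo_pair_small.surface, cfg,
                                  center=logo_pair_small.rotation_center)
        corrected = rearrange_sinogram(sino, table)
        whole, _ = make_rois(logo_pair_small.surface)
        s_un = ssim(recon_to_uint8(fbp(sino)).astype(float), matched, whole)
        s_co = ssim(recon_to_uint8(fbp(corrected)).astype(float), matched,
                    whole)
        assert s_co > s_un

    def test_outer_columns_become_invalid_when_sample_denser(
            self, logo_pair_small):
        fractions = []
        for n2 in (1.45, 1.50, 1.55):
            cfg = OpticalConfig(n_medium=1.4, n_sample=n2, n_projections=24)
            table = build_entry_table(logo_pair_small.surface, cfg,
                                      center=logo_pair_small.rotation_center)
            fractions.append(table.invalid_fraction())
        assert fractions[0] > 0
        assert fractions == sorted(fractions)

    def test_entry_table_csv_export(self, tmp_path, logo_pair_small):
        import pandas as pd

        cfg = OpticalConfig(1.4, 1.3, n_projections=8)
        table = build_entry_table(logo_pair_small.surface, cfg,
                                  center=logo_pair_small.rotation_center)
        table.to_csv(tmp_path / "t.csv")
        df = pd.read_csv(tmp_path / "t.csv")
        assert len(df) == 8 * 128
        assert {"projection", "column", "alpha_rad",
                "delta_theta_deg"} <= set(df.columns)


class TestPreemptiveSurface:
    def test_disk_surface_recovered_within_two_pixels(self, circle_pair):
        cfg = OpticalConfig(1.4, 1.4, 120)
        rec = fbp(simulate_sinogram(circle_pair, cfg))
        surf = surface_from_reconstruction(rec)
        pts = trace_contour(surf).points
        r = np.hypot(pts[:, 0] - 63.5, pts[:, 1] - 63.5)
        # structure disk has radius ~40; its boundary must come back within 2 px
        assert np.all(np.abs(r - np.median(r)) <= 2.0)

    def test_empty_reconstruction_rejected(self):
        with pytest.raises(GeometryError):
            surface_from_reconstruction(np.zeros((64, 64)))

    def test_mismatched_reconstruction_still_yields_closed_surface(
            self, circle_pair):
        cfg = OpticalConfig(1.4, 1.3, 120)
        rec = fbp(simulate_sinogram(circle_pair, cfg))
        surf = surface_from_reconstruction(rec)
        trace_contour(surf)  # raises if open or fragmented


@pytest.fixture(scope="module")
def mismatch_sim():
    pair = _small_logo()
    cfg = OpticalConfig(1.4, 1.30, 120)
    return pair, cfg, simulate_sinogram(pair, cfg)


class TestRISweep:
    def test_single_true_candidate_equals_pipeline(self, mismatch_sim):
        pair, cfg, sino = mismatch_sim
        res = ri_sweep(sino, pair.surface, 1.4, [1.30], config=cfg,
                       center=pair.rotation_center)
        table = build_entry_table(pair.surface, cfg,
                                  center=pair.rotation_center)
        direct = fbp(rearrange_sinogram(sino, table))
        assert np.array_equal(res[0].recon.pixels, direct.pixels)

    def test_medium_candidate_reduces_to_plain_fbp(self, mismatch_sim):
        pair, cfg, sino = mismatch_sim
        res = ri_sweep(sino, pair.surface, 1.4, [1.4], config=cfg,
                       center=pair.rotation_center)
        plain = fbp(sino)
        scale = 255.0 / np.abs(plain.pixels).max()
        assert np.max(np.abs(res[0].recon.pixels - plain.pixels)) * scale <= 1.0

    def test_consistency_score_peaks_at_true_index(self, mismatch_sim):
        pair, cfg, sino = mismatch_sim
        candidates = [round(1.26 + 0.01 * k, 2) for k in range(9)]  # 1.26..1.34
        res = ri_sweep(sino, pair.surface, 1.4, candidates, config=cfg,
                       center=pair.rotation_center)
        best = max(res, key=lambda r: r.score)
        assert best.n_sample == pytest.approx(1.30, abs=0.011)

    def test_empty_candidate_list_rejected(self, mismatch_sim):
        pair, cfg, sino = mismatch_sim
        with pytest.raises(ValueError):
            ri_sweep(sino, pair.surface, 1.4, [], config=cfg)


def _small_logo():
    from slotsim import make_phantom

    return make_phantom(seed=3, size=(128, 128), pattern="logo_like",
                        boundary_params=dict(mean_radius=48,
                                             irregularity=0.08))


class TestConjugateConsistency:
    def test_matched_sinogram_nearly_symmetric(self, matched_sino_small):
        sino, _ = matched_sino_small
        assert conjugate_consistency(sino) > -0.02

    def test_mismatch_breaks_symmetry(self, logo_pair_small,
                                      matched_sino_small):
        sino_m, _ = matched_sino_small
        sino_x = simulate_sinogram(logo_pair_small,
                                   OpticalConfig(1.4, 1.3, 90))
        assert conjugate_consistency(sino_x) < conjugate_consistency(sino_m)
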