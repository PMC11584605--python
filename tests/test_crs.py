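"""Cartilage roughness pipeline: closed-form and planted-truth checks."""

import numpy as np
import pytest

from oamorph.crs import (
    CondyleROI,
    CRSConfig,
    HeightFieldSurface,
    compute_crs,
    compute_roughness_map,
    estimate_local_orientation,
    extract_cartilage_surface,
    fit_reference_surface,
)
from oamorph.errors import EmptyROIError, SurfaceQualityError, UnderdeterminedFitError
from oamorph.phantoms import default_condyle_coeffs, make_condyle_phantom
from oamorph.volumes import ImageVolume


def _grid_surface(n=80, spacing=4.5, fn=lambda x, y: np.zeros_like(x)):
    x = np.arange(n) * spacing
    y = np.arange(n) * spacing
    xg, yg = np.meshgrid(x, y)
    return HeightFieldSurface(x_um=x, y_um=y, z_um=fn(xg, yg))


class TestSurfaceExtraction:
    def test_flat_slab_surface_recovered_within_half_voxel(self):
        h = 4.5
        data = np.zeros((60, 30, 30), np.float32)
        data[:51] = 100.0  # top face at voxel 50 -> z = 50.5 * h (upper edge)
        vol = ImageVolume(data, h)
        surf = extract_cartilage_surface(vol)
        np.testing.assert_allclose(surf.z_um, 50.5 * h, atol=0.5 * h)

    def test_polynomial_condyle_surface_subvoxel_accuracy(self):
        ph = make_condyle_phantom(extent_um=(450, 450), margin_px=4)
        surf = extract_cartilage_surface(ph.volume, ph.roi)
        truth = ph.ground_truth["surface_z_um"]
        err = surf.z_um - truth
        rms = np.sqrt(np.nanmean(err[ph.roi.mask_xy] ** 2))
        assert rms < 0.5 * 4.5

    def test_pure_background_raises_quality_error(self):
        vol = ImageVolume(np.zeros((10, 10, 10), np.float32), 4.5)
        with pytest.raises(SurfaceQualityError):
            extract_cartilage_surface(vol)

    def test_roi_shape_mismatch_raises(self):
        vol = ImageVolume(np.ones((5, 8, 8), np.float32), 4.5)
        roi = CondyleROI("medial tibia", np.ones((4, 4), bool))
        with pytest.raises(EmptyROIError):
            extract_cartilage_surface(vol, roi)


class TestLocalOrientation:
    def test_horizontal_plane_gives_vertical_normals(self):
        surf = _grid_surface(fn=lambda x, y: np.full_like(x, 33.0))
        surf = estimate_local_orientation(surf)
        np.testing.assert_allclose(surf.normals[..., 2], 1.0, atol=1e-12)
        np.testing.assert_allclose(surf.normals[..., 0], 0.0, atol=1e-12)

    def test_inclined_plane_angle_matches_closed_form(self):
        slope = np.tan(np.radians(10.0))
        surf = _grid_surface(fn=lambda x, y: x * slope)
        surf = estimate_local_orientation(surf)
        angle = np.degrees(np.arccos(surf.normals[..., 2]))
        np.testing.assert_allclose(angle, 10.0, atol=1e-6)

    def test_sinusoid_normals_match_differential_geometry(self):
        lam, a, spacing = 400.0, 10.0, 2.0
        w = 2 * np.pi / lam
        surf = _grid_surface(n=200, spacing=spacing, fn=lambda x, y: a * np.sin(w * x))
        surf = estimate_local_orientation(surf, neighborhood_area_um2=28.0)
        xg, _ = np.meshgrid(surf.x_um, surf.y_um)
        gx = a * w * np.cos(w * xg)
        n_true = np.stack([-gx, np.zeros_like(gx), np.ones_like(gx)], axis=-1)
        n_true /= np.linalg.norm(n_true, axis=-1, keepdims=True)
        interior = np.zeros(xg.shape, bool)
        interior[3:-3, 3:-3] = True
        dot = np.sum(surf.normals * n_true, axis=-1)[interior]
        angle_err = np.degrees(np.arccos(np.clip(dot, -1, 1)))
        max_true_angle = np.degrees(np.arctan(a * w))
        assert np.max(angle_err) < 0.01 * max_true_angle

    def test_sparse_nodes_expand_window_or_drop(self):
        z = np.full((9, 9), np.nan)
        z[::2, ::2] = 5.0  # checkerboard of valid nodes
        surf = HeightFieldSurface(np.arange(9.0), np.arange(9.0), z)
        surf = estimate_local_orientation(surf, neighborhood_area_um2=1.0)
        assert np.isfinite(surf.normals[4, 4]).all()
        assert np.isnan(surf.normals[1, 1]).all()  # invalid node stays NaN


class TestReferenceFit:
    def test_exact_degree5_recovered_in_one_iteration(self):
        rng = np.random.default_rng(11)
        surf = _grid_surface(n=60)
        ref0 = fit_reference_surface(surf)  # establishes scaling on the grid
        coeffs = rng.normal(0, 10, ref0.coefficients.size)
        xg, yg = np.meshgrid(surf.x_um, surf.y_um)
        from oamorph.crs import _exponents

        u = (xg - ref0.x0) / ref0.xs
        v = (yg - ref0.y0) / ref0.ys
        z = sum(c * u**i * v**j for c, (i, j) in zip(coeffs, _exponents(5)))
        surf2 = HeightFieldSurface(surf.x_um, surf.y_um, z)
        ref = fit_reference_surface(surf2)
        assert ref.n_iterations_run == 1
        np.testing.assert_allclose(ref.coefficients, coeffs, rtol=1e-6)

    def test_planted_outliers_excluded_and_coeffs_recovered(self):
        rng = np.random.default_rng(5)
        surf = _grid_surface(n=60)
        ref0 = fit_reference_surface(surf)
        coeffs = rng.normal(0, 10, ref0.coefficients.size)
        xg, yg = np.meshgrid(surf.x_um, surf.y_um)
        from oamorph.crs import _exponents

        u = (xg - ref0.x0) / ref0.xs
        v = (yg - ref0.y0) / ref0.ys
        z = sum(c * u**i * v**j for c, (i, j) in zip(coeffs, _exponents(5)))
        n_out = int(0.01 * z.size)
        flat = rng.choice(z.size, n_out, replace=False)
        z.ravel()[flat] += rng.choice([-1.0, 1.0], n_out) * 10 * z.std()
        surf2 = HeightFieldSurface(surf.x_um, surf.y_um, z)
        ref = fit_reference_surface(surf2)
        excluded = ~ref.included_mask.ravel()[flat]
        assert excluded.all()
        np.testing.assert_allclose(ref.coefficients, coeffs, rtol=1e-3)

    def test_underdetermined_raises(self):
        surf = _grid_surface(n=7)  # 49 nodes < 3 * 21
        with pytest.raises(UnderdeterminedFitError):
            fit_reference_surface(surf)


class TestRoughnessMap:
    def test_self_reference_is_zero(self):
        surf = _grid_surface(n=50, fn=lambda x, y: 0.001 * x + 20.0)
        surf = estimate_local_orientation(surf)
        ref = fit_reference_surface(surf)
        rm = compute_roughness_map(surf, ref)
        assert rm.crs == pytest.approx(0.0, abs=1e-6)

    def test_plane_tilted_against_flat_reference(self):
        surf = _grid_surface(n=50, fn=lambda x, y: np.full_like(x, 7.0))
        surf = estimate_local_orientation(surf)
        ref = fit_reference_surface(surf)
        tilted = _grid_surface(n=50, fn=lambda x, y: x * np.tan(np.radians(7.0)))
        tilted = estimate_local_orientation(tilted)
        rm = compute_roughness_map(tilted, ref)
        np.testing.assert_allclose(rm.theta_deg, 7.0, atol=1e-6)
        assert rm.crs == pytest.approx(7.0, abs=1e-6)

    def test_angles_bounded_and_nonnegative(self):
        ph = make_condyle_phantom(target_mean_angle_deg=5.0, extent_um=(450, 450))
        rm = compute_crs(ph.volume, ph.roi)
        valid = np.isfinite(rm.theta_deg)
        assert (rm.theta_deg[valid] >= 0).all()
        assert (rm.theta_deg[valid] <= 90).all()


class TestPipelineProperties:
    def test_crs_increases_with_bump_amplitude(self):
        crss = []
        for amp in (2.0, 4.0, 8.0):
            ph = make_condyle_phantom(bump_amplitude_um=amp, extent_um=(450, 450))
            crss.append(compute_crs(ph.volume, ph.roi).crs)
        assert crss[0] < crss[1] < crss[2]

    def test_crs_invariant_under_translation_and_axis_relabel(self):
        ph = make_condyle_phantom(
            bump_amplitude_um=4.0, extent_um=(450, 450), seed=2
        )
        base = compute_crs(ph.volume, ph.roi).crs
        shifted = ImageVolume(
            ph.volume.data, ph.volume.voxel_size_um,
            origin_um=ph.volume.origin_um + np.array([90.0, 45.0, 45.0]),
        )
        assert compute_crs(shifted, ph.roi).crs == pytest.approx(base, rel=1e-9)
        swapped = ImageVolume(
            np.transpose(ph.volume.data, (0, 2, 1)), ph.volume.voxel_size_um,
            origin_um=ph.volume.origin_um,
        )
        roi_T = CondyleROI(ph.roi.label, ph.roi.mask_xy.T)
        assert compute_crs(swapped, roi_T).crs == pytest.approx(base, rel=1e-6)

    def test_pipeline_matches_dense_finite_difference_oracle(self):
        """CRS on an analytic-grid surface vs brute-force normals on a 10x
        denser grid of the same analytic surface."""
        from oamorph.phantoms import _surface_and_gradient, analytic_mean_angle

        coeffs = default_condyle_coeffs()
        extent = (450.0, 450.0)
        amp, lam = 5.0, 150.0
        ph = make_condyle_phantom(
            base_coeffs=coeffs, bump_amplitude_um=amp, bump_wavelength_um=lam,
            extent_um=extent,
        )
        crs = compute_crs(ph.volume, ph.roi).crs

        # oracle: finite-difference normals on a 10x refined grid
        h = 0.45
        x = np.arange(0, extent[0], h)
        y = np.arange(0, extent[1], h)
        z, _, _ = _surface_and_gradient(x[None, :], y[:, None], coeffs, extent, amp, lam)
        zb, _, _ = _surface_and_gradient(x[None, :], y[:, None], coeffs, extent, 0.0, 1.0)

        def fd_normals(zz):
            gy, gx = np.gradient(zz, h, h)
            n = np.stack([-gx, -gy, np.ones_like(gx)], -1)
            return n / np.linalg.norm(n, axis=-1, keepdims=True)

        nf, nb = fd_normals(z), fd_normals(zb)
        x0, x1, y0, y1 = ph.ground_truth["roi_bounds_um"]
        sel = ((x[None, :] >= x0) & (x[None, :] <= x1)
               & (y[:, None] >= y0) & (y[:, None] <= y1))
        dot = np.clip(np.sum(nf * nb, -1), -1, 1)
        oracle = float(np.degrees(np.arccos(dot))[sel].mean())
        assert crs == pytest.approx(oracle, rel=0.10)
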