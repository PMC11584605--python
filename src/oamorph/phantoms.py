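"""Synthetic phantoms with exact ground truth for every analysis module.

Each generator is deterministic given its parameters and seed, and returns
the data together with a ground-truth record, so every pipeline can be
exercised as a round trip against known truth:

* condyle phantoms — a degree-5 polynomial base surface plus a controlled
  sinusoidal bump field, voxelized with exact column partial volume (xy
  supersampled); truth = analytic mean angular deviation by dense quadrature;
* trabecular phantoms — parallel-plate stacks and orthogonal rod lattices of
  known BV/TV, Tb.Th, Tb.Sp (closed-form volume fractions);
* histology phantoms — seeded non-overlapping nuclei and collagen blob
  fields synthesized through the same stain-OD model the analyzers invert;
* fluorescence phantoms — per-class cell counts with marker disks around
  Hoechst nuclei, plus a lining/sublining annotation;
* load curves — linear-elastic ramp with a defined failure peak and
  optional load-cell ceiling;
* gait cohorts — longitudinal sessions with a planted injected-limb deficit
  and run-speed variations whose selected-run mean is controlled.

Intensity model for uCT phantoms: two levels (tissue/background) plus
optional Gaussian noise; the default is noiseless, emulating the high
contrast of PTA-stained cartilage against air.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial import polynomial as P
from scipy.optimize import brentq

from .crs import CondyleROI
from .gait import GaitSession
from .histology import MASSON_RGB_FROM_STAINS, SynoviumAnnotation
from .mechanics import LoadDisplacementCurve
from .volumes import BinaryMask, ImageVolume, SectionImage

__all__ = [
    "PhantomResult",
    "default_condyle_coeffs",
    "analytic_mean_angle",
    "amplitude_for_mean_angle",
    "make_condyle_phantom",
    "make_slab_phantom",
    "make_cylinder_phantom",
    "make_plate_phantom",
    "rod_lattice_volume_fraction",
    "make_rod_lattice_phantom",
    "make_histology_phantom",
    "make_trichrome_phantom",
    "make_fluorescence_phantom",
    "make_load_curve",
    "make_gait_cohort",
    "make_pam_cohort",
]


@dataclass
class PhantomResult:
    """A generated phantom: payload object(s) plus its ground-truth record."""

    kind: str
    params: dict
    ground_truth: dict
    seed: int | None = None
    volume: ImageVolume | None = None
    mask: BinaryMask | None = None
    roi: object | None = None
    section: SectionImage | None = None
    annotation: SynoviumAnnotation | None = None
    curve: LoadDisplacementCurve | None = None
    sessions: dict | None = None
    table: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# condyle surface phantoms


def default_condyle_coeffs(dome_height_um: float = 120.0,
                           base_height_um: float = 60.0) -> np.ndarray:
    """A gentle elliptic dome z(u, v) = base + dome*(1 - (u^2 + v^2)/2) on the
    scaled domain u, v in [-1, 1]; total degree 2 (well inside degree 5)."""
    c = np.zeros((6, 6))
    c[0, 0] = base_height_um + dome_height_um
    c[2, 0] = -dome_height_um / 2.0
    c[0, 2] = -dome_height_um / 2.0
    return c


def _surface_and_gradient(x_um, y_um, base_coeffs, extent_um,
                          bump_amplitude_um, bump_wavelength_um):
    """z(x, y) and its analytic gradient for base + sinusoidal bump field."""
    lx, ly = extent_um
    x_um, y_um = np.broadcast_arrays(np.asarray(x_um, float), np.asarray(y_um, float))
    u = 2.0 * x_um / lx - 1.0
    v = 2.0 * y_um / ly - 1.0
    c = np.asarray(base_coeffs, dtype=float)
    z = P.polyval2d(u, v, c)
    gx = P.polyval2d(u, v, P.polyder(c, axis=0)) * (2.0 / lx)
    gy = P.polyval2d(u, v, P.polyder(c, axis=1)) * (2.0 / ly)
    if bump_amplitude_um:
        w = 2.0 * np.pi / bump_wavelength_um
        sx, cx = np.sin(w * np.asarray(x_um)), np.cos(w * np.asarray(x_um))
        sy, cy = np.sin(w * np.asarray(y_um)), np.cos(w * np.asarray(y_um))
        z = z + bump_amplitude_um * sx * sy
        gx = gx + bump_amplitude_um * w * cx * sy
        gy = gy + bump_amplitude_um * w * sx * cy
    return z, gx, gy


def analytic_mean_angle(
    base_coeffs,
    bump_amplitude_um: float,
    bump_wavelength_um: float,
    extent_um: tuple[float, float],
    roi_bounds_um: tuple[float, float, float, float] | None = None,
    n_quad: int = 600,
) -> float:
    """Mean angular deviation (deg) between the bumped surface and the base
    polynomial, by dense gradient quadrature over the ROI (evaluated in row
    blocks so refined grids stay within memory)."""
    lx, ly = extent_um
    x0, x1, y0, y1 = roi_bounds_um or (0.0, lx, 0.0, ly)
    xq = np.linspace(x0, x1, n_quad)
    yq = np.linspace(y0, y1, n_quad)
    total = 0.0
    block = max(1, int(2e6 // n_quad))
    for start in range(0, n_quad, block):
        yb = yq[start : start + block][:, None]
        xb = xq[None, :]
        _, gx_f, gy_f = _surface_and_gradient(
            xb, yb, base_coeffs, extent_um, bump_amplitude_um, bump_wavelength_um
        )
        _, gx_b, gy_b = _surface_and_gradient(xb, yb, base_coeffs, extent_um, 0.0, 1.0)
        dot = gx_f * gx_b + gy_f * gy_b + 1.0
        nf = np.sqrt(gx_f**2 + gy_f**2 + 1.0)
        nb = np.sqrt(gx_b**2 + gy_b**2 + 1.0)
        theta = np.degrees(np.arccos(np.clip(dot / (nf * nb), -1.0, 1.0)))
        total += float(theta.sum())
    return total / (n_quad * n_quad)


def amplitude_for_mean_angle(
    target_deg: float,
    base_coeffs,
    bump_wavelength_um: float,
    extent_um: tuple[float, float],
    roi_bounds_um=None,
    n_quad: int = 600,
) -> float:
    """Invert the quadrature: bump amplitude whose planted mean angular
    deviation equals ``target_deg`` (the mean angle is monotone in the
    amplitude)."""
    if target_deg == 0:
        return 0.0

    def f(a):
        return (
            analytic_mean_angle(
                base_coeffs, a, bump_wavelength_um, extent_um, roi_bounds_um, n_quad
            )
            - target_deg
        )

    hi = bump_wavelength_um / 8.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > bump_wavelength_um * 100:
            raise RuntimeError("cannot bracket amplitude for requested angle")
    return float(brentq(f, 0.0, hi, xtol=1e-6))


def make_condyle_phantom(
    base_coeffs=None,
    target_mean_angle_deg: float | None = None,
    bump_amplitude_um: float = 0.0,
    bump_wavelength_um: float = 200.0,
    voxel_size_um: float = 4.5,
    extent_um: tuple[float, float] = (1200.0, 1200.0),
    cartilage_thickness_um: float = 135.0,
    tissue_intensity: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    supersample: int = 4,
    margin_px: int = 6,
) -> PhantomResult:
    """Voxelized cartilage band under z = P5(x, y) + a sin(2pi x/L) sin(2pi y/L).

    The column occupancy of each voxel is computed exactly (the surface is a
    height field), and averaged over ``supersample^2`` sub-columns per voxel
    footprint for in-plane partial volume. Ground truth is the analytic mean
    angular deviation of the bumped surface from the base polynomial over the
    ROI (border margin excluded), validated by quadrature.
    """
    if (bump_amplitude_um or target_mean_angle_deg) and (
        bump_wavelength_um <= 4.0 * voxel_size_um
    ):
        raise ValueError(
            f"bump wavelength {bump_wavelength_um} um under the sampling limit "
            f"({4 * voxel_size_um} um at {voxel_size_um} um voxels)"
        )
    if base_coeffs is None:
        base_coeffs = default_condyle_coeffs()
    h = voxel_size_um
    lx, ly = extent_um
    nx = int(round(lx / h))
    ny = int(round(ly / h))
    x = np.arange(nx) * h
    y = np.arange(ny) * h

    if target_mean_angle_deg is not None:
        roi_b = (x[margin_px], x[nx - margin_px - 1],
                 y[margin_px], y[ny - margin_px - 1])
        bump_amplitude_um = amplitude_for_mean_angle(
            target_mean_angle_deg, base_coeffs, bump_wavelength_um, extent_um,
            roi_bounds_um=roi_b,
        )

    zs_coarse, _, _ = _surface_and_gradient(
        x[None, :], y[:, None], base_coeffs, extent_um,
        bump_amplitude_um, bump_wavelength_um,
    )
    z_lo = zs_coarse.min() - cartilage_thickness_um - 3 * h
    z_hi = zs_coarse.max() + 3 * h
    nz = int(np.ceil((z_hi - z_lo) / h)) + 1
    z_off = z_lo  # physical z of voxel index 0

    acc = np.zeros((nz, ny, nx), dtype=np.float32)
    kk = np.arange(nz, dtype=np.float32)[:, None, None]
    for oy in range(supersample):
        for ox in range(supersample):
            xf = x + ((ox + 0.5) / supersample - 0.5) * h
            yf = y + ((oy + 0.5) / supersample - 0.5) * h
            zs, _, _ = _surface_and_gradient(
                xf[None, :], yf[:, None], base_coeffs, extent_um,
                bump_amplitude_um, bump_wavelength_um,
            )
            # voxel k spans physical z in [z_off + (k-0.5)h, z_off + (k+0.5)h)
            hi_e = ((zs - z_off) / h + 0.5).astype(np.float32)
            lo_e = ((zs - cartilage_thickness_um - z_off) / h + 0.5).astype(np.float32)
            acc += np.clip(hi_e[None] - kk, 0.0, 1.0) - np.clip(lo_e[None] - kk, 0.0, 1.0)
    acc *= np.float32(tissue_intensity / supersample**2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        acc += rng.normal(0.0, noise_sd, size=acc.shape).astype(np.float32)

    volume = ImageVolume(acc, voxel_size_um=h, origin_um=np.array([z_off, 0.0, 0.0]))

    mask = np.zeros((ny, nx), dtype=bool)
    mask[margin_px : ny - margin_px, margin_px : nx - margin_px] = True
    roi = CondyleROI(label="medial tibia", mask_xy=mask)
    roi_bounds = (
        x[margin_px], x[nx - margin_px - 1], y[margin_px], y[ny - margin_px - 1]
    )
    truth_angle = analytic_mean_angle(
        base_coeffs, bump_amplitude_um, bump_wavelength_um, extent_um, roi_bounds
    )
    params = dict(
        bump_amplitude_um=bump_amplitude_um,
        bump_wavelength_um=bump_wavelength_um,
        voxel_size_um=h,
        extent_um=extent_um,
        cartilage_thickness_um=cartilage_thickness_um,
        noise_sd=noise_sd,
        supersample=supersample,
        margin_px=margin_px,
    )
    truth = dict(
        mean_angle_deg=truth_angle,
        surface_z_um=zs_coarse,
        base_coeffs=np.asarray(base_coeffs, dtype=float),
        roi_bounds_um=roi_bounds,
    )
    return PhantomResult(
        kind="condyle", params=params, ground_truth=truth, seed=seed,
        volume=volume, roi=roi,
    )


# ---------------------------------------------------------------------------
# bone phantoms


def make_slab_phantom(
    thickness_vox: int, lateral: int = 40, pad: int = 6, voxel_size_um: float = 4.5
) -> PhantomResult:
    """A slab of given voxel thickness spanning the full lateral extent."""
    nz = thickness_vox + 2 * pad
    data = np.zeros((nz, lateral, lateral), dtype=bool)
    data[pad : pad + thickness_vox] = True
    mask = BinaryMask(data, voxel_size_um)
    return PhantomResult(
        kind="slab",
        params=dict(thickness_vox=thickness_vox, voxel_size_um=voxel_size_um),
        ground_truth=dict(thickness_um=thickness_vox * voxel_size_um),
        mask=mask,
    )


def make_cylinder_phantom(
    diameter_vox: int, length: int = 60, pad: int = 8, voxel_size_um: float = 4.5
) -> PhantomResult:
    """A solid cylinder along z (length >> diameter), axis on a voxel center
    so the discrete cross-section width equals the diameter for odd sizes."""
    r = diameter_vox / 2.0
    n = diameter_vox + 2 * pad + 1
    yy, xx = np.mgrid[:n, :n]
    c = n // 2
    disk = (yy - c) ** 2 + (xx - c) ** 2 <= r * r
    data = np.broadcast_to(disk, (length, n, n)).copy()
    return PhantomResult(
        kind="cylinder",
        params=dict(diameter_vox=diameter_vox, voxel_size_um=voxel_size_um),
        ground_truth=dict(diameter_um=diameter_vox * voxel_size_um),
        mask=BinaryMask(data, voxel_size_um),
    )


def make_plate_phantom(
    plate_thickness_um: float = 45.0,
    gap_um: float = 135.0,
    voxel_size_um: float = 4.5,
    n_periods: int = 4,
    lateral: int = 64,
) -> PhantomResult:
    """Parallel plates of thickness t separated by gaps g along z.

    The returned ROI covers exactly ``n_periods`` plate+gap periods whose
    plates and gaps are all interior (bounded on both sides), so
    BV/TV = t/(t+g), Tb.Th = t and Tb.Sp = g hold exactly on the voxel grid.
    """
    h = voxel_size_um
    t = int(round(plate_thickness_um / h))
    g = int(round(gap_um / h))
    nz = g + n_periods * (t + g) + t + g
    data = np.zeros((nz, lateral, lateral), dtype=bool)
    for k in range(n_periods + 1):
        z0 = g + k * (t + g)
        data[z0 : z0 + t] = True
    roi = np.zeros_like(data)
    roi[g : g + n_periods * (t + g)] = True
    truth = dict(
        bv_tv_percent=100.0 * t / (t + g),
        tb_th_um=t * h,
        tb_sp_um=g * h,
    )
    return PhantomResult(
        kind="plate",
        params=dict(plate_thickness_um=t * h, gap_um=g * h, voxel_size_um=h,
                    n_periods=n_periods),
        ground_truth=truth,
        mask=BinaryMask(data, h),
        roi=BinaryMask(roi, h),
    )


def rod_lattice_volume_fraction(rod_radius_um: float, spacing_um: float) -> float:
    """Closed-form volume fraction of three orthogonal rod families on a
    cubic lattice (inclusion–exclusion: three cylinders per cell, three
    perpendicular bicylinder intersections, one tricylinder)."""
    r, s = rod_radius_um, spacing_um
    if 2 * r >= s:
        raise ValueError("rods overlap within a family (2r >= spacing)")
    cell = 3.0 * np.pi * r * r * s - 16.0 * r**3 + 8.0 * (2.0 - np.sqrt(2.0)) * r**3
    return cell / s**3


def make_rod_lattice_phantom(
    rod_radius_um: float = 22.5,
    spacing_um: float = 135.0,
    n_cells: int = 3,
    voxel_size_um: float = 4.5,
) -> PhantomResult:
    """Orthogonal rod lattice: rods along x, y and z on a cubic lattice of
    pitch s (periodic, so the sampled fraction matches the closed form)."""
    h = voxel_size_um
    s = spacing_um
    n = int(round(n_cells * s / h))
    coord = np.arange(n) * h

    def wrapped(c):
        m = np.mod(c, s)
        return np.minimum(m, s - m)

    d = wrapped(coord)
    d2z = d[:, None] ** 2 + d[None, :] ** 2  # (y, x) distance^2 to z-rod axes
    r2 = rod_radius_um**2
    zrods = d2z <= r2
    mask = np.broadcast_to(zrods[None, :, :], (n, n, n)).copy()
    d2y = d[:, None] ** 2 + d[None, :] ** 2  # (z, x)
    mask |= np.broadcast_to((d2y <= r2)[:, None, :], (n, n, n))
    d2x = d[:, None] ** 2 + d[None, :] ** 2  # (z, y)
    mask |= np.broadcast_to((d2x <= r2)[:, :, None], (n, n, n))

    truth = dict(
        volume_fraction=rod_lattice_volume_fraction(rod_radius_um, spacing_um),
        bv_tv_percent=100.0 * rod_lattice_volume_fraction(rod_radius_um, spacing_um),
    )
    return PhantomResult(
        kind="trabecular_lattice",
        params=dict(rod_radius_um=rod_radius_um, spacing_um=spacing_um,
                    voxel_size_um=h, n_cells=n_cells),
        ground_truth=truth,
        mask=BinaryMask(mask, h),
    )


# ---------------------------------------------------------------------------
# histology phantoms


def _place_points(rng, n, width, height, min_sep, max_tries=200000,
                  exclude_band_y=None):
    """Dart-throwing with a uniform grid for the minimum-separation test.

    ``exclude_band_y`` keeps points out of a horizontal band (used to keep
    cells clear of the lining/sublining boundary so compartment truth is
    unambiguous).
    """
    if n == 0:
        return np.zeros((0, 2))
    cell = min_sep / np.sqrt(2.0)
    gw, gh = int(np.ceil(width / cell)), int(np.ceil(height / cell))
    grid = -np.ones((gh, gw), dtype=int)
    pts = np.zeros((n, 2))
    placed = 0
    for _ in range(max_tries):
        p = rng.uniform([min_sep, min_sep], [width - min_sep, height - min_sep])
        if exclude_band_y is not None and exclude_band_y[0] < p[1] < exclude_band_y[1]:
            continue
        gi, gj = int(p[1] / cell), int(p[0] / cell)
        ok = True
        for ii in range(max(gi - 2, 0), min(gi + 3, gh)):
            for jj in range(max(gj - 2, 0), min(gj + 3, gw)):
                q = grid[ii, jj]
                if q >= 0 and np.hypot(*(pts[q] - p)) < min_sep:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            pts[placed] = p
            grid[gi, gj] = placed
            placed += 1
            if placed == n:
                return pts
    raise RuntimeError(f"could only place {placed}/{n} points at separation {min_sep}")


def _stamp_disks(shape, centers_px, radius_px, value, edge_px=1.0):
    """Accumulate soft-edged disks into a float image."""
    img = np.zeros(shape, dtype=float)
    r_out = int(np.ceil(radius_px + edge_px)) + 1
    for cy, cx in centers_px:
        y0, y1 = int(cy) - r_out, int(cy) + r_out + 1
        x0, x1 = int(cx) - r_out, int(cx) + r_out + 1
        y0c, x0c = max(y0, 0), max(x0, 0)
        y1c, x1c = min(y1, shape[0]), min(x1, shape[1])
        yy, xx = np.mgrid[y0c:y1c, x0c:x1c]
        d = np.hypot(yy - cy, xx - cx)
        img[y0c:y1c, x0c:x1c] += value * np.clip((radius_px + edge_px - d) / edge_px, 0, 1)
    return np.clip(img, 0, value)


def make_histology_phantom(
    density_per_mm2: float = 2727.0,
    extent_um: tuple[float, float] = (600.0, 600.0),
    pixel_size_um: float = 1.0,
    nucleus_radius_um: float = 3.5,
    hematoxylin_od: float = 0.9,
    eosin_od: float = 0.25,
    seed: int = 0,
) -> PhantomResult:
    """H&E section with seeded, non-overlapping nuclei at a planted density.

    Synthesized through the Ruifrok–Johnston H&E OD model (the same model the
    density analyzer inverts): hematoxylin disks on a uniform eosin tissue
    background. Densities default to the study's observed synovial range.
    """
    from skimage.color import combine_stains, rgb_from_hed

    rng = np.random.default_rng(seed)
    w_um, h_um = extent_um
    area_mm2 = w_um * h_um / 1e6
    n = int(round(density_per_mm2 * area_mm2))
    min_sep = 2 * nucleus_radius_um + 3.0
    pts = _place_points(rng, n, w_um, h_um, min_sep)

    shape = (int(round(h_um / pixel_size_um)), int(round(w_um / pixel_size_um)))
    centers_px = pts[:, ::-1] / pixel_size_um  # (y, x)
    h_ch = _stamp_disks(shape, centers_px, nucleus_radius_um / pixel_size_um,
                        hematoxylin_od)
    e_ch = np.full(shape, eosin_od)
    stains = np.stack([h_ch, e_ch, np.zeros(shape)], axis=-1)
    rgb = np.clip(combine_stains(stains, rgb_from_hed), 0, 1)

    section = SectionImage(rgb, pixel_size_um=pixel_size_um,
                           channel_names=("R", "G", "B"))
    truth = dict(n_cells=n, density_per_mm2=n / area_mm2, area_mm2=area_mm2,
                 centers_um=pts)
    return PhantomResult(
        kind="histology",
        params=dict(density_per_mm2=density_per_mm2, extent_um=extent_um,
                    pixel_size_um=pixel_size_um,
                    nucleus_radius_um=nucleus_radius_um),
        ground_truth=truth, seed=seed, section=section,
    )


def make_trichrome_phantom(
    collagen_fraction: float = 0.3,
    extent_um: tuple[float, float] = (600.0, 600.0),
    pixel_size_um: float = 1.0,
    blob_scale_um: float = 30.0,
    blue_od: float = 0.8,
    red_od: float = 0.7,
    seed: int = 0,
) -> PhantomResult:
    """Masson's trichrome section with an exact planted collagen fraction.

    A smoothed noise field is thresholded at the (1 - fraction) quantile, so
    the planted pixel fraction is exact; collagen pixels carry aniline-blue
    OD, the rest scarlet OD.
    """
    from scipy.ndimage import gaussian_filter
    from skimage.color import combine_stains

    if not 0.0 <= collagen_fraction <= 1.0:
        raise ValueError("collagen_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    shape = (
        int(round(extent_um[1] / pixel_size_um)),
        int(round(extent_um[0] / pixel_size_um)),
    )
    if collagen_fraction == 0.0:
        collagen = np.zeros(shape, dtype=bool)
    elif collagen_fraction == 1.0:
        collagen = np.ones(shape, dtype=bool)
    else:
        noise = gaussian_filter(rng.standard_normal(shape),
                                blob_scale_um / pixel_size_um)
        thr = np.quantile(noise, 1.0 - collagen_fraction)
        collagen = noise > thr

    planted = float(np.count_nonzero(collagen)) / collagen.size
    scarlet = np.where(collagen, 0.0, red_od)
    blue = np.where(collagen, blue_od, 0.0)
    stains = np.stack([scarlet, blue, np.zeros(shape)], axis=-1)
    rgb = np.clip(combine_stains(stains, MASSON_RGB_FROM_STAINS), 0, 1)
    section = SectionImage(rgb, pixel_size_um=pixel_size_um,
                           channel_names=("R", "G", "B"))
    return PhantomResult(
        kind="histology",
        params=dict(collagen_fraction=collagen_fraction, extent_um=extent_um,
                    pixel_size_um=pixel_size_um, blob_scale_um=blob_scale_um),
        ground_truth=dict(collagen_fraction=planted, collagen_mask=collagen),
        seed=seed, section=section,
    )


def make_fluorescence_phantom(
    class_counts: dict[str, int] | None = None,
    extent_um: tuple[float, float] = (400.0, 400.0),
    pixel_size_um: float = 1.0,
    nucleus_radius_um: float = 3.5,
    marker_radius_um: float = 6.0,
    marker_intensity: float = 0.8,
    nuclear_intensity: float = 0.9,
    lining_depth_um: float = 60.0,
    seed: int = 0,
) -> PhantomResult:
    """Hoechst/CX3CR1/CD68 phantom with known per-class cell counts.

    All cells carry a Hoechst nucleus; marker channels get disks around the
    nuclei of the classes positive for them. The annotation splits the field
    into a lining band (top ``lining_depth_um``) and the sublining below;
    per-compartment truth counts come from the realized placement.
    """
    counts = dict(class_counts or {"CX3CR1+": 50, "CD68+CX3CR1-": 30,
                                   "double+": 0, "negative": 20})
    for k in counts:
        if k not in ("CX3CR1+", "CD68+CX3CR1-", "double+", "negative"):
            raise ValueError(f"unknown class {k!r}")
    rng = np.random.default_rng(seed)
    w_um, h_um = extent_um
    n_total = sum(counts.values())
    min_sep = 2 * (marker_radius_um + 1.5) + 2.0
    band = (lining_depth_um - nucleus_radius_um - 2.0,
            lining_depth_um + nucleus_radius_um + 2.0)
    pts = _place_points(rng, n_total, w_um, h_um, min_sep, exclude_band_y=band)
    labels = np.array([k for k in counts for _ in range(counts[k])])
    labels = labels[rng.permutation(n_total)]  # classes are position-independent

    shape = (int(round(h_um / pixel_size_um)), int(round(w_um / pixel_size_um)))
    centers_px = pts[:, ::-1] / pixel_size_um
    hoechst = _stamp_disks(shape, centers_px, nucleus_radius_um / pixel_size_um,
                           nuclear_intensity)
    cx_sel = np.isin(labels, ["CX3CR1+", "double+"])
    cd_sel = np.isin(labels, ["CD68+CX3CR1-", "double+"])
    cx = _stamp_disks(shape, centers_px[cx_sel], marker_radius_um / pixel_size_um,
                      marker_intensity)
    cd = _stamp_disks(shape, centers_px[cd_sel], marker_radius_um / pixel_size_um,
                      marker_intensity)
    section = SectionImage(
        np.stack([hoechst, cx, cd], axis=-1),
        pixel_size_um=pixel_size_um,
        channel_names=("Hoechst", "CX3CR1", "CD68"),
    )

    lining_poly = [(0, 0), (w_um, 0), (w_um, lining_depth_um), (0, lining_depth_um)]
    sublining_poly = [(0, lining_depth_um), (w_um, lining_depth_um),
                      (w_um, h_um), (0, h_um)]
    annotation = SynoviumAnnotation(
        lining_contour=np.array([[0.0, 0.0], [w_um, 0.0]]),
        fibrous_membrane_contour=np.array([[0.0, h_um], [w_um, h_um]]),
        compartments={"lining": lining_poly, "sublining": sublining_poly},
    )
    in_lining = pts[:, 1] <= lining_depth_um
    truth = dict(
        class_counts=counts,
        n_cells=n_total,
        compartment_counts={"lining": int(in_lining.sum()),
                            "sublining": int((~in_lining).sum())},
        centers_um=pts,
        labels=labels,
    )
    return PhantomResult(
        kind="fluorescence",
        params=dict(extent_um=extent_um, pixel_size_um=pixel_size_um,
                    lining_depth_um=lining_depth_um),
        ground_truth=truth, seed=seed, section=section, annotation=annotation,
    )


# ---------------------------------------------------------------------------
# mechanics / behavior phantoms


def make_load_curve(
    stiffness_N_per_mm: float = 47.1,
    failure_load_N: float = 31.4,
    max_displacement_mm: float = 1.2,
    step_mm: float = 0.002,
    noise_sd: float = 0.0,
    load_cell_max_N: float = 50.0,
    post_failure_decay_mm: float = 0.05,
    seed: int = 0,
) -> PhantomResult:
    """Linear-elastic ramp to a failure peak, then an exponential drop.

    A nominal failure load at or above the load-cell ceiling produces a
    clipped plateau (the censored regime). Noiseless curves recover the
    planted stiffness exactly through the windowed slope.
    """
    x = np.arange(0.0, max_displacement_mm + step_mm / 2, step_mm)
    x_fail = failure_load_N / stiffness_N_per_mm
    if 0.0 < x_fail < max_displacement_mm:  # sample the peak itself
        x = np.unique(np.append(x, x_fail))
    load = np.where(
        x <= x_fail,
        stiffness_N_per_mm * x,
        failure_load_N * np.exp(-(x - x_fail) / post_failure_decay_mm),
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        load = load + rng.normal(0.0, noise_sd, size=load.shape)
    censored = failure_load_N >= load_cell_max_N
    load = np.minimum(load, load_cell_max_N)
    curve = LoadDisplacementCurve(
        displacement_mm=x, load_N=load, load_cell_max_N=load_cell_max_N
    )
    truth = dict(
        stiffness_N_per_mm=stiffness_N_per_mm,
        failure_load_N=min(failure_load_N, load_cell_max_N),
        censored=bool(censored),
    )
    return PhantomResult(
        kind="load_curve",
        params=dict(stiffness_N_per_mm=stiffness_N_per_mm,
                    failure_load_N=failure_load_N, noise_sd=noise_sd),
        ground_truth=truth, seed=seed, curve=curve,
    )


DEFAULT_DEFICIT_BY_DAY = {-7: 0.0, 7: -9.0, 21: -2.0, 35: 0.0, 49: 0.0, 63: 0.0}


def make_gait_cohort(
    deficit_by_day: dict[int, float] | None = None,
    n_animals: int = 4,
    n_runs: int = 6,
    base_duty_percent: float = 60.0,
    cycle_s: float = 0.5,
    stride_mm: float = 100.0,
    mean_selected_variation: float = 43.0,
    noise_sd: float = 0.0,
    injected_side: str = "left",
    seed: int = 0,
) -> PhantomResult:
    """Longitudinal gait sessions with a planted injected-limb duty deficit.

    Per session, run-speed variations are laid out so the three lowest
    average ``mean_selected_variation`` percent (the study's reported mean);
    the injected paw's duty cycle is scaled by the planted per-day deficit
    relative to the contralateral paw, with a symmetric baseline, so the
    noiseless normalization round-trips exactly.
    """
    deficits = dict(deficit_by_day or DEFAULT_DEFICIT_BY_DAY)
    if -7 not in deficits:
        deficits[-7] = 0.0
    rng = np.random.default_rng(seed)
    animals = {}
    for a in range(n_animals):
        sessions = {}
        for day, deficit in sorted(deficits.items()):
            # three lowest variations average the requested mean exactly
            lows = mean_selected_variation + np.array([-3.0, 0.0, 3.0])
            highs = mean_selected_variation + 10.0 + 5.0 * np.arange(n_runs - 3)
            variations = np.concatenate([lows, highs])
            variations = variations[rng.permutation(n_runs)]
            rows = []
            for run in range(n_runs):
                duty_c = base_duty_percent + (
                    rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                )
                duty_i = base_duty_percent * (1.0 + deficit / 100.0) + (
                    rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                )
                for side, duty in (
                    (injected_side, duty_i),
                    ("right" if injected_side == "left" else "left", duty_c),
                ):
                    stand = cycle_s * duty / 100.0
                    swing = cycle_s - stand
                    rows.append(
                        {
                            "run": run,
                            "side": side,
                            "run_speed_variation_percent": variations[run],
                            "duty_cycle_percent": duty,
                            "stand_s": stand,
                            "swing_speed_mm_s": stride_mm / swing,
                        }
                    )
            sessions[day] = GaitSession(
                day=day, injected_side=injected_side,
                runs=pd.DataFrame(rows),
            )
        animals[a] = sessions
    truth = dict(
        deficit_by_day=deficits,
        mean_selected_variation=mean_selected_variation,
    )
    return PhantomResult(
        kind="gait_cohort",
        params=dict(n_animals=n_animals, n_runs=n_runs, noise_sd=noise_sd,
                    base_duty_percent=base_duty_percent),
        ground_truth=truth, seed=seed, sessions=animals,
    )


def make_pam_cohort(
    percent_by_day: dict[int, float] | None = None,
    baseline_force_N: float = 8.0,
    n_animals: int = 4,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> PhantomResult:
    """Withdrawal-force series with a planted percent-of-baseline trajectory
    (default: 20 % acute drop on day 7 recovering by day 35)."""
    traj = dict(percent_by_day or {-7: 100.0, 7: 80.0, 21: 90.0, 35: 100.0,
                                   49: 100.0, 63: 100.0})
    if -7 not in traj:
        traj[-7] = 100.0
    rng = np.random.default_rng(seed)
    rows = []
    for a in range(n_animals):
        for day, pct in sorted(traj.items()):
            force = baseline_force_N * pct / 100.0
            if noise_sd > 0:
                force += rng.normal(0.0, noise_sd)
            rows.append({"animal": a, "day": day, "peak_force_N": force})
    return PhantomResult(
        kind="gait_cohort",
        params=dict(baseline_force_N=baseline_force_N, n_animals=n_animals,
                    noise_sd=noise_sd),
        ground_truth=dict(percent_by_day=traj), seed=seed,
        table=pd.DataFrame(rows),
    )
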