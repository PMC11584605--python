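"""Cartilage roughness score (CRS) from contrast-enhanced uCT.

The articular cartilage surface (PTA-stained, bright against background) is
extracted per condyle as a height field z(x, y) at sub-voxel precision. Local
surface orientation is estimated by least-squares plane fits in a small
physical neighborhood (default 28 um^2, expanded to the smallest window with
enough valid nodes for a well-posed fit). A smooth per-condyle reference
surface is constructed by an iterative 5th-degree bivariate polynomial fit
with symmetric outlier rejection, so that lesions (pits) and loose debris
(spikes) are both down-weighted. The CRS is the angular difference between
the cartilage normals and the analytic reference normals, folded to
[0, 90] degrees and averaged over the condyle: a high CRS means a rough,
damaged surface; an intact surface scores near zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import EmptyROIError, SurfaceQualityError, UnderdeterminedFitError
from .volumes import ImageVolume

__all__ = [
    "CondyleROI",
    "HeightFieldSurface",
    "ReferenceSurface",
    "RoughnessMap",
    "CRSConfig",
    "extract_cartilage_surface",
    "estimate_local_orientation",
    "fit_reference_surface",
    "compute_roughness_map",
    "compute_crs",
]

_CONDYLE_LABELS = {
    f"{side} {bone}" for side in ("medial", "lateral") for bone in ("femur", "tibia")
}


@dataclass
class CondyleROI:
    """A per-condyle region of interest over the (y, x) height-field lattice."""

    label: str
    mask_xy: np.ndarray  # 2D boolean, shape (ny, nx)

    def __post_init__(self) -> None:
        if self.label not in _CONDYLE_LABELS:
            raise ValueError(f"label must be one of {sorted(_CONDYLE_LABELS)}")
        self.mask_xy = np.asarray(self.mask_xy, dtype=bool)
        if self.mask_xy.ndim != 2 or not self.mask_xy.any():
            raise EmptyROIError("condyle ROI mask is empty or not 2D")


@dataclass
class HeightFieldSurface:
    """Cartilage surface as a height field with optional per-node normals.

    ``z_um`` is NaN outside the condyle ROI / where no surface was found.
    ``normals`` (ny, nx, 3) are unit vectors (x, y, z components) oriented
    towards +z; NaN where orientation could not be estimated.
    """

    x_um: np.ndarray  # (nx,) lattice x positions
    y_um: np.ndarray  # (ny,)
    z_um: np.ndarray  # (ny, nx), NaN = invalid
    normals: np.ndarray | None = None
    neighborhood_area_um2: float | None = None  # effective base-window area

    def __post_init__(self) -> None:
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        self.z_um = np.asarray(self.z_um, dtype=float)
        if self.z_um.shape != (self.y_um.size, self.x_um.size):
            raise ValueError("z grid shape does not match lattice vectors")
        if not np.isfinite(self.z_um).any():
            raise SurfaceQualityError("surface has no valid nodes")

    @property
    def spacing_um(self) -> float:
        return float(self.x_um[1] - self.x_um[0]) if self.x_um.size > 1 else 1.0

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.z_um)


@dataclass
class ReferenceSurface:
    """Bivariate polynomial reference surface in centered/scaled coordinates.

    Coefficients index monomials u^i v^j with i + j <= degree, where
    u = (x - x0) / xs and v = (y - y0) / ys map the fit domain to [-1, 1].
    """

    degree: int
    coefficients: np.ndarray  # (n_coef,) ordered by _exponents(degree)
    x0: float
    xs: float
    y0: float
    ys: float
    included_mask: np.ndarray  # boolean over the surface grid
    n_iterations_run: int
    converged: bool = True

    def __post_init__(self) -> None:
        n_expected = (self.degree + 1) * (self.degree + 2) // 2
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.size != n_expected:
            raise ValueError(
                f"degree {self.degree} needs {n_expected} coefficients, "
                f"got {self.coefficients.size}"
            )
        if self.n_iterations_run < 1:
            raise ValueError("n_iterations_run must be >= 1")

    def _uv(self, x_um, y_um):
        return (np.asarray(x_um) - self.x0) / self.xs, (np.asarray(y_um) - self.y0) / self.ys

    def evaluate(self, x_um, y_um) -> np.ndarray:
        u, v = self._uv(x_um, y_um)
        out = np.zeros(np.broadcast(u, v).shape)
        for c, (i, j) in zip(self.coefficients, _exponents(self.degree)):
            out = out + c * u**i * v**j
        return out

    def gradient(self, x_um, y_um) -> tuple[np.ndarray, np.ndarray]:
        """(dz/dx, dz/dy) in um/um at physical coordinates."""
        u, v = self._uv(x_um, y_um)
        shape = np.broadcast(u, v).shape
        du = np.zeros(shape)
        dv = np.zeros(shape)
        for c, (i, j) in zip(self.coefficients, _exponents(self.degree)):
            if i > 0:
                du = du + c * i * u ** (i - 1) * v**j
            if j > 0:
                dv = dv + c * j * u**i * v ** (j - 1)
        return du / self.xs, dv / self.ys

    def normals(self, x_um, y_um) -> np.ndarray:
        """Unit normals (x, y, z components) of the polynomial surface."""
        gx, gy = self.gradient(x_um, y_um)
        n = np.stack([-gx, -gy, np.ones_like(gx)], axis=-1)
        return n / np.linalg.norm(n, axis=-1, keepdims=True)


@dataclass
class RoughnessMap:
    """Per-node angular deviation map (degrees) and its condyle mean (CRS)."""

    theta_deg: np.ndarray
    crs: float
    surface: HeightFieldSurface | None = None
    reference: ReferenceSurface | None = None


@dataclass
class CRSConfig:
    """Tunable parameters of the CRS pipeline (defaults follow the method)."""

    neighborhood_area_um2: float = 28.0
    degree: int = 5
    max_iter: int = 50
    outlier_k: float = 2.0
    tol: float = 1e-8
    threshold: float | None = None  # intensity threshold; None = Otsu
    max_missing_fraction: float = 0.2
    area_weighted: bool = False


def _exponents(degree: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(degree + 1) for j in range(degree + 1 - i)]


# ---------------------------------------------------------------------------
# surface extraction


def extract_cartilage_surface(
    volume: ImageVolume,
    roi: CondyleROI | None = None,
    threshold: float | None = None,
    max_missing_fraction: float = 0.2,
) -> HeightFieldSurface:
    """Extract the topmost cartilage surface per (x, y) column, sub-voxel.

    Segmentation: Otsu threshold on the ROI intensity histogram (overridable),
    largest connected tissue component. The surface height in each column is
    the bottom of the topmost above-threshold voxel plus the partial-volume
    occupancy of that voxel and the one above it (intensity rescaled between
    the background and tissue class means). For a two-level partial-volume
    image this estimate is exact; it degrades gracefully with noise.
    """
    data = volume.data
    nz, ny, nx = data.shape
    if roi is not None and roi.mask_xy.shape != (ny, nx):
        raise EmptyROIError(
            f"ROI shape {roi.mask_xy.shape} does not match volume XY {(ny, nx)}"
        )
    roi_xy = roi.mask_xy if roi is not None else np.ones((ny, nx), bool)

    sub = data[:, roi_xy]
    if threshold is None:
        from skimage.filters import threshold_otsu

        if np.ptp(sub) == 0:
            raise SurfaceQualityError("ROI intensities are constant; no surface")
        threshold = float(threshold_otsu(sub.ravel()))
    fg_vals = sub[sub >= threshold]
    bg_vals = sub[sub < threshold]
    if fg_vals.size == 0 or bg_vals.size == 0:
        raise SurfaceQualityError("thresholding found no tissue/background split")
    fg_level = float(fg_vals.mean())
    bg_level = float(bg_vals.mean())

    tissue = data >= threshold
    tissue[:, ~roi_xy] = False
    labels, n_lab = ndimage.label(tissue)
    if n_lab == 0:
        raise SurfaceQualityError("no tissue component found in ROI")
    if n_lab > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        tissue = labels == int(np.argmax(counts))

    any_col = tissue.any(axis=0)
    # topmost tissue voxel index per column (z index increases upwards)
    zidx = np.arange(nz)[:, None, None]
    top = np.where(tissue, zidx, -1).max(axis=0)

    yy, xx = np.nonzero(any_col)
    k = top[yy, xx]
    contrast = fg_level - bg_level
    f_top = np.clip((data[k, yy, xx] - bg_level) / contrast, 0.0, 1.0)
    above = np.minimum(k + 1, nz - 1)
    i_above = np.where(k + 1 < nz, data[above, yy, xx], bg_level)
    f_above = np.clip((i_above - bg_level) / contrast, 0.0, 1.0)

    h = volume.voxel_size_um
    z = np.full((ny, nx), np.nan)
    z[yy, xx] = (k - 0.5 + f_top + f_above) * h + volume.origin_um[0]

    missing = np.count_nonzero(roi_xy & ~any_col) / np.count_nonzero(roi_xy)
    if missing > max_missing_fraction:
        raise SurfaceQualityError(
            f"{missing:.0%} of ROI columns have no cartilage surface "
            f"(limit {max_missing_fraction:.0%})"
        )
    z[~roi_xy] = np.nan

    x_um = np.arange(nx) * h + volume.origin_um[2]
    y_um = np.arange(ny) * h + volume.origin_um[1]
    return HeightFieldSurface(x_um=x_um, y_um=y_um, z_um=z)


# ---------------------------------------------------------------------------
# local orientation


def _box_sum(arr: np.ndarray, size: int) -> np.ndarray:
    return ndimage.uniform_filter(arr, size=size, mode="constant") * size * size


def _plane_normals_from_moments(s1, sx, sy, sz, sxx, syy, sxy, sxz, syz):
    """Solve the centered 2x2 normal equations for plane slopes, vectorized."""
    with np.errstate(invalid="ignore", divide="ignore"):
        mx, my, mz = sx / s1, sy / s1, sz / s1
        cxx = sxx / s1 - mx * mx
        cyy = syy / s1 - my * my
        cxy = sxy / s1 - mx * my
        cxz = sxz / s1 - mx * mz
        cyz = syz / s1 - my * mz
        det = cxx * cyy - cxy * cxy
        b = (cxz * cyy - cyz * cxy) / det
        c = (cyz * cxx - cxz * cxy) / det
    return b, c, det


def estimate_local_orientation(
    surface: HeightFieldSurface,
    neighborhood_area_um2: float = 28.0,
    min_valid: int = 6,
    max_expansions: int = 8,
) -> HeightFieldSurface:
    """Fill per-node unit normals from windowed least-squares plane fits.

    The window is the centered square whose physical area is closest from
    above to the requested neighborhood area; nodes whose window holds fewer
    than ``min_valid`` valid neighbors get the window enlarged stepwise (the
    effective base-window area is recorded on the surface). Nodes that stay
    degenerate get NaN normals and are excluded downstream.
    """
    h = surface.spacing_um
    side = int(np.ceil(np.sqrt(neighborhood_area_um2) / h))
    side = max(side, 1)
    if side % 2 == 0:
        side += 1

    valid = surface.valid
    w = valid.astype(float)
    z = np.where(valid, surface.z_um, 0.0)
    xg, yg = np.meshgrid(surface.x_um, surface.y_um)
    xg = xg * w
    yg = yg * w

    def moments(size):
        return (
            _box_sum(w, size),
            _box_sum(xg, size),
            _box_sum(yg, size),
            _box_sum(z * w, size),
            _box_sum(xg * xg / np.where(w > 0, w, 1), size),  # w*x^2 == (wx)^2/w
            _box_sum(yg * yg / np.where(w > 0, w, 1), size),
            _box_sum(xg * yg / np.where(w > 0, w, 1), size),
            _box_sum(xg * z, size),
            _box_sum(yg * z, size),
        )

    s1, sx, sy, sz, sxx, syy, sxy, sxz, syz = moments(side)
    b, c, det = _plane_normals_from_moments(s1, sx, sy, sz, sxx, syy, sxy, sxz, syz)
    counts = np.round(s1).astype(int)
    ok = valid & (counts >= min_valid) & np.isfinite(det) & (np.abs(det) > 1e-12 * h**4)

    # per-node window expansion for under-populated neighborhoods; the target
    # is min_valid nodes, with a >= 3 fallback at the maximum expansion
    need = valid & ~ok
    size = side
    for step in range(max_expansions):
        if not need.any():
            break
        size += 2
        m = moments(size)
        b2, c2, det2 = _plane_normals_from_moments(*m)
        counts2 = np.round(m[0]).astype(int)
        quota = min_valid if step < max_expansions - 1 else 3
        ok2 = need & (counts2 >= quota) & np.isfinite(det2) & (
            np.abs(det2) > 1e-12 * h**4
        )
        b = np.where(ok2, b2, b)
        c = np.where(ok2, c2, c)
        ok |= ok2
        need &= ~ok2

    normals = np.full(surface.z_um.shape + (3,), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.sqrt(b**2 + c**2 + 1.0)
        normals[ok, 0] = (-b / norm)[ok]
        normals[ok, 1] = (-c / norm)[ok]
        normals[ok, 2] = (1.0 / norm)[ok]

    return HeightFieldSurface(
        x_um=surface.x_um,
        y_um=surface.y_um,
        z_um=surface.z_um,
        normals=normals,
        neighborhood_area_um2=(side * h) ** 2,
    )


# ---------------------------------------------------------------------------
# reference surface


def fit_reference_surface(
    surface: HeightFieldSurface,
    degree: int = 5,
    max_iter: int = 50,
    outlier_k: float = 2.0,
    tol: float = 1e-8,
) -> ReferenceSurface:
    """Iterative least-squares polynomial fit with symmetric outlier rejection.

    Fit on the included nodes, compute residuals, drop nodes with
    ``|residual| > outlier_k * SD(residuals)``, refit; stop when the included
    set is unchanged, the relative coefficient change falls below ``tol`` or
    ``max_iter`` is reached. Coordinates are centered and scaled to [-1, 1]
    before fitting for conditioning. Non-convergence sets ``converged=False``
    rather than raising.
    """
    valid = surface.valid
    n_coef = (degree + 1) * (degree + 2) // 2
    if np.count_nonzero(valid) < 3 * n_coef:
        raise UnderdeterminedFitError(
            f"{np.count_nonzero(valid)} valid nodes for {n_coef} coefficients "
            f"(need >= {3 * n_coef})"
        )

    xg, yg = np.meshgrid(surface.x_um, surface.y_um)
    xv, yv, zv = xg[valid], yg[valid], surface.z_um[valid]
    x0, y0 = (xv.min() + xv.max()) / 2, (yv.min() + yv.max()) / 2
    xs = max((xv.max() - xv.min()) / 2, 1e-12)
    ys = max((yv.max() - yv.min()) / 2, 1e-12)
    u, v = (xv - x0) / xs, (yv - y0) / ys

    exps = _exponents(degree)
    A = np.stack([u**i * v**j for i, j in exps], axis=1)

    included = np.ones(zv.size, dtype=bool)
    coeffs = None
    z_scale = max(float(np.abs(zv).max()), 1.0)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if np.count_nonzero(included) < n_coef:
            raise UnderdeterminedFitError(
                "outlier rejection left fewer nodes than coefficients"
            )
        new_coeffs, *_ = np.linalg.lstsq(A[included], zv[included], rcond=None)
        res = A[included] @ new_coeffs - zv[included]
        sd = float(res.std())
        if coeffs is not None:
            delta = np.linalg.norm(new_coeffs - coeffs) / max(
                np.linalg.norm(coeffs), 1e-300
            )
            if delta < tol:
                coeffs = new_coeffs
                converged = True
                break
        coeffs = new_coeffs
        if sd <= 1e-9 * z_scale:  # exact model class; nothing left to reject
            converged = True
            break
        keep = np.abs(res) <= outlier_k * sd
        if keep.all():
            converged = True
            break
        idx = np.flatnonzero(included)
        included[idx[~keep]] = False

    included_mask = np.zeros_like(valid)
    included_mask[valid] = included
    return ReferenceSurface(
        degree=degree,
        coefficients=coeffs,
        x0=x0,
        xs=xs,
        y0=y0,
        ys=ys,
        included_mask=included_mask,
        n_iterations_run=n_iter,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# roughness


def compute_roughness_map(
    surface: HeightFieldSurface,
    ref: ReferenceSurface,
    area_weighted: bool = False,
) -> RoughnessMap:
    """Angular difference between surface and reference normals, in degrees.

    theta = arccos(|n_surface . n_reference|), folded to [0, 90] — the method
    does not define a sign for the deviation. NaN normals are excluded from
    the condyle mean. ``area_weighted`` weights each node by its true surface
    patch area (1/n_z); the default is the plain arithmetic mean over nodes.
    """
    if surface.normals is None:
        raise ValueError("surface normals not populated; run estimate_local_orientation")
    xg, yg = np.meshgrid(surface.x_um, surface.y_um)
    n_ref = ref.normals(xg, yg)
    dot = np.abs(np.sum(surface.normals * n_ref, axis=-1))
    theta = np.degrees(np.arccos(np.clip(dot, 0.0, 1.0)))
    valid = np.isfinite(theta)
    if not valid.any():
        raise SurfaceQualityError("no valid nodes to average")
    if area_weighted:
        wts = 1.0 / np.clip(surface.normals[..., 2], 1e-6, None)
        crs = float(np.nansum(theta * wts) / np.nansum(np.where(valid, wts, np.nan)))
    else:
        crs = float(np.nanmean(theta))
    return RoughnessMap(theta_deg=theta, crs=crs, surface=surface, reference=ref)


def compute_crs(
    volume: ImageVolume,
    roi: CondyleROI | None = None,
    config: CRSConfig | None = None,
) -> RoughnessMap:
    """End-to-end CRS: extract -> orient -> fit reference -> angular map."""
    cfg = config or CRSConfig()
    surf = extract_cartilage_surface(
        volume, roi, threshold=cfg.threshold,
        max_missing_fraction=cfg.max_missing_fraction,
    )
    surf = estimate_local_orientation(surf, cfg.neighborhood_area_um2)
    ref = fit_reference_surface(
        surf, degree=cfg.degree, max_iter=cfg.max_iter,
        outlier_k=cfg.outlier_k, tol=cfg.tol,
    )
    return compute_roughness_map(surf, ref, area_weighted=cfg.area_weighted)
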