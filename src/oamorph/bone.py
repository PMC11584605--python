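"""Subchondral and trabecular bone morphometry.

Local thickness follows the model-independent (largest inscribed sphere)
definition: the thickness at a point is the diameter of the largest sphere
that lies fully inside the structure and contains the point. From the
thickness maps of the bone phase and of the marrow phase within a trabecular
ROI, the standard morphometric scalars are derived:

* BV/TV — bone volume fraction, exact voxel-count ratio (percent);
* Tb.Th — mean local thickness of the bone phase (um);
* Tb.Sp — mean local thickness of the marrow phase (um).

The trabecular ROI is built by eroding the medullary volume with a
structuring element of physical radius 315 um — a 2D disc applied slice-wise
by default ("circular" kernel), with a 3D ball available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import EmptyROIError
from .volumes import BinaryMask

__all__ = [
    "ThicknessMap",
    "TrabecularMetrics",
    "local_thickness",
    "subchondral_plate_thickness",
    "build_trabecular_roi",
    "trabecular_metrics",
]


@dataclass
class ThicknessMap:
    """Per-voxel largest-fitting-sphere diameter (um) on foreground voxels."""

    thickness_um: np.ndarray  # NaN outside foreground
    voxel_size_um: float
    method: str = "largest-fitting-sphere"

    @property
    def foreground(self) -> np.ndarray:
        return np.isfinite(self.thickness_um)

    def mean(self) -> float:
        return float(np.nanmean(self.thickness_um))


@dataclass
class TrabecularMetrics:
    bv_tv_percent: float
    tb_th_um: float | None  # None when no bone in ROI
    tb_sp_um: float | None
    roi_voxels: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.bv_tv_percent <= 100.0:
            raise ValueError(f"BV/TV out of range: {self.bv_tv_percent}")
        if self.roi_voxels <= 0:
            raise EmptyROIError("trabecular ROI is empty")


def local_thickness(mask: BinaryMask) -> ThicknessMap:
    """Model-independent local thickness via a radius-descending sphere sweep.

    For each foreground voxel the map holds the diameter of the largest
    inscribed sphere containing it. Spheres are centered on foreground voxels
    with radius equal to the Euclidean distance to the nearest background
    voxel; sweeping the distinct radii in descending order, every voxel within
    a sphere of the current radius that is still unassigned receives that
    diameter. Squared distances on the voxel grid are integers, so the cover
    test is exact. Boundary convention: the volume continues as foreground
    beyond the array (a slab spanning the field of view behaves as infinite).
    """
    fg = mask.data
    if not fg.any():
        raise EmptyROIError("local_thickness: empty mask")
    edt = ndimage.distance_transform_edt(fg)
    r2 = np.round(edt * edt).astype(np.int64)

    out2 = np.zeros(fg.shape, dtype=np.int64)  # squared radius of best sphere
    unassigned = fg.copy()
    for r2v in np.sort(np.unique(r2[fg]))[::-1]:
        seeds = fg & (r2 == r2v)
        d = ndimage.distance_transform_edt(~seeds)
        d2 = np.round(d * d).astype(np.int64)
        covered = unassigned & (d2 <= r2v)
        out2[covered] = r2v
        unassigned &= ~covered
        if not unassigned.any():
            break

    th = np.full(fg.shape, np.nan)
    th[fg] = 2.0 * np.sqrt(out2[fg]) * mask.voxel_size_um
    return ThicknessMap(thickness_um=th, voxel_size_um=mask.voxel_size_um)


def subchondral_plate_thickness(plate_mask: BinaryMask, condyle_roi=None) -> float:
    """Mean local plate thickness (um) over the condyle.

    ``condyle_roi`` may be a 2D (y, x) boolean mask / CondyleROI restricting
    the columns that belong to the condyle, or None for the whole plate.
    """
    roi_xy = None
    if condyle_roi is not None:
        roi_xy = getattr(condyle_roi, "mask_xy", condyle_roi)
        roi_xy = np.asarray(roi_xy, dtype=bool)
    select = plate_mask.data.copy()
    if roi_xy is not None:
        select &= roi_xy[None, :, :]
    if not select.any():
        raise EmptyROIError("condyle ROI does not intersect the plate mask")
    tm = local_thickness(plate_mask)
    return float(np.nanmean(tm.thickness_um[select]))


def build_trabecular_roi(
    medullary_mask: BinaryMask,
    erosion_radius_um: float = 315.0,
    kernel: str = "disc2d",
) -> BinaryMask:
    """Erode the medullary volume to a trabecular ROI clear of its borders.

    The physical radius is converted to voxels by rounding to the nearest
    integer. ``disc2d`` erodes each axis-0 (coronal) slice with a closed
    disc; ``ball3d`` uses a closed ball. Outside the array counts as
    background, so the ROI also retreats from the volume borders.
    """
    r_vox = int(round(erosion_radius_um / medullary_mask.voxel_size_um))
    if kernel == "disc2d":
        yy, xx = np.mgrid[-r_vox : r_vox + 1, -r_vox : r_vox + 1]
        disc = (yy * yy + xx * xx) <= r_vox * r_vox
        structure = disc[None, :, :]
    elif kernel == "ball3d":
        zz, yy, xx = np.mgrid[-r_vox : r_vox + 1, -r_vox : r_vox + 1, -r_vox : r_vox + 1]
        structure = (zz * zz + yy * yy + xx * xx) <= r_vox * r_vox
    else:
        raise ValueError(f"kernel must be 'disc2d' or 'ball3d', got {kernel!r}")
    eroded = ndimage.binary_erosion(
        medullary_mask.data, structure=structure, border_value=0
    )
    if not eroded.any():
        raise EmptyROIError(
            f"erosion by {erosion_radius_um} um ({r_vox} voxels) emptied the ROI"
        )
    return BinaryMask(eroded, medullary_mask.voxel_size_um)


def trabecular_metrics(bone_mask: BinaryMask, roi: BinaryMask) -> TrabecularMetrics:
    """BV/TV, Tb.Th and Tb.Sp within a trabecular ROI.

    BV/TV is the exact voxel-count ratio. Tb.Th averages the bone-phase
    thickness map over bone voxels inside the ROI (volume-weighted mean, the
    standard model-independent definition); Tb.Sp does the same for the
    marrow phase. When the ROI holds no bone, BV/TV is 0 and Tb.Th is
    reported as missing (None), not zero.
    """
    if bone_mask.shape != roi.shape:
        raise EmptyROIError("bone mask and ROI shapes differ")
    roi_n = int(np.count_nonzero(roi.data))
    if roi_n == 0:
        raise EmptyROIError("trabecular ROI is empty")
    bone_in = bone_mask.data & roi.data
    bv_tv = 100.0 * np.count_nonzero(bone_in) / roi_n

    tb_th = None
    if bone_in.any():
        th_bone = local_thickness(bone_mask)
        tb_th = float(np.nanmean(th_bone.thickness_um[bone_in]))

    marrow_in = ~bone_mask.data & roi.data
    tb_sp = None
    if marrow_in.any():
        th_marrow = local_thickness(BinaryMask(~bone_mask.data, bone_mask.voxel_size_um))
        tb_sp = float(np.nanmean(th_marrow.thickness_um[marrow_in]))

    return TrabecularMetrics(
        bv_tv_percent=bv_tv, tb_th_um=tb_th, tb_sp_um=tb_sp, roi_voxels=roi_n
    )
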