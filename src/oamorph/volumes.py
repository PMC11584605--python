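"""Image containers and file I/O.

All volumetric data is held in ZYX axis order with 0-based indices; voxel
centers sit at ``index * voxel_size_um + origin_um``. Only isotropic volumes
are supported — anisotropic spacing raises :class:`GeometryError` instead of
silently resampling, because resampling would hide resolution effects in the
surface-roughness pipeline. Every downstream module receives physical units
(um, mm, N); bare voxel counts never cross module boundaries.

Supported formats: multipage TIFF or a directory of per-slice TIFFs, and
NIfTI-1 (which carries the voxel spacing; TIFF requires an explicit
``voxel_size_um``). 2D sections are TIFF/PNG; curves and gait tables are CSV.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

from .errors import GeometryError, SchemaError, UnitError

__all__ = [
    "ImageVolume",
    "BinaryMask",
    "SectionImage",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_curve",
    "read_gait_table",
]

_ISO_RTOL = 1e-3  # relative tolerance when deciding whether spacing is isotropic


@dataclass
class ImageVolume:
    """A 3D scalar grid (ZYX) with isotropic physical voxel size in um."""

    data: np.ndarray
    voxel_size_um: float
    origin_um: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise GeometryError(f"volume must be 3D, got shape {self.data.shape}")
        if not np.isfinite(self.voxel_size_um) or self.voxel_size_um <= 0:
            raise UnitError(f"voxel_size_um must be positive, got {self.voxel_size_um}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")
        self.origin_um = np.asarray(self.origin_um, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class BinaryMask:
    """A 3D boolean grid (ZYX) with isotropic voxel size in um."""

    data: np.ndarray
    voxel_size_um: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise GeometryError(f"mask must be 3D, got shape {self.data.shape}")
        if self.data.dtype != bool:
            self.data = self.data > 0
        if not np.isfinite(self.voxel_size_um) or self.voxel_size_um <= 0:
            raise UnitError(f"voxel_size_um must be positive, got {self.voxel_size_um}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class SectionImage:
    """A 2D histology/fluorescence image with named channels.

    ``pixels`` is (H, W, C); for RGB stains the channels are ("R", "G", "B"),
    for immunofluorescence e.g. ("Hoechst", "CX3CR1", "CD68"). Channels are
    addressed by name so channel order never matters downstream.
    """

    pixels: np.ndarray
    pixel_size_um: float
    channel_names: tuple[str, ...] = ("R", "G", "B")

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[..., None]
        if self.pixels.ndim != 3:
            raise GeometryError(f"section must be 2D(+channels), got {self.pixels.shape}")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.pixels.shape[-1]:
            raise SchemaError(
                f"{len(self.channel_names)} channel names for "
                f"{self.pixels.shape[-1]} channels"
            )
        if not np.isfinite(self.pixel_size_um) or self.pixel_size_um <= 0:
            raise UnitError(f"pixel_size_um must be positive, got {self.pixel_size_um}")

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise SchemaError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None
        return self.pixels[..., idx]


def _check_isotropic(zooms_um) -> float:
    zooms = np.asarray(zooms_um, dtype=float)
    if zooms.min() <= 0:
        raise UnitError(f"non-positive voxel spacing {tuple(zooms)}")
    if (zooms.max() - zooms.min()) > _ISO_RTOL * zooms.mean():
        raise GeometryError(
            f"anisotropic spacing {tuple(zooms)} um is unsupported; "
            "resample to isotropic voxels before analysis"
        )
    return float(zooms.mean())


def read_volume(path: str, voxel_size_um: float | None = None) -> ImageVolume:
    """Read a TIFF stack/multipage TIFF or NIfTI file as an :class:`ImageVolume`.

    The voxel size comes from NIfTI metadata or from the explicit override;
    TIFF carries no trusted physical spacing, so an override is required —
    guessing units would silently corrupt every downstream metric.
    """
    lower = str(path).lower()
    if lower.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        zooms_mm = img.header.get_zooms()[:3]
        meta_um = _check_isotropic(np.asarray(zooms_mm) * 1000.0)
        if voxel_size_um is None:
            voxel_size_um = meta_um
        data = np.asanyarray(img.dataobj)  # XYZ on disk
        data = np.transpose(data, (2, 1, 0))  # -> ZYX
        return ImageVolume(np.ascontiguousarray(data), voxel_size_um)
    if os.path.isdir(path):
        files = sorted(
            os.path.join(path, f)
            for f in os.listdir(path)
            if f.lower().endswith((".tif", ".tiff"))
        )
        if not files:
            raise FileNotFoundError(f"no TIFF slices in {path}")
        data = np.stack([tifffile.imread(f) for f in files], axis=0)
    elif lower.endswith((".tif", ".tiff")):
        data = tifffile.imread(str(path))
    else:
        raise UnitError(f"unsupported volume format: {path}")
    if voxel_size_um is None:
        raise UnitError(
            f"{path}: TIFF carries no trusted voxel size; pass voxel_size_um"
        )
    return ImageVolume(data, voxel_size_um)


def write_volume(volume: ImageVolume, path: str) -> str:
    """Write a volume losslessly; ``read_volume`` round-trips the grid."""
    lower = str(path).lower()
    if lower.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        mm = volume.voxel_size_um / 1000.0
        affine = np.diag([mm, mm, mm, 1.0])
        img = nib.Nifti1Image(np.transpose(volume.data, (2, 1, 0)), affine)
        img.header.set_zooms((mm, mm, mm))
        nib.save(img, str(path))
    elif lower.endswith((".tif", ".tiff")):
        tifffile.imwrite(str(path), volume.data)
    else:
        raise UnitError(f"unsupported volume format: {path}")
    return str(path)


def read_mask(path: str, voxel_size_um: float | None = None) -> BinaryMask:
    """Read a 0/255 (or 0/1) TIFF or NIfTI volume as a boolean mask."""
    vol = read_volume(path, voxel_size_um=voxel_size_um)
    return BinaryMask(vol.data > 0, vol.voxel_size_um)


def write_mask(mask: BinaryMask, path: str) -> str:
    return write_volume(
        ImageVolume(mask.data.astype(np.uint8) * 255, mask.voxel_size_um), path
    )


def read_curve(path: str, extension_rate_mm_s: float = 0.03,
               load_cell_max_N: float = 50.0):
    """Read a load–displacement CSV (columns ``displacement_mm, load_N``).

    Displacement must be strictly increasing (a tensile ramp at constant
    extension rate); violations raise :class:`SchemaError`.
    """
    from .mechanics import LoadDisplacementCurve

    df = pd.read_csv(path)
    required = {"displacement_mm", "load_N"}
    if not required.issubset(df.columns):
        raise SchemaError(f"{path}: need columns {sorted(required)}, got {list(df.columns)}")
    return LoadDisplacementCurve(
        displacement_mm=df["displacement_mm"].to_numpy(float),
        load_N=df["load_N"].to_numpy(float),
        extension_rate_mm_s=extension_rate_mm_s,
        load_cell_max_N=load_cell_max_N,
    )


GAIT_COLUMNS = ("day", "run", "side", "run_speed_variation_percent")


def read_gait_table(path: str, injected_side: str = "left"):
    """Read a long-format gait CSV into one :class:`GaitSession` per day.

    Schema: one row per (day, run, side) with ``run_speed_variation_percent``
    plus per-paw metric columns (``duty_cycle_percent``, ``swing_speed_mm_s``,
    ``stand_s``, ...). Returns ``{day: GaitSession}``.
    """
    from .gait import GaitSession

    df = pd.read_csv(path)
    missing = [c for c in GAIT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing gait columns {missing}")
    sessions = {}
    for day, sub in df.groupby("day"):
        sessions[int(day)] = GaitSession(
            day=int(day),
            injected_side=injected_side,
            runs=sub.drop(columns="day").reset_index(drop=True),
        )
    return sessions
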