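"""Quantitative synovial histomorphometry and immunofluorescence.

Three readouts from stained sections of the peripatellar joint capsule:

* synovial thickness — mean nearest distance from the synovial lining contour
  to the fibrous membrane contour (um);
* synovial cellularity — nuclei per mm^2 from the hematoxylin channel after
  Ruifrok–Johnston colour deconvolution of H&E images;
* collagen density — fraction of region pixels above an aniline-blue optical
  density threshold after trichrome deconvolution.

Immunofluorescence sections (Hoechst / CX3CR1 / CD68) are analyzed with
nuclei as cell anchors: each Hoechst-detected nucleus is dilated by a ring
radius, marker intensities are averaged inside, positivity is thresholded
per channel, and every cell receives exactly one of four exhaustive classes
(CX3CR1+, CD68+CX3CR1-, double+, negative) plus a lining/sublining
compartment from the user annotation. Up to four regions of interest
(medial/lateral x proximal/distal) per synovium are averaged unweighted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import LineString, Point, Polygon

from .errors import EmptyROIError, SchemaError
from .volumes import SectionImage

__all__ = [
    "SynoviumAnnotation",
    "HistoMeasurements",
    "CellTable",
    "NucleiConfig",
    "MASSON_RGB_FROM_STAINS",
    "measure_synovial_thickness",
    "detect_nuclei",
    "measure_cell_density",
    "measure_collagen_fraction",
    "classify_if_cells",
    "average_rois",
]

CELL_CLASSES = ("CX3CR1+", "CD68+CX3CR1-", "double+", "negative")
COMPARTMENTS = ("lining", "sublining")


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


# Masson's trichrome OD vectors (Biebrich scarlet / aniline blue); the third
# row completes an orthogonal basis for the residual channel.
_SCARLET = _unit([0.80, 0.59, 0.11])
_ANILINE_BLUE = _unit([0.10, 0.74, 0.67])
MASSON_RGB_FROM_STAINS = np.array(
    [_SCARLET, _ANILINE_BLUE, _unit(np.cross(_SCARLET, _ANILINE_BLUE))]
)


@dataclass
class SynoviumAnnotation:
    """User-drawn synovium geometry for one region of interest.

    Contours are polylines in um image coordinates (x, y). ``compartments``
    maps "lining"/"sublining" to polygon vertex arrays; they must not
    overlap. ``roi_id`` is one of up to four regions
    (medial/lateral x proximal/distal).
    """

    lining_contour: np.ndarray
    fibrous_membrane_contour: np.ndarray
    compartments: dict = field(default_factory=dict)
    roi_id: str = "medial-proximal"

    def __post_init__(self) -> None:
        self.lining_contour = np.asarray(self.lining_contour, dtype=float)
        self.fibrous_membrane_contour = np.asarray(
            self.fibrous_membrane_contour, dtype=float
        )
        for name, contour in (
            ("lining", self.lining_contour),
            ("fibrous membrane", self.fibrous_membrane_contour),
        ):
            if contour.ndim != 2 or contour.shape[1] != 2 or contour.shape[0] < 2:
                raise SchemaError(f"{name} contour must be an (N, 2) polyline")
            if not LineString(contour).is_simple:
                raise SchemaError(f"{name} contour is self-intersecting")
        polys = {k: Polygon(v) for k, v in self.compartments.items()}
        for name, p in polys.items():
            if not p.is_valid:
                raise SchemaError(f"compartment {name!r} polygon is invalid")
        if {"lining", "sublining"} <= set(polys):
            inter = polys["lining"].intersection(polys["sublining"]).area
            if inter > 1e-9 * max(polys["lining"].area, 1e-12):
                raise SchemaError("lining and sublining compartments overlap")

    def region_polygon(self) -> Polygon:
        """The measured region: union of compartments if given, else the
        polygon enclosed by the lining and membrane contours."""
        if self.compartments:
            poly = Polygon()
            for coords in self.compartments.values():
                poly = poly.union(Polygon(coords))
            return poly
        ring = np.vstack([self.lining_contour, self.fibrous_membrane_contour[::-1]])
        return Polygon(ring)


@dataclass
class HistoMeasurements:
    thickness_um: float | None = None
    cell_density_per_mm2: float | None = None
    collagen_fraction: float | None = None
    roi_id: str = ""

    def __post_init__(self) -> None:
        for name in ("thickness_um", "cell_density_per_mm2", "collagen_fraction"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.collagen_fraction is not None and self.collagen_fraction > 1:
            raise ValueError("collagen_fraction must be <= 1")


@dataclass
class CellTable:
    """Per-cell records: centroid (um), nucleus area (um^2), per-marker mean
    intensity, class label and compartment."""

    cells: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"x_um", "y_um", "nucleus_area_um2", "cell_class", "compartment"}
        if not required.issubset(self.cells.columns):
            raise SchemaError(f"cell table needs columns {sorted(required)}")
        if not set(self.cells["cell_class"]).issubset(CELL_CLASSES):
            raise SchemaError("unknown cell class label")
        if not set(self.cells["compartment"]).issubset(COMPARTMENTS):
            raise SchemaError("unknown compartment label")

    def __len__(self) -> int:
        return len(self.cells)

    def class_counts(self) -> dict[str, int]:
        counts = self.cells["cell_class"].value_counts()
        return {c: int(counts.get(c, 0)) for c in CELL_CLASSES}

    def compartment_counts(self) -> dict[str, int]:
        counts = self.cells["compartment"].value_counts()
        return {c: int(counts.get(c, 0)) for c in COMPARTMENTS}


@dataclass
class NucleiConfig:
    """Nuclei detection knobs (defaults sized for ~7 um rat synovial nuclei)."""

    smooth_um: float = 1.0
    min_area_um2: float = 8.0
    min_distance_um: float = 4.0
    od_floor: float = 0.08          # below this peak OD a channel is empty
    threshold: float | None = None  # fixed OD threshold override (None = Otsu)


# ---------------------------------------------------------------------------
# geometry


def measure_synovial_thickness(
    annotation: SynoviumAnnotation, sample_spacing_um: float = 1.0
) -> float:
    """Mean nearest distance (um) from the lining to the membrane contour."""
    lining = LineString(annotation.lining_contour)
    membrane = LineString(annotation.fibrous_membrane_contour)
    if lining.equals(membrane):  # coincident contours: fully collapsed synovium
        return 0.0
    if lining.intersects(membrane):
        raise SchemaError("lining and membrane contours intersect")
    n = max(int(np.ceil(lining.length / sample_spacing_um)) + 1, 2)
    distances = [
        lining.interpolate(t, normalized=True).distance(membrane)
        for t in np.linspace(0.0, 1.0, n)
    ]
    return float(np.mean(distances))


def _polygon_mask(poly: Polygon, shape: tuple[int, int], pixel_size_um: float) -> np.ndarray:
    from skimage.draw import polygon as draw_polygon

    mask = np.zeros(shape, dtype=bool)
    geoms = poly.geoms if hasattr(poly, "geoms") else [poly]
    for g in geoms:
        x, y = np.asarray(g.exterior.coords).T
        rr, cc = draw_polygon(y / pixel_size_um, x / pixel_size_um, shape=shape)
        mask[rr, cc] = True
    return mask


# ---------------------------------------------------------------------------
# nuclei


def detect_nuclei(
    od: np.ndarray, pixel_size_um: float, config: NucleiConfig | None = None,
    region_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Detect nuclei in an optical-density channel.

    Gaussian smoothing, Otsu (or fixed) threshold, distance-transform peaks
    and watershed to split touching nuclei, then a minimum-area filter.
    Returns one row per nucleus: label, x_um, y_um, nucleus_area_um2.
    """
    from skimage.feature import peak_local_max
    from skimage.filters import threshold_otsu
    from skimage.measure import regionprops
    from skimage.segmentation import watershed

    cfg = config or NucleiConfig()
    empty = pd.DataFrame(columns=["label", "x_um", "y_um", "nucleus_area_um2"])
    od = np.asarray(od, dtype=float)
    work = od.copy()
    if region_mask is not None:
        work[~region_mask] = 0.0
    if work.max() < cfg.od_floor:
        return empty
    smoothed = ndimage.gaussian_filter(work, cfg.smooth_um / pixel_size_um)
    thr = cfg.threshold
    if thr is None:
        thr = float(threshold_otsu(smoothed))
        thr = max(thr, cfg.od_floor)
    binary = smoothed > thr
    if not binary.any():
        return empty

    distance = ndimage.distance_transform_edt(binary)
    min_dist_px = max(int(round(cfg.min_distance_um / pixel_size_um)), 1)
    peaks = peak_local_max(
        distance, min_distance=min_dist_px, labels=binary, exclude_border=False
    )
    markers = np.zeros(binary.shape, dtype=int)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-distance, markers, mask=binary)

    rows = []
    px_area = pixel_size_um**2
    for prop in regionprops(labels):
        area = prop.area * px_area
        if area < cfg.min_area_um2:
            continue
        cy, cx = prop.centroid
        rows.append(
            {
                "label": prop.label,
                "x_um": cx * pixel_size_um,
                "y_um": cy * pixel_size_um,
                "nucleus_area_um2": area,
            }
        )
    return pd.DataFrame(rows) if rows else empty


def measure_cell_density(
    section: SectionImage,
    region: SynoviumAnnotation | None = None,
    config: NucleiConfig | None = None,
) -> float:
    """Nuclei per mm^2 in an H&E section within the annotated region."""
    from skimage.color import separate_stains, hed_from_rgb

    rgb = section.pixels[..., :3].astype(float)
    if rgb.max() > 1.0:
        rgb = rgb / 255.0
    hed = separate_stains(rgb, hed_from_rgb)
    hematoxylin = hed[..., 0]

    if region is not None:
        poly = region.region_polygon()
        mask = _polygon_mask(poly, hematoxylin.shape, section.pixel_size_um)
        area_mm2 = poly.area / 1e6
    else:
        mask = None
        area_mm2 = hematoxylin.size * section.pixel_size_um**2 / 1e6
    if area_mm2 <= 0:
        raise EmptyROIError("region area is zero")
    nuclei = detect_nuclei(hematoxylin, section.pixel_size_um, config, region_mask=mask)
    return len(nuclei) / area_mm2


def measure_collagen_fraction(
    section: SectionImage,
    region: SynoviumAnnotation | None = None,
    od_threshold: float = 0.15,
    rgb_from_stains: np.ndarray = MASSON_RGB_FROM_STAINS,
) -> float:
    """Fraction of region pixels above the aniline-blue OD threshold."""
    from skimage.color import separate_stains

    rgb = section.pixels[..., :3].astype(float)
    if rgb.max() > 1.0:
        rgb = rgb / 255.0
    stains = separate_stains(rgb, np.linalg.inv(rgb_from_stains))
    blue_od = stains[..., 1]
    if region is not None:
        mask = _polygon_mask(
            region.region_polygon(), blue_od.shape, section.pixel_size_um
        )
    else:
        mask = np.ones(blue_od.shape, dtype=bool)
    n = int(np.count_nonzero(mask))
    if n == 0:
        raise EmptyROIError("region is empty")
    return float(np.count_nonzero(blue_od[mask] > od_threshold)) / n


# ---------------------------------------------------------------------------
# immunofluorescence


def _marker_positive(intensities: np.ndarray, abs_floor: float,
                     fixed_threshold: float | None) -> np.ndarray:
    """Per-cell positivity for one marker channel.

    Default: Otsu on the nucleus-sampled intensities, floored at an absolute
    minimum so a marker-free section never splits noise into a positive
    class; a fixed threshold overrides both.
    """
    from skimage.filters import threshold_otsu

    if fixed_threshold is not None:
        return intensities > fixed_threshold
    if intensities.size == 0:
        return np.zeros(0, dtype=bool)
    if np.ptp(intensities) < abs_floor:  # unimodal: all-negative or all-positive
        return intensities > abs_floor
    thr = max(float(threshold_otsu(intensities)), abs_floor)
    return intensities > thr


def classify_if_cells(
    section: SectionImage,
    annotation: SynoviumAnnotation | None = None,
    nuclei_config: NucleiConfig | None = None,
    ring_radius_um: float = 1.5,
    marker_floor: float = 0.15,
    marker_thresholds: dict[str, float] | None = None,
    nuclear_channel: str = "Hoechst",
    marker_channels: tuple[str, str] = ("CX3CR1", "CD68"),
) -> CellTable:
    """Nuclei-anchored cell classification on a multichannel IF image.

    Channels are addressed by name, so channel order is irrelevant. Marker
    intensity per cell is the mean over the nucleus dilated by
    ``ring_radius_um``; positivity per channel uses Otsu over cell
    intensities (floored) or a fixed per-channel threshold.
    """
    for ch in (nuclear_channel, *marker_channels):
        if ch not in section.channel_names:
            raise SchemaError(f"missing channel {ch!r} in {section.channel_names}")
    hoechst = np.asarray(section.channel(nuclear_channel), dtype=float)
    nuclei = detect_nuclei(hoechst, section.pixel_size_um, nuclei_config)
    cx_name, cd_name = marker_channels

    if nuclei.empty:
        return CellTable(
            cells=pd.DataFrame(
                columns=[
                    "x_um", "y_um", "nucleus_area_um2",
                    f"intensity_{cx_name}", f"intensity_{cd_name}",
                    "cell_class", "compartment",
                ]
            ).astype({"cell_class": str, "compartment": str})
        )

    # re-derive the label image to sample marker intensity per nucleus
    cfg = nuclei_config or NucleiConfig()
    smoothed = ndimage.gaussian_filter(hoechst, cfg.smooth_um / section.pixel_size_um)
    from skimage.filters import threshold_otsu
    from skimage.segmentation import watershed

    thr = cfg.threshold or max(float(threshold_otsu(smoothed)), cfg.od_floor)
    binary = smoothed > thr
    distance = ndimage.distance_transform_edt(binary)
    seeds = np.zeros(binary.shape, dtype=int)
    rr = (nuclei["y_um"] / section.pixel_size_um).round().astype(int).clip(0, binary.shape[0] - 1)
    cc = (nuclei["x_um"] / section.pixel_size_um).round().astype(int).clip(0, binary.shape[1] - 1)
    seeds[rr, cc] = nuclei["label"].to_numpy()
    labels = watershed(-distance, seeds, mask=binary)

    ring_px = max(int(round(ring_radius_um / section.pixel_size_um)), 1)
    dilated = ndimage.grey_dilation(labels, size=2 * ring_px + 1)
    dilated[labels > 0] = labels[labels > 0]

    intensities = {}
    for name in marker_channels:
        chan = np.asarray(section.channel(name), dtype=float)
        means = ndimage.mean(chan, labels=dilated, index=nuclei["label"].to_numpy())
        intensities[name] = np.asarray(means)

    fixed = marker_thresholds or {}
    cx_pos = _marker_positive(intensities[cx_name], marker_floor, fixed.get(cx_name))
    cd_pos = _marker_positive(intensities[cd_name], marker_floor, fixed.get(cd_name))

    cell_class = np.where(
        cx_pos & cd_pos, "double+",
        np.where(cx_pos, "CX3CR1+", np.where(cd_pos, "CD68+CX3CR1-", "negative")),
    )

    if annotation is not None and "lining" in annotation.compartments:
        lining = Polygon(annotation.compartments["lining"])
        compartment = [
            "lining" if lining.covers(Point(x, y)) else "sublining"
            for x, y in zip(nuclei["x_um"], nuclei["y_um"])
        ]
    else:
        compartment = ["sublining"] * len(nuclei)

    cells = pd.DataFrame(
        {
            "x_um": nuclei["x_um"],
            "y_um": nuclei["y_um"],
            "nucleus_area_um2": nuclei["nucleus_area_um2"],
            f"intensity_{cx_name}": intensities[cx_name],
            f"intensity_{cd_name}": intensities[cd_name],
            "cell_class": cell_class,
            "compartment": compartment,
        }
    )
    return CellTable(cells=cells)


def average_rois(measurements: list[HistoMeasurements]) -> HistoMeasurements:
    """Unweighted mean of up to four per-ROI measurement records."""
    if not measurements:
        raise SchemaError("no ROI measurements to average")
    if len(measurements) > 4:
        raise SchemaError("at most 4 ROIs per synovium")

    def mean_of(name):
        vals = [getattr(m, name) for m in measurements if getattr(m, name) is not None]
        return float(np.mean(vals)) if vals else None

    return HistoMeasurements(
        thickness_um=mean_of("thickness_um"),
        cell_density_per_mm2=mean_of("cell_density_per_mm2"),
        collagen_fraction=mean_of("collagen_fraction"),
        roi_id="mean",
    )
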