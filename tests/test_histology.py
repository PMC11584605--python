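"""Synovial histomorphometry and immunofluorescence classification."""

import numpy as np
import pytest

from oamorph.errors import SchemaError
from oamorph.histology import (
    HistoMeasurements,
    SynoviumAnnotation,
    average_rois,
    classify_if_cells,
    measure_cell_density,
    measure_collagen_fraction,
    measure_synovial_thickness,
)
from oamorph.phantoms import (
    make_fluorescence_phantom,
    make_histology_phantom,
    make_trichrome_phantom,
)
from oamorph.volumes import SectionImage


def _parallel_annotation(gap_um, length_um=500.0):
    return SynoviumAnnotation(
        lining_contour=np.array([[0.0, 0.0], [length_um, 0.0]]),
        fibrous_membrane_contour=np.array([[0.0, gap_um], [length_um, gap_um]]),
    )


class TestSynovialThickness:
    def test_parallel_contours_at_saline_magnitude(self):
        ann = _parallel_annotation(345.0)
        assert measure_synovial_thickness(ann) == pytest.approx(345.0)

    def test_concentric_circles_give_annulus_width(self):
        t = np.linspace(0, 2 * np.pi, 721)
        inner = np.c_[200 * np.cos(t), 200 * np.sin(t)]
        outer = np.c_[320 * np.cos(t), 320 * np.sin(t)]
        ann = SynoviumAnnotation(inner[:-1], outer[:-1])
        assert measure_synovial_thickness(ann) == pytest.approx(120.0, rel=0.005)

    def test_identical_contours_measure_zero(self):
        line = np.array([[0.0, 0.0], [100.0, 0.0]])
        assert measure_synovial_thickness(SynoviumAnnotation(line, line)) == 0.0

    def test_intersecting_contours_raise(self):
        a = np.array([[0.0, 0.0], [100.0, 100.0]])
        b = np.array([[0.0, 100.0], [100.0, 0.0]])
        with pytest.raises(SchemaError):
            measure_synovial_thickness(SynoviumAnnotation(a, b))

    def test_near_symmetric_under_contour_exchange(self):
        t = np.linspace(0, 2 * np.pi, 721)[:-1]
        inner = np.c_[200 * np.cos(t), 200 * np.sin(t)]
        outer = np.c_[320 * np.cos(t), 320 * np.sin(t)]
        fwd = measure_synovial_thickness(SynoviumAnnotation(inner, outer))
        rev = measure_synovial_thickness(SynoviumAnnotation(outer, inner))
        assert fwd == pytest.approx(rev, rel=0.01)


class TestCellDensity:
    def test_planted_density_recovered_within_five_percent(self):
        ph = make_histology_phantom(density_per_mm2=2000.0, seed=10)
        measured = measure_cell_density(ph.section)
        assert measured == pytest.approx(ph.ground_truth["density_per_mm2"], rel=0.05)

    def test_blank_eosin_only_phantom_counts_zero(self):
        ph = make_histology_phantom(density_per_mm2=0.0, seed=0)
        assert measure_cell_density(ph.section) == 0.0

    def test_density_doubles_linearly(self):
        lo = make_histology_phantom(density_per_mm2=1500.0, seed=3)
        hi = make_histology_phantom(density_per_mm2=3000.0, seed=3)
        d_lo = measure_cell_density(lo.section)
        d_hi = measure_cell_density(hi.section)
        assert d_hi / d_lo == pytest.approx(2.0, rel=0.10)


class TestCollagenFraction:
    @pytest.mark.parametrize("planted", [0.0, 0.3, 1.0])
    def test_planted_fraction_recovered(self, planted):
        ph = make_trichrome_phantom(planted, seed=5)
        measured = measure_collagen_fraction(ph.section)
        assert measured == pytest.approx(ph.ground_truth["collagen_fraction"], abs=0.02)

    def test_monotone_in_planted_fraction(self):
        fractions = [0.1, 0.35, 0.6, 0.85]
        measured = [
            measure_collagen_fraction(make_trichrome_phantom(f, seed=6).section)
            for f in fractions
        ]
        assert all(a < b for a, b in zip(measured, measured[1:]))


class TestIFClassification:
    def test_planted_class_counts_recovered(self):
        ph = make_fluorescence_phantom(
            {"CX3CR1+": 50, "CD68+CX3CR1-": 30, "double+": 0, "negative": 20}, seed=8
        )
        table = classify_if_cells(ph.section, ph.annotation)
        counts = table.class_counts()
        for cls, n_true in ph.ground_truth["class_counts"].items():
            assert counts[cls] == pytest.approx(n_true, abs=max(1, 0.05 * n_true))

    def test_class_and_compartment_counts_sum_to_total(self):
        ph = make_fluorescence_phantom(seed=9)
        table = classify_if_cells(ph.section, ph.annotation)
        assert sum(table.class_counts().values()) == len(table)
        assert sum(table.compartment_counts().values()) == len(table)
        assert table.compartment_counts() == ph.ground_truth["compartment_counts"]

    def test_all_negative_phantom(self):
        ph = make_fluorescence_phantom(
            {"CX3CR1+": 0, "CD68+CX3CR1-": 0, "double+": 0, "negative": 40}, seed=11
        )
        table = classify_if_cells(ph.section, ph.annotation)
        assert table.class_counts()["negative"] == len(table) > 0

    def test_channel_order_irrelevant_with_names(self):
        ph = make_fluorescence_phantom(seed=12)
        t1 = classify_if_cells(ph.section, ph.annotation)
        perm = [2, 0, 1]
        swapped = SectionImage(
            ph.section.pixels[..., perm],
            ph.section.pixel_size_um,
            tuple(ph.section.channel_names[i] for i in perm),
        )
        t2 = classify_if_cells(swapped, ph.annotation)
        assert t1.class_counts() == t2.class_counts()

    def test_missing_channel_raises(self):
        ph = make_fluorescence_phantom(seed=13)
        two = SectionImage(
            ph.section.pixels[..., :2], ph.section.pixel_size_um,
            ph.section.channel_names[:2],
        )
        with pytest.raises(SchemaError):
            classify_if_cells(two, ph.annotation)


class TestROIAveraging:
    def test_mean_of_two_thicknesses(self):
        out = average_rois(
            [HistoMeasurements(thickness_um=300.0), HistoMeasurements(thickness_um=400.0)]
        )
        assert out.thickness_um == 350.0

    def test_single_roi_is_identity(self):
        m = HistoMeasurements(thickness_um=512.0, cell_density_per_mm2=2100.0,
                              collagen_fraction=0.4)
        out = average_rois([m])
        assert (out.thickness_um, out.cell_density_per_mm2, out.collagen_fraction) == (
            512.0, 2100.0, 0.4,
        )

    def test_four_roi_density_mean(self):
        ms = [HistoMeasurements(cell_density_per_mm2=v) for v in (1000, 2000, 3000, 4000)]
        assert average_rois(ms).cell_density_per_mm2 == 2500.0

    def test_empty_and_oversized_lists_raise(self):
        with pytest.raises(SchemaError):
            average_rois([])
        with pytest.raises(SchemaError):
            average_rois([HistoMeasurements(thickness_um=1.0)] * 5)
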