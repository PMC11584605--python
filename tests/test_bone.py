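"""Bone morphometry: closed forms, exhaustive sphere oracle, erosion oracle."""

import numpy as np
import pytest
from helpers import (
    brute_force_local_thickness,
    erosion_by_distance_transform,
    random_blob_mask,
)
from scipy import ndimage

from oamorph.bone import (
    build_trabecular_roi,
    local_thickness,
    subchondral_plate_thickness,
    trabecular_metrics,
)
from oamorph.errors import EmptyROIError
from oamorph.phantoms import (
    make_cylinder_phantom,
    make_plate_phantom,
    make_rod_lattice_phantom,
    make_slab_phantom,
    rod_lattice_volume_fraction,
)
from oamorph.volumes import BinaryMask


class TestLocalThickness:
    def test_slab_thickness_exact(self):
        ph = make_slab_phantom(10)
        tm = local_thickness(ph.mask)
        vals = tm.thickness_um[ph.mask.data]
        np.testing.assert_allclose(vals, ph.ground_truth["thickness_um"])

    def test_cylinder_mean_within_one_voxel(self):
        ph = make_cylinder_phantom(13)
        tm = local_thickness(ph.mask)
        mean_um = float(np.nanmean(tm.thickness_um))
        assert abs(mean_um - ph.ground_truth["diameter_um"]) <= 4.5

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_exhaustive_sphere_oracle(self, seed):
        mask = random_blob_mask((12, 12, 12), seed)
        if not mask.any() or mask.all():
            pytest.skip("degenerate random draw")
        tm = local_thickness(BinaryMask(mask, 1.0))
        oracle = brute_force_local_thickness(mask)
        np.testing.assert_allclose(
            tm.thickness_um[mask], oracle[mask], rtol=0, atol=1e-9
        )

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyROIError):
            local_thickness(BinaryMask(np.zeros((4, 4, 4), bool), 1.0))


class TestPlateThickness:
    def test_slab_mean_matches_planted_thickness(self):
        ph = make_slab_phantom(20)  # 90 um at 4.5 um voxels
        mean = subchondral_plate_thickness(ph.mask)
        assert abs(mean - 90.0) <= 4.5

    def test_two_thickness_slab_mixture_mean(self):
        h = 4.5
        data = np.zeros((40, 20, 40), bool)
        data[5:16, :, :20] = True   # ~50 um half
        data[5:27, :, 20:] = True   # ~99 um half
        mask = BinaryMask(data, h)
        mean = subchondral_plate_thickness(mask)
        t1, t2 = 11 * h, 22 * h
        expected = (11 * t1 + 22 * t2) / 33  # volume-weighted mixture
        assert abs(mean - expected) <= h

    def test_disjoint_roi_raises(self):
        ph = make_slab_phantom(6, lateral=10)
        roi = np.zeros((10, 10), bool)
        with pytest.raises(EmptyROIError):
            subchondral_plate_thickness(ph.mask, roi)


class TestTrabecularROI:
    def test_square_closed_form(self):
        # 200x200 voxel square at 4.5 um, r = 315 um = 70 voxels -> side 60
        data = np.zeros((3, 220, 220), bool)
        data[:, 10:210, 10:210] = True
        roi = build_trabecular_roi(BinaryMask(data, 4.5), 315.0)
        per_slice = roi.data[1]
        ys, xs = np.nonzero(per_slice)
        assert ys.max() - ys.min() + 1 == 60
        assert xs.max() - xs.min() + 1 == 60
        assert per_slice.sum() == 60 * 60

    @pytest.mark.parametrize("kernel", ["disc2d", "ball3d"])
    def test_erosion_equals_distance_transform_threshold(self, kernel):
        for seed in range(20):
            mask = ndimage.binary_dilation(
                random_blob_mask((14, 30, 30), seed + 100), iterations=2
            )
            r_um = 3.0
            try:
                roi = build_trabecular_roi(
                    BinaryMask(mask, 1.0), r_um, kernel=kernel
                )
            except EmptyROIError:
                continue
            oracle = erosion_by_distance_transform(
                mask, int(round(r_um)), slicewise=(kernel == "disc2d")
            )
            np.testing.assert_array_equal(roi.data, oracle)

    def test_over_erosion_raises_empty_roi(self):
        data = np.zeros((3, 40, 300), bool)
        data[:, 9:31, :] = True  # ~100 um-wide strip at 4.5 um
        with pytest.raises(EmptyROIError):
            build_trabecular_roi(BinaryMask(data, 4.5), 315.0)


class TestTrabecularMetrics:
    def test_plate_phantom_closed_form(self):
        ph = make_plate_phantom()
        m = trabecular_metrics(ph.mask, ph.roi)
        t = ph.ground_truth
        assert m.bv_tv_percent == pytest.approx(t["bv_tv_percent"], abs=1e-9)
        assert abs(m.tb_th_um - t["tb_th_um"]) <= 4.5
        assert abs(m.tb_sp_um - t["tb_sp_um"]) <= 4.5

    def test_rod_lattice_fraction_matches_analytic(self):
        ph = make_rod_lattice_phantom()
        voxel_frac = ph.mask.data.mean()
        assert voxel_frac == pytest.approx(
            rod_lattice_volume_fraction(22.5, 135.0), rel=0.05
        )
        roi = BinaryMask(np.ones(ph.mask.shape, bool), ph.mask.voxel_size_um)
        m = trabecular_metrics(ph.mask, roi)
        assert m.bv_tv_percent == pytest.approx(100 * voxel_frac, abs=1e-9)

    def test_empty_bone_reports_missing_thickness(self):
        bone = BinaryMask(np.zeros((6, 6, 6), bool), 4.5)
        roi = BinaryMask(np.ones((6, 6, 6), bool), 4.5)
        m = trabecular_metrics(bone, roi)
        assert m.bv_tv_percent == 0.0
        assert m.tb_th_um is None

    def test_bvtv_invariant_under_translation_and_axis_permutation(self):
        ph = make_plate_phantom(n_periods=2, lateral=20)
        m1 = trabecular_metrics(ph.mask, ph.roi)
        rolled = BinaryMask(np.transpose(ph.mask.data, (1, 2, 0)), 4.5)
        roi_t = BinaryMask(np.transpose(ph.roi.data, (1, 2, 0)), 4.5)
        m2 = trabecular_metrics(rolled, roi_t)
        assert m1.bv_tv_percent == m2.bv_tv_percent
        assert m1.tb_th_um == pytest.approx(m2.tb_th_um)

    def test_dilation_monotonicity(self):
        ph = make_rod_lattice_phantom(rod_radius_um=18.0, spacing_um=135.0, n_cells=2)
        roi = BinaryMask(np.ones(ph.mask.shape, bool), ph.mask.voxel_size_um)
        m1 = trabecular_metrics(ph.mask, roi)
        dilated = BinaryMask(
            ndimage.binary_dilation(ph.mask.data), ph.mask.voxel_size_um
        )
        m2 = trabecular_metrics(dilated, roi)
        assert m2.bv_tv_percent > m1.bv_tv_percent
        assert m2.tb_th_um > m1.tb_th_um
        assert m2.tb_sp_um < m1.tb_sp_um
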