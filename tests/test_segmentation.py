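"""Thresholding, nucleus splitting and the two watershed stages."""

import numpy as np
import pytest
from scipy import ndimage

from neuroshape import (
    LabeledVolume,
    SegmentationParams,
    binarize_predictions,
    label_nuclei,
    match_labels,
    resample_isotropic,
    segment_cells,
    split_nuclei,
)


def _ball_mask(shape, center, radius):
    zz, yy, xx = np.indices(shape)
    return (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (
        xx - center[2]
    ) ** 2 <= radius**2


class TestBinarize:
    def test_thresholds_inclusive(self):
        nuc = np.array([[[0.7, 0.59], [0.61, 0.2]]])
        mem = np.full((1, 2, 2), 0.4)
        nm, mm = binarize_predictions(nuc, mem)
        assert np.array_equal(nm[0], [[1, 0], [1, 0]])
        assert mm.all()  # >= comparison keeps the boundary value

    def test_all_zero_probability(self):
        z = np.zeros((2, 2, 2))
        nm, mm = binarize_predictions(z, z)
        assert not nm.any() and not mm.any()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            binarize_predictions(np.zeros((2, 2, 2)), np.zeros((2, 2, 3)))

    def test_probability_range_checked(self):
        with pytest.raises(ValueError):
            binarize_predictions(np.full((1, 1, 1), 1.5), np.zeros((1, 1, 1)))


class TestSplitNuclei:
    def test_membrane_column_splits_plane(self):
        nuc = np.ones((1, 3, 3), dtype=bool)
        mem = np.zeros((1, 3, 3), dtype=bool)
        mem[0, :, 1] = True
        out = split_nuclei(nuc, mem)
        n_comp = ndimage.label(out)[1]
        assert n_comp == 2

    def test_no_membrane_is_identity(self):
        nuc = np.ones((2, 3, 3), dtype=bool)
        out = split_nuclei(nuc, np.zeros_like(nuc))
        assert np.array_equal(out, nuc)

    def test_roi_restricts_splitting(self):
        """With an ROI on the top row only that row is zeroed."""
        nuc = np.ones((1, 3, 3), dtype=bool)
        mem = np.zeros((1, 3, 3), dtype=bool)
        mem[0, :, 1] = True
        roi = np.zeros_like(mem)
        roi[0, 0, :] = True
        out = split_nuclei(nuc, mem, rois=roi)
        assert not out[0, 0, 1]
        assert out[0, 1, 1] and out[0, 2, 1]
        # connected-components oracle: the remaining mask is one piece
        assert ndimage.label(out)[1] == 1

    def test_roi_as_slices(self):
        nuc = np.ones((1, 3, 3), dtype=bool)
        mem = np.ones((1, 3, 3), dtype=bool)
        out = split_nuclei(nuc, mem, rois=[(slice(0, 1), slice(0, 1), slice(None))])
        assert not out[0, 0].any() and out[0, 1:].all()


class TestLabelNuclei:
    def test_two_disjoint_spheres(self):
        shape = (24, 24, 48)
        mask = _ball_mask(shape, (12, 12, 12), 6) | _ball_mask(shape, (12, 12, 36), 6)
        lv = label_nuclei(mask, SegmentationParams(smoothing_sigma=1.0))
        assert len(lv.ids) == 2
        for lab in lv.ids:
            sel = lv.labels == lab
            # each label coincides with one sphere
            assert ndimage.label(sel)[1] == 1

    def test_overlapping_spheres_cut_near_midplane(self):
        """The watershed interface must track the equidistance plane."""
        shape = (24, 30, 30)
        c1, c2 = (12, 15, 9), (12, 15, 21)
        mask = _ball_mask(shape, c1, 7) | _ball_mask(shape, c2, 7)
        lv = label_nuclei(mask, SegmentationParams(smoothing_sigma=1.0,
                                                   min_seed_distance=5))
        assert len(lv.ids) == 2
        zz, yy, xx = np.indices(shape)
        d1 = np.sqrt((zz - c1[0]) ** 2 + (yy - c1[1]) ** 2 + (xx - c1[2]) ** 2)
        d2 = np.sqrt((zz - c2[0]) ** 2 + (yy - c2[1]) ** 2 + (xx - c2[2]) ** 2)
        # voxel-level nearest-centre oracle away from the midplane
        away = np.abs(d1 - d2) > 1.0
        lab1 = lv.labels[tuple(np.array(c1))]
        lab2 = lv.labels[tuple(np.array(c2))]
        sel = mask & away
        expect = np.where(d1 < d2, lab1, lab2)
        assert np.mean(lv.labels[sel] == expect[sel]) > 0.99

    def test_partition_of_mask(self):
        shape = (16, 16, 32)
        mask = _ball_mask(shape, (8, 8, 8), 5) | _ball_mask(shape, (8, 8, 24), 5)
        lv = label_nuclei(mask, SegmentationParams())
        assert np.array_equal(lv.labels > 0, mask)

    def test_empty_mask_warns(self):
        with pytest.warns(UserWarning):
            lv = label_nuclei(np.zeros((4, 4, 4), dtype=bool))
        assert lv.labels.max() == 0


class TestSegmentCells:
    def test_cells_partition_foreground_and_contain_nuclei(self, ground_truth):
        params = SegmentationParams()
        nm, mm = binarize_predictions(
            ground_truth.probability_maps["nucleus"],
            ground_truth.probability_maps["boundary"], params,
        )
        nm = split_nuclei(nm, mm)
        nuclei = label_nuclei(nm, params, ground_truth.cell_labels.voxel_size_um)
        cells, qc = segment_cells(nuclei, ground_truth.probability_maps["boundary"])
        assert set(cells.ids) == set(nuclei.ids)
        for lab in cells.ids:
            nuc_sel = nuclei.labels == lab
            inter = (cells.labels[nuc_sel] == lab).mean()
            assert inter > 0.99  # cell contains its nucleus

    def test_two_nuclei_cut_at_ridge(self):
        """A probability ridge between two seeds becomes the cell cut."""
        shape = (8, 16, 32)
        prob = np.zeros(shape)
        prob[:, :, 15:17] = 1.0  # ridge
        nuc = np.zeros(shape, dtype=np.int32)
        nuc[3:5, 6:10, 6:10] = 1
        nuc[3:5, 6:10, 22:26] = 2
        fg = np.ones(shape, dtype=bool)
        cells, _ = segment_cells(LabeledVolume(nuc, (1, 1, 1)), prob,
                                 min_object_voxels=0, foreground_mask=fg)
        # flood-fill oracle: left basin is label 1, right basin label 2
        assert (cells.labels[:, :, :15] == 1).all()
        assert (cells.labels[:, :, 17:] == 2).all()

    def test_small_objects_removed_and_logged(self):
        shape = (6, 6, 12)
        nuc = np.zeros(shape, dtype=np.int32)
        nuc[2:4, 2:4, 2:4] = 1
        nuc[3, 3, 9] = 2  # one-voxel nucleus -> tiny cell
        prob = np.ones(shape) * 0.5
        fg = np.zeros(shape, dtype=bool)
        fg[1:5, 1:5, 1:6] = True
        fg[3, 3, 9] = True
        cells, qc = segment_cells(LabeledVolume(nuc, (1, 1, 1)), prob,
                                  min_object_voxels=5, foreground_mask=fg)
        assert 2 not in cells.ids
        assert (qc["flag"] == "removed_small_object").sum() == 1


class TestResampleIsotropic:
    def test_paper_voxel_geometry(self):
        vol = np.zeros((10, 8, 8), dtype=np.int32)
        out = resample_isotropic(LabeledVolume(vol, (0.22, 0.05, 0.05)))
        assert out.voxel_size_um == (0.05, 0.05, 0.05)
        assert out.labels.shape[0] == round(10 * 0.22 / 0.05)

    def test_isotropic_input_unchanged(self):
        vol = np.random.default_rng(0).random((5, 5, 5))
        out, size = resample_isotropic(vol, (0.1, 0.1, 0.1), is_label=False)
        assert np.array_equal(out, vol)

    def test_sphere_volume_preserved(self):
        shape = (20, 40, 40)
        mask = _ball_mask(shape, (10, 20, 20), 8).astype(np.int32)
        # anisotropy 2x in z: the physical object is a 2:1 ellipsoid
        lv = LabeledVolume(mask, (0.4, 0.2, 0.2))
        out = resample_isotropic(lv)
        vol_in = mask.sum() * 0.4 * 0.2 * 0.2
        vol_out = (out.labels > 0).sum() * 0.2**3
        assert abs(vol_out - vol_in) / vol_in < 0.05


class TestMatchLabels:
    def test_identity_matching(self, ground_truth):
        m = match_labels(ground_truth.cell_labels, ground_truth.cell_labels)
        assert (m["iou"] == 1.0).all()
        assert (m["predicted"] == m["truth"]).all()
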