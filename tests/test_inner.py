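import numpy as np
import pytest

from breastseg.core import BinaryMask, ImageStack
from breastseg.inner import (
    FatSeparabilityError,
    InnerParams,
    combine_labels,
    difference_image,
    fat_mask,
    fg_mask,
    remove_skin,
    tumor_mask,
)

SPACING = (3.0, 1.2, 1.2)


def mask_of(vox, name="mask1"):
    return BinaryMask(np.asarray(vox, bool), SPACING, name)


class TestFatMask:
    def test_identical_pair_not_separable(self, rng):
        vol = rng.random((3, 8, 8)) * 100
        stack = ImageStack(vol, SPACING)
        m1 = mask_of(np.ones((3, 8, 8)))
        with pytest.raises(FatSeparabilityError):
            fat_mask(stack, stack, m1)

    def test_large_difference_outside_mask1_excluded(self):
        nofs = np.zeros((1, 4, 4))
        fs = np.zeros((1, 4, 4))
        nofs[0, 0, 0] = 1000.0          # fat-like voxel outside mask1
        nofs[0, 2, 2] = 900.0           # fat inside mask1
        nofs[0, 2, 3] = 10.0            # FG-ish inside mask1
        m1 = np.zeros((1, 4, 4), bool)
        m1[0, 2, 2:4] = True
        m2 = fat_mask(ImageStack(nofs, SPACING), ImageStack(fs, SPACING), mask_of(m1))
        assert not m2.voxels[0, 0, 0]
        assert m2.voxels[0, 2, 2]
        assert not m2.voxels[0, 2, 3]


class TestDifferenceImage:
    def test_worked_single_voxel_series(self):
        series = np.array([10, 10, 10, 10, 30, 32, 30, 28], dtype=float)
        dce = series.reshape(8, 1, 1, 1)
        di = difference_image(dce)
        # pre = 10, t* at the 32 frame, post = mean(30, 32, 30, 28) = 30
        assert di.voxels[0, 0, 0] == pytest.approx(2.0, abs=1e-12)

    def test_flat_series_gives_zero(self):
        dce = np.full((10, 2, 3, 3), 7.0)
        di = difference_image(dce)
        assert np.allclose(di.voxels, 0.0)

    def test_window_clamped_at_series_end(self):
        series = np.concatenate([np.full(4, 10.0), np.linspace(11, 40, 6)])
        dce = series.reshape(10, 1, 1, 1)
        di = difference_image(dce)
        # t* is the last frame; window = last four frames
        expected = (series[6:].mean() - 10.0) / 10.0
        assert di.voxels[0, 0, 0] == pytest.approx(expected, rel=1e-12)

    def test_scale_invariance(self, rng):
        dce = rng.random((12, 3, 6, 6)) * 50 + 5
        a = difference_image(dce).voxels
        b = difference_image(dce * 137.0).voxels
        assert np.allclose(a, b, atol=1e-12)


class TestTumorMask:
    def test_blob_thinner_than_disc_eliminated(self):
        di = np.zeros((1, 40, 40))
        di[0, 10:15, 10:15] = 3.0      # 5 px blob < disc diameter 9
        m1 = mask_of(np.ones((1, 40, 40)))
        m4 = tumor_mask(ImageStack(di, SPACING), m1)
        assert m4.count() == 0

    def test_wide_blob_survives_morphology(self):
        di = np.zeros((1, 80, 80))
        yy, xx = np.mgrid[:80, :80]
        blob = (yy - 40) ** 2 + (xx - 40) ** 2 <= 8**2  # ~3% of the breast
        di[0][blob] = 3.0
        m1 = mask_of(np.ones((1, 80, 80)))
        m4 = tumor_mask(ImageStack(di, SPACING), m1)
        assert 0.8 * blob.sum() <= m4.count() <= 1.1 * blob.sum()

    def test_degenerate_di_yields_empty_mask(self):
        di = ImageStack(np.zeros((1, 10, 10)), SPACING)
        m1 = mask_of(np.ones((1, 10, 10)))
        assert tumor_mask(di, m1).count() == 0


class TestFgMaskAlgebra:
    def test_toy_set_arithmetic(self):
        # |mask1| = 8, |mask2| = 5 (subset), |mask4| = 1 (inside mask3)
        m1 = np.zeros(9, bool)
        m1[:8] = True
        m2 = np.zeros(9, bool)
        m2[:5] = True
        m4 = np.zeros(9, bool)
        m4[5] = True
        shape = (1, 3, 3)
        m3, m5 = fg_mask(
            mask_of(m1.reshape(shape)), mask_of(m2.reshape(shape)),
            mask_of(m4.reshape(shape)),
        )
        assert m3.count() == 3
        assert m5.count() == 2

    def test_empty_tumor_means_mask5_equals_mask3(self, rng):
        m1 = mask_of(rng.random((2, 6, 6)) > 0.4)
        m2 = mask_of(m1.voxels & (rng.random((2, 6, 6)) > 0.5))
        m4 = mask_of(np.zeros((2, 6, 6)))
        m3, m5 = fg_mask(m1, m2, m4)
        assert np.array_equal(m3.voxels, m5.voxels)

    def test_pipeline_mask_partition_invariants(self, pipeline_result):
        r = pipeline_result
        assert np.array_equal(r.mask2.voxels | r.mask3.voxels, r.mask1.voxels)
        assert not (r.mask2.voxels & r.mask3.voxels).any()
        m4_in_3 = r.mask4.voxels & r.mask3.voxels
        assert np.array_equal(r.mask5.voxels | m4_in_3, r.mask3.voxels)
        assert not (r.mask5.voxels & m4_in_3).any()
        for m in (r.mask2, r.mask3, r.mask4, r.mask5):
            assert not (m.voxels & ~r.mask1.voxels).any()


class TestRemoveSkin:
    def test_disabled_flag_is_identity(self, rng):
        vol = ImageStack(rng.random((3, 10, 10)) * 100, SPACING)
        mask = mask_of(rng.random((3, 10, 10)) > 0.5)
        params = InnerParams(skin_removal_enabled=False)
        out = remove_skin(vol, mask, params)
        assert np.array_equal(out.voxels, mask.voxels)

    def test_phantom_shell_removed_interior_fat_kept(self):
        # the filter's own contract, judged on a motion-free phantom (the
        # pipeline-level criteria cover the registered case)
        from breastseg import outer, preprocess
        from breastseg.phantom import PhantomConfig, generate_phantom

        study, gt = generate_phantom(PhantomConfig(
            seed=7, rigid_shift_mm=(0, 0, 0), n_timepoints=8,
        ))
        stack = preprocess.remove_background(study.structural[("T2W", False)])
        rng_ = preprocess.select_relevant_slices(stack)
        lo, hi = rng_
        mask1, _ = outer.outer_segment(preprocess.crop_slices(stack, rng_))
        fs = preprocess.crop_slices(
            preprocess.remove_background(study.structural[("T2W", True)]), rng_
        )
        out = remove_skin(fs, mask1)
        removed = mask1.voxels & ~out.voxels
        skin = gt.skin.voxels[lo : hi + 1]
        fat = gt.fat.voxels[lo : hi + 1]
        shell_in_mask = skin & mask1.voxels
        assert (removed & shell_in_mask).sum() >= 0.9 * shell_in_mask.sum()
        # interior fat (away from the boundary band) essentially untouched
        from scipy import ndimage

        depth = ndimage.distance_transform_edt(mask1.voxels, sampling=SPACING)
        interior_fat = fat & mask1.voxels & (depth > 3.0)
        assert (removed & interior_fat).sum() < 0.02 * interior_fat.sum()

    def test_skinless_phantom_mask_nearly_unchanged(self):
        # no skin layer: no boundary-adjacent sheet structure to remove
        from breastseg import outer, preprocess
        from breastseg.phantom import PhantomConfig, generate_phantom

        study, _ = generate_phantom(PhantomConfig(
            seed=7, include_skin=False, rigid_shift_mm=(0, 0, 0), n_timepoints=8,
        ))
        stack = preprocess.remove_background(study.structural[("T2W", False)])
        rng_ = preprocess.select_relevant_slices(stack)
        mask1, _ = outer.outer_segment(preprocess.crop_slices(stack, rng_))
        fs = preprocess.crop_slices(
            preprocess.remove_background(study.structural[("T2W", True)]), rng_
        )
        out = remove_skin(fs, mask1)
        changed = (out.voxels != mask1.voxels).sum()
        assert changed < 0.01 * mask1.count()


class TestCombineLabels:
    def test_disjoint_masks_labelled(self):
        m2 = mask_of([[[1, 0, 0]]])
        m5 = mask_of([[[0, 1, 0]]])
        m4 = mask_of([[[0, 0, 1]]])
        labels = combine_labels(m2, m5, m4)
        assert labels.voxels.tolist() == [[[1, 2, 3]]]

    def test_tumor_precedence_over_fat(self):
        overlap = mask_of([[[1]]])
        labels = combine_labels(overlap, mask_of([[[0]]]), overlap)
        assert labels.voxels[0, 0, 0] == 3

    def test_phantom_label_volumes_close_to_truth(
        self, pipeline_result, cropped_truth
    ):
        from breastseg.core import voxel_volume

        labels = pipeline_result.labels.voxels
        vox_cm3 = voxel_volume(pipeline_result.mask1) / 1000.0
        for label, name in ((1, "fat"), (2, "fg")):
            vol = (labels == label).sum() * vox_cm3
            true = cropped_truth[name].count() * vox_cm3
            assert vol == pytest.approx(true, rel=0.10)
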