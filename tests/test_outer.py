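import numpy as np
import pytest

from breastseg.core import ImageStack
from breastseg.outer import (
    DegenerateHistogramError,
    NoLandmarksError,
    OuterParams,
    clean_lower_part,
    cut_below_spline,
    detect_lateral_landmarks,
    first_row_reaching_width,
    fractional_otsu,
    locate_corner_points,
    outer_segment,
    refine_midline,
    remove_pectoral,
)


def brute_force_otsu(values):
    """Independent oracle: exhaustive search over all inter-value splits for
    the threshold maximising between-class variance (lowest on ties)."""
    values = sorted(values)
    n = len(values)
    uniq = sorted(set(values))
    best_var, best_thr = -1.0, None
    for k in range(len(uniq) - 1):
        thr = (uniq[k] + uniq[k + 1]) / 2.0
        lo = [v for v in values if v <= thr]
        hi = [v for v in values if v > thr]
        w0 = len(lo) / n
        var = w0 * (1 - w0) * (np.mean(lo) - np.mean(hi)) ** 2
        if var > best_var + 1e-15:
            best_var, best_thr = var, thr
    return best_thr


class TestFractionalOtsu:
    def test_two_class_sample_split_exactly(self):
        values = np.array([1, 1, 1, 10, 10, 10], dtype=float)
        thr = fractional_otsu(values, 1.0)
        assert 1 < thr < 10
        assert (values <= thr).sum() == 3 and (values > thr).sum() == 3

    def test_fraction_scales_linearly(self, rng):
        values = rng.integers(0, 50, size=80).astype(float)
        assert fractional_otsu(values, 0.5) == pytest.approx(
            0.5 * fractional_otsu(values, 1.0)
        )

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateHistogramError):
            fractional_otsu(np.full(10, 7.0))

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 60))
            values = rng.integers(0, 30, size=n).astype(float)
            if len(set(values.tolist())) < 2:
                continue
            assert fractional_otsu(values) == pytest.approx(
                brute_force_otsu(values.tolist()), abs=1e-12
            )


class TestLateralLandmarks:
    def test_two_blob_toy_grid(self):
        grid = np.zeros((9, 9))
        grid[2:6, 1:4] = 1.0   # left blob rows 2-5, cols 1-3
        grid[2:6, 5:8] = 1.0   # right blob rows 2-5, cols 5-7
        grid[5, 4] = 1.0       # bridge at row 5, col 4
        p1, p2, p3 = detect_lateral_landmarks(grid)
        assert p1 == (2, 1)
        assert p2 == (2, 7)
        assert p3 == (5, 4)
        assert p1[1] < p3[1] < p2[1]

    def test_single_centred_blob_p3_at_top_row(self):
        grid = np.zeros((8, 9))
        grid[3:6, 2:7] = 1.0
        _, _, p3 = detect_lateral_landmarks(grid)
        assert p3[0] == 3

    def test_empty_slice_rejected(self):
        with pytest.raises(NoLandmarksError):
            detect_lateral_landmarks(np.zeros((5, 5)))


class TestCleanLowerPart:
    def test_upper_part_bit_identical(self, rng):
        slice2d = rng.random((20, 16)) * 100
        out = clean_lower_part(slice2d, (7, 8), OuterParams())
        assert np.array_equal(out[:8], slice2d[:8])

    def test_all_zero_lower_part_unchanged(self):
        slice2d = np.zeros((10, 10))
        slice2d[2, 2:8] = 50.0
        out = clean_lower_part(slice2d, (4, 5), OuterParams())
        assert np.array_equal(out, slice2d)

    def test_dim_blob_removed_bright_rim_kept(self):
        # lower part: dim organ blob (350) plus a thick bright fat rim (1000)
        slice2d = np.zeros((40, 40))
        slice2d[0, 20] = 900.0                 # P3 anchor in the upper part
        slice2d[10:18, :] = 1000.0             # bright rim, thicker than kernel 7
        slice2d[22:34, 10:30] = 350.0          # organ blob
        out = clean_lower_part(slice2d, (0, 20), OuterParams())
        assert out[22:34, 10:30].sum() == 0.0
        assert np.array_equal(out[10:18], slice2d[10:18])


class TestRefineMidline:
    def test_deepest_pixel_on_column(self):
        slice2d = np.zeros((12, 5))
        slice2d[5:10, 2] = 1.0
        assert refine_midline(slice2d, (5, 2)) == (9, 2)

    def test_only_p3_nonzero_returns_p3(self):
        slice2d = np.zeros((6, 5))
        slice2d[2, 3] = 1.0
        assert refine_midline(slice2d, (2, 3)) == (2, 3)


class TestCornerStoppingRule:
    def test_synthetic_width_profile(self):
        widths = np.array([4, 4, 4, 4, 7, 9])
        assert first_row_reaching_width(widths, t=4, factor=1.5) == 4  # w=7 >= 6

    def test_degenerate_factor_one_triggers_at_start(self):
        widths = np.array([4, 4, 5, 9])
        assert first_row_reaching_width(widths, t=4, factor=1.0, start=0) == 0

    def test_never_met_returns_none(self):
        assert first_row_reaching_width(np.array([4, 4, 4]), 4, 1.5) is None


class TestCornerPoints:
    def test_phantom_corners_at_breast_torso_junction(
        self, pipeline_result, cropped_truth
    ):
        truth = cropped_truth["truth"]
        lm = pipeline_result.landmarks
        assert abs(lm.P4[0] - truth.chest_row) <= 3
        assert abs(lm.P5[0] - truth.chest_row) <= 3
        assert lm.t > 0


class TestCutBelowSpline:
    def test_collinear_points_horizontal_cut(self):
        img = np.ones((20, 12))
        out = cut_below_spline(img, (10, 2), (10, 6), (10, 10))
        assert out[11:, 2:11].sum() == 0.0
        assert out[10, 2:11].sum() == 9.0

    def test_sagging_curve_keeps_corners_cuts_below_midline(self):
        img = np.ones((20, 12))
        out = cut_below_spline(img, (8, 2), (12, 6), (8, 10))
        assert out[13, 6] == 0.0   # just below P3'
        assert out[8, 2] == 1.0    # P4 itself kept
        assert out[9:, :2].sum() == 0.0   # below horizontal line left of P4

    def test_ordering_violation_rejected(self):
        with pytest.raises(ValueError):
            cut_below_spline(np.ones((5, 8)), (1, 5), (2, 3), (1, 6))


class TestRemovePectoral:
    def test_pectoral_band_removed_under_bright_fat(self):
        slice2d = np.zeros((30, 20))
        slice2d[0:10, :] = 1000.0      # fat above the P3/P3' midpoint
        slice2d[12:22, :] = 1000.0     # fat below it
        slice2d[16:20, 2:18] = 380.0   # pectoral band inside the lower fat
        out = remove_pectoral(slice2d, (8, 10), (14, 10), OuterParams())
        pect = out[16:20, 2:18]
        assert (pect == 0).mean() >= 0.95

    def test_rows_above_midpoint_untouched(self, rng):
        slice2d = rng.random((30, 20)) * 100
        out = remove_pectoral(slice2d, (8, 10), (14, 10), OuterParams())
        assert np.array_equal(out[:12], slice2d[:12])

    def test_constant_fat_region_unchanged(self):
        slice2d = np.zeros((20, 15))
        slice2d[12:18, 2:12] = 1000.0
        out = remove_pectoral(slice2d, (6, 7), (10, 7), OuterParams())
        assert np.array_equal(out, slice2d)

    def test_hard_limit_cuts_deep_rows(self):
        slice2d = np.full((40, 10), 1000.0)
        params = OuterParams(pectoral_hard_limit_mm=6.0)
        out = remove_pectoral(slice2d, (2, 5), (4, 5), params, spacing_row_mm=1.2)
        assert out[10:].sum() == 0.0   # beyond P3'.row + 5 px


class TestOuterSegment:
    def test_mask1_is_subset_of_foreground(self, default_phantom, pipeline_result):
        study, _ = default_phantom
        from breastseg.preprocess import crop_slices, remove_background

        bg = remove_background(study.structural[("T2W", False)])
        bg = crop_slices(bg, pipeline_result.slice_range)
        assert not (pipeline_result.mask1_raw.voxels & ~(bg.voxels > 0)).any()

    def test_landmark_invariants_hold_per_slice(self, pipeline_result):
        pipeline_result.landmarks.validate()
        for lm in pipeline_result.landmarks.per_slice.values():
            assert lm.P1[1] < lm.P3[1] < lm.P2[1]
            assert lm.P3_prime[0] >= lm.P3[0]

    def test_deterministic(self, default_phantom):
        from breastseg.preprocess import crop_slices, remove_background, select_relevant_slices

        study, _ = default_phantom
        bg = remove_background(study.structural[("T2W", False)])
        bg = crop_slices(bg, select_relevant_slices(bg))
        m1, _ = outer_segment(bg)
        m2, _ = outer_segment(bg)
        assert np.array_equal(m1.voxels, m2.voxels)

    def test_empty_stack_fails_in_preprocessing(self):
        from breastseg.preprocess import EmptyStackError, remove_background

        with pytest.raises(EmptyStackError):
            remove_background(ImageStack(np.zeros((4, 8, 8)), (3, 1.2, 1.2)))
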