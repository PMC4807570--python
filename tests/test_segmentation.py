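import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import brute_segment, flood_fill_components
from kescan.phantom import PhantomSpec, build_root_phantom
from kescan.registration import estimate_transform, resample
from kescan.segmentation import (
    BinaryMask,
    SegmentationParams,
    dice,
    dilate26,
    label_regions,
    segment_yttria,
    shift_artifact_mask,
    threshold_mask,
)
from kescan.subtraction import SubtractionVolume, subtract


class TestSegmentationParams:
    def test_defaults_match_protocol(self):
        p = SegmentationParams()
        assert p.threshold_A == 3.8
        assert p.threshold_B == 12.0
        assert p.threshold_C == 3.0
        assert p.threshold_D_cutoff == 0.0
        assert p.threshold_E == (3.0, 4.0)

    def test_b_must_exceed_a(self):
        with pytest.raises(ValueError):
            SegmentationParams(threshold_A=5.0, threshold_B=4.0)

    def test_invalid_e_interval_rejected(self):
        with pytest.raises(ValueError):
            SegmentationParams(threshold_E=(4.0, 3.0))


class TestThresholdMask:
    def test_all_zero_volume_gives_empty_mask(self):
        mask = threshold_mask(np.zeros((4, 4, 4)), 3.8)
        assert mask.voxel_count == 0

    def test_boundary_value_included(self):
        vol = np.full((1, 1, 1), 3.8)
        assert threshold_mask(vol, 3.8).voxel_count == 1

    def test_interval_selection(self):
        vol = np.array([[[2.5, 3.5, 4.5]]])
        mask = threshold_mask(vol, 3.0, 4.0)
        np.testing.assert_array_equal(mask.data, [[[False, True, False]]])

    def test_interval_bounds_inclusive(self):
        vol = np.array([[[3.0, 4.0]]])
        assert threshold_mask(vol, 3.0, 4.0).voxel_count == 2

    def test_lower_above_upper_rejected(self):
        with pytest.raises(ValueError):
            threshold_mask(np.zeros((1, 1, 1)), 4.0, 3.0)

    def test_output_is_strictly_binary(self, rng):
        mask = threshold_mask(rng.uniform(0, 10, (4, 4, 4)), 5.0)
        assert mask.data.dtype == bool


class TestDilate26:
    def test_single_interior_voxel_becomes_27_cube(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        out = dilate26(BinaryMask(mask))
        assert out.voxel_count == 27
        assert out.data[1:4, 1:4, 1:4].all()

    def test_empty_mask_stays_empty(self):
        out = dilate26(BinaryMask(np.zeros((4, 4, 4), dtype=bool)))
        assert out.voxel_count == 0

    def test_corner_voxel_clipped_to_8(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[0, 0, 0] = True
        assert dilate26(BinaryMask(mask)).voxel_count == 8

    def test_zero_iterations_is_identity(self, rng):
        mask = BinaryMask(rng.random((4, 6, 6)) > 0.5)
        np.testing.assert_array_equal(dilate26(mask, 0).data, mask.data)

    def test_matches_brute_force_on_random_masks(self, rng):
        from _oracles import brute_dilate26

        for _ in range(5):
            mask = rng.random((6, 6, 6)) > 0.7
            np.testing.assert_array_equal(
                dilate26(BinaryMask(mask)).data, brute_dilate26(mask)
            )

    def test_negative_iterations_rejected(self):
        with pytest.raises(ValueError):
            dilate26(BinaryMask(np.zeros((2, 2, 2), dtype=bool)), -1)


class TestShiftArtifactMask:
    def test_all_positive_subtraction_gives_empty_mask(self):
        sub = SubtractionVolume(np.full((4, 4, 4), 1.0))
        assert shift_artifact_mask(sub).voxel_count == 0

    def test_single_negative_voxel_gives_27_cube(self):
        data = np.full((5, 5, 5), 1.0)
        data[2, 2, 2] = -0.5
        assert shift_artifact_mask(SubtractionVolume(data)).voxel_count == 27

    def test_shifted_mineral_rim_is_covered(self):
        spec = PhantomSpec(
            shape=(12, 64, 64),
            n_yttria_junction=0,
            n_yttria_epidermis=0,
            shrinkage_shift=(0.0, 0.0, 1.0),
            seed=17,
        )
        below, above, truth = build_root_phantom(spec)
        sub = subtract(above, below)
        D = shift_artifact_mask(sub)
        bright_rim = sub.data >= 3.0
        assert bright_rim.any()
        assert (bright_rim & ~D.data).sum() == 0


class TestSegmentYttria:
    def test_noise_free_phantom_recovers_truth(self, small_phantom):
        below, above, truth = small_phantom
        sub = subtract(above, below)
        mask = segment_yttria(above, below, sub)
        assert dice(mask, truth.yttria_mask) >= 0.90

    def test_shifted_mineral_only_phantom_yields_empty_mask(self):
        spec = PhantomSpec(
            shape=(12, 64, 64),
            n_yttria_junction=0,
            n_yttria_epidermis=0,
            shrinkage_shift=(0.0, 0.0, 1.0),
            seed=23,
        )
        below, above, _ = build_root_phantom(spec)
        mask = segment_yttria(above, below, subtract(above, below))
        assert mask.voxel_count == 0

    def test_all_air_volumes_yield_empty_mask(self):
        zeros = np.zeros((4, 8, 8), dtype=np.float32)
        mask = segment_yttria(zeros, zeros, subtract(zeros, zeros))
        assert mask.voxel_count == 0

    def test_matches_brute_force_oracle_on_random_volumes(self, rng):
        for _ in range(50):
            above = rng.uniform(0, 15, (8, 8, 8)).astype(np.float32)
            below = rng.uniform(0, 15, (8, 8, 8)).astype(np.float32)
            sub = subtract(above, below)
            ours = segment_yttria(above, below, sub)
            oracle = brute_segment(above, below, sub.data)
            np.testing.assert_array_equal(ours.data, oracle)

    @pytest.mark.parametrize("h_rule", ["table2", "text"])
    @pytest.mark.parametrize("use_e", [False, True])
    def test_option_variants_match_oracle(self, rng, h_rule, use_e):
        params = SegmentationParams(h_rule=h_rule, use_threshold_E=use_e)
        for _ in range(10):
            above = rng.uniform(0, 15, (8, 8, 8)).astype(np.float32)
            below = rng.uniform(0, 15, (8, 8, 8)).astype(np.float32)
            sub = subtract(above, below)
            ours = segment_yttria(above, below, sub, params)
            oracle = brute_segment(
                above, below, sub.data, h_rule=h_rule, use_threshold_E=use_e
            )
            np.testing.assert_array_equal(ours.data, oracle)

    def test_every_stage_is_strictly_binary(self, small_phantom):
        below, above, truth = small_phantom
        sub = subtract(above, below)
        _, stages = segment_yttria(above, below, sub, full_output=True)
        assert set(stages) == set("ABCDE") | set("fghi")
        for mask in stages.values():
            assert mask.data.dtype == bool

    def test_final_mask_subset_of_c(self, small_phantom):
        below, above, truth = small_phantom
        sub = subtract(above, below)
        final, stages = segment_yttria(above, below, sub, full_output=True)
        assert not (final.data & ~stages["C"].data).any()

    def test_raising_threshold_c_never_grows_final_mask(self, small_phantom):
        below, above, truth = small_phantom
        sub = subtract(above, below)
        sizes = []
        for tC in (2.0, 3.0, 4.0, 6.0):
            mask = segment_yttria(
                above, below, sub, SegmentationParams(threshold_C=tC)
            )
            sizes.append(mask.voxel_count)
        assert all(b <= a for a, b in zip(sizes, sizes[1:]))

    def test_more_dilation_never_shrinks_g(self, small_phantom):
        below, above, truth = small_phantom
        sub = subtract(above, below)
        previous = None
        for it in (0, 1, 2):
            _, stages = segment_yttria(
                above,
                below,
                sub,
                SegmentationParams(dilation_iterations=it),
                full_output=True,
            )
            g = stages["g"].data
            if previous is not None:
                assert not (previous & ~g).any()
            previous = g

    def test_shape_mismatch_rejected(self):
        a = np.zeros((2, 4, 4))
        b = np.zeros((2, 4, 5))
        with pytest.raises(ValueError):
            segment_yttria(a, b, SubtractionVolume(np.zeros((2, 4, 4))))

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_oracle_equivalence_property(self, seed):
        rng = np.random.default_rng(seed)
        above = rng.uniform(0, 16, (6, 6, 6)).astype(np.float32)
        below = rng.uniform(0, 16, (6, 6, 6)).astype(np.float32)
        sub = subtract(above, below)
        np.testing.assert_array_equal(
            segment_yttria(above, below, sub).data,
            brute_segment(above, below, sub.data),
        )


class TestLabelRegions:
    def test_empty_mask_gives_empty_list(self):
        result = label_regions(BinaryMask(np.zeros((4, 4, 4), dtype=bool)))
        assert result.regions == ()

    def test_two_separated_cubes(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[1:4, 1:4, 1:4] = True
        mask[6:9, 6:9, 6:9] = True
        result = label_regions(BinaryMask(mask))
        assert sorted(r.voxel_count for r in result.regions) == [27, 27]

    def test_total_labelled_voxels_equals_mask_sum(self, rng):
        mask = rng.random((12, 12, 12)) > 0.6
        result = label_regions(BinaryMask(mask))
        assert sum(r.voxel_count for r in result.regions) == int(mask.sum())

    def test_counts_match_flood_fill_oracle(self, rng):
        mask = rng.random((20, 20, 20)) > 0.7
        result = label_regions(BinaryMask(mask))
        assert sorted(r.voxel_count for r in result.regions) == flood_fill_components(mask)

    def test_bounding_boxes_contain_their_regions(self):
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[2:5, 1:3, 0:2] = True
        result = label_regions(BinaryMask(mask))
        assert result.regions[0].bounding_box == ((2, 5), (1, 3), (0, 2))


class TestDice:
    def test_identical_masks_give_one(self, rng):
        m = rng.random((4, 4, 4)) > 0.5
        assert dice(m, m) == 1.0

    def test_disjoint_masks_give_zero(self):
        a = np.zeros((2, 2, 2), dtype=bool)
        b = np.zeros((2, 2, 2), dtype=bool)
        a[0, 0, 0] = True
        b[1, 1, 1] = True
        assert dice(a, b) == 0.0

    def test_empty_vs_empty_is_one(self):
        empty = np.zeros((2, 2, 2), dtype=bool)
        assert dice(empty, empty) == 1.0
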