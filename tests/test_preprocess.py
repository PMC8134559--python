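"""Image preparation chain: background, mask, crop/resize, packing, scaling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pdprobe.preprocess import (
    apply_mask,
    crop_square_resize,
    downsample_labels,
    downsample_mask,
    generate_mask,
    pack_cells,
    preprocess_image,
    rescale_to_254,
    subtract_background,
    unpack_cells,
)


class TestSubtractBackground:
    def test_fixed_value_cancels_a_uniform_image(self):
        out = subtract_background(np.full((8, 8), 40.0), "fixed-value", 40.0)
        assert np.all(out == 0.0)

    def test_two_level_image_with_low_percentile(self):
        img = np.full((20, 20), 10.0)
        img[5:10, 5:10] = 200.0
        out = subtract_background(img, "low-percentile", 5.0)
        assert set(np.unique(out)) == {0.0, 190.0}

    def test_clean_input_is_unchanged(self):
        img = np.zeros((10, 10))
        img[2, 2] = 99.0
        assert np.array_equal(subtract_background(img, "low-percentile", 1.0), img)

    @pytest.mark.parametrize("estimator,value", [
        ("low-percentile", 0.0),
        ("low-percentile", 60.0),
        ("fixed-value", -1.0),
        ("median", 1.0),
    ])
    def test_invalid_parameters(self, estimator, value):
        with pytest.raises(ValueError):
            subtract_background(np.ones((4, 4)), estimator, value)


class TestGenerateMask:
    def test_opening_removes_small_islands(self):
        img = np.zeros((400, 400))
        img[100:300, 100:300] = 200.0  # principal blob
        islands = np.zeros((400, 400), dtype=bool)
        for r, c in [(20, 20), (20, 380), (380, 40)]:
            img[r : r + 3, c : c + 3] = 200.0  # 3x3 islands
            islands[r : r + 3, c : c + 3] = True
        mask = generate_mask(img, struct_radius=5)
        blob = np.zeros((400, 400), dtype=bool)
        blob[100:300, 100:300] = True
        assert not (mask & islands).any()          # islands vanish
        assert (mask <= blob).all()                # nothing outside the blob
        assert mask[105:295, 105:295].all()        # interior intact
        # only the disk-rounded corners of the blob may be shaved off
        assert (blob & ~mask).sum() < 4 * 25

    def test_all_dark_image_raises(self):
        with pytest.raises(ValueError, match="constant image"):
            generate_mask(np.zeros((50, 50)))

    def test_phantom_ground_truth_is_recovered_exactly(self, clean_bundle):
        mask = generate_mask(subtract_background(clean_bundle.image))
        assert np.array_equal(mask, clean_bundle.mask)

    def test_fixed_threshold_mode(self):
        img = np.zeros((100, 100))
        img[30:70, 30:70] = 50.0
        mask = generate_mask(img, threshold="fixed", threshold_value=25.0,
                             struct_radius=3)
        square = np.zeros((100, 100), dtype=bool)
        square[30:70, 30:70] = True
        assert (mask <= square).all()
        assert mask[33:67, 33:67].all()  # corners may round, interior intact


class TestApplyMask:
    def test_full_mask_is_identity(self, rng):
        img = rng.uniform(0, 100, (30, 30))
        assert np.array_equal(apply_mask(img, np.ones((30, 30), bool)), img)

    def test_everything_outside_the_mask_is_zero(self, rng):
        img = rng.uniform(1, 100, (30, 30))
        mask = np.zeros((30, 30), bool)
        mask[5:12, 5:12] = True
        out = apply_mask(img, mask)
        assert out[~mask].sum() == 0.0
        assert np.array_equal(out[mask], img[mask])

    def test_masking_is_idempotent(self, rng):
        img = rng.uniform(0, 100, (30, 30))
        mask = img > 50
        once = apply_mask(img, mask)
        assert np.array_equal(apply_mask(once, mask), once)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            apply_mask(np.ones((4, 4)), np.ones((5, 5), bool))


class TestCropSquareResize:
    def test_output_is_always_598(self, clean_bundle):
        res = crop_square_resize(clean_bundle.image, clean_bundle.mask, 0.1)
        assert res.image.shape == (598, 598)
        assert res.mask.shape == (598, 598)

    def test_centered_square_hand_is_a_pure_resize(self, rng):
        img = rng.uniform(10, 100, (598, 598))
        mask = np.ones((598, 598), bool)
        res = crop_square_resize(img, mask, 0.0)
        assert res.window == (0, 0, 598)
        np.testing.assert_allclose(res.image, img, atol=1e-9)

    def test_resized_mask_corners_map_back_within_one_source_pixel(self, clean_bundle):
        res = crop_square_resize(clean_bundle.image, clean_bundle.mask, 0.0)
        rows = np.flatnonzero(res.mask.any(axis=1))
        cols = np.flatnonzero(res.mask.any(axis=0))
        src_rows = np.flatnonzero(clean_bundle.mask.any(axis=1))
        src_cols = np.flatnonzero(clean_bundle.mask.any(axis=0))
        for out_rc, src_rc in [
            ((rows[0], cols[0]), (src_rows[0], src_cols[0])),
            ((rows[-1], cols[-1]), (src_rows[-1], src_cols[-1])),
        ]:
            back = res.to_source(out_rc)
            assert abs(back[0] - src_rc[0]) <= 1.0
            assert abs(back[1] - src_rc[1]) <= 1.0

    def test_mask_area_fraction_is_conserved(self, clean_bundle):
        res = crop_square_resize(clean_bundle.image, clean_bundle.mask, 0.0)
        side = res.window[2]
        before = clean_bundle.mask.sum() / side**2
        after = res.mask.mean()
        assert abs(after - before) / before < 0.05

    def test_labels_ride_through_with_nearest_neighbour(self, clean_bundle):
        res = crop_square_resize(
            clean_bundle.image, clean_bundle.mask, 0.0, labels=clean_bundle.labels
        )
        assert res.labels.shape == (598, 598)
        assert set(np.unique(res.labels)) <= set(np.unique(clean_bundle.labels))

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty mask"):
            crop_square_resize(np.ones((20, 20)), np.zeros((20, 20), bool))


class TestPackCells:
    def test_uniform_image_packs_to_uniform_channels(self):
        packed = pack_cells(np.full((598, 598), 7.0))
        assert np.all(packed == 7.0)

    def test_single_cell_layout(self):
        img = np.zeros((598, 598))
        img[0:2, 0:2] = [[10, 20], [30, 40]]
        packed = pack_cells(img)
        assert tuple(packed[0, 0]) == (30.0, 40.0, 15.0)

    def test_checkerboard_top_row_mean_is_half(self):
        img = np.indices((598, 598)).sum(axis=0) % 2 * 100.0
        packed = pack_cells(img)
        assert np.all(packed[:, :, 2] == 50.0)

    @given(st.integers(0, 2**31 - 1))
    def test_packing_preserves_bottom_rows_and_top_means_exactly(self, seed):
        img = np.random.default_rng(seed).integers(0, 4096, (598, 598)).astype(float)
        packed = pack_cells(img)
        assert np.array_equal(packed[:, :, 0], img[1::2, 0::2])
        assert np.array_equal(packed[:, :, 1], img[1::2, 1::2])
        assert np.array_equal(packed[:, :, 2], (img[0::2, 0::2] + img[0::2, 1::2]) / 2)
        restored = unpack_cells(packed)
        assert np.array_equal(restored[1::2, :], img[1::2, :])
        assert np.array_equal(restored[0::2, 0::2], packed[:, :, 2])

    def test_wrong_dimensions_raise(self):
        with pytest.raises(ValueError, match="expected"):
            pack_cells(np.zeros((100, 100)))


class TestRescaleTo254:
    def test_range_0_254_is_identity(self, rng):
        x = rng.integers(0, 255, (299, 299, 3)).astype(float)
        x.flat[0], x.flat[1] = 0.0, 254.0
        assert np.array_equal(rescale_to_254(x), x.astype(np.uint8))

    def test_two_point_map(self):
        x = np.zeros((299, 299, 3))
        x[0, 0, 0] = 1.0
        out = rescale_to_254(x)
        assert out[0, 0, 0] == 254 and out[1, 1, 1] == 0

    @given(st.integers(0, 2**31 - 1))
    def test_extremes_hit_0_and_254(self, seed):
        x = np.random.default_rng(seed).uniform(-50, 900, (20, 20, 3))
        out = rescale_to_254(x)
        assert out.dtype == np.uint8
        assert out.min() == 0 and out.max() == 254

    def test_constant_input_raises(self):
        with pytest.raises(ValueError, match="constant"):
            rescale_to_254(np.full((4, 4, 3), 9.0))


class TestGridReduction:
    def test_majority_vote_with_ties_inside(self):
        m = np.zeros((598, 598), bool)
        m[0, 0] = True                      # 1 of 4 -> outside
        m[0, 2] = m[1, 2] = True            # 2 of 4 (tie) -> inside
        m[0:2, 4:6] = True                  # 4 of 4 -> inside
        small = downsample_mask(m)
        assert not small[0, 0] and small[0, 1] and small[0, 2]

    def test_label_reduction_needs_a_two_pixel_majority(self):
        lab = np.zeros((598, 598), np.int64)
        lab[0, 0] = 3                       # single pixel -> unassigned
        lab[0, 2] = lab[1, 2] = 2           # two pixels -> label 2
        lab[0, 4], lab[1, 4] = 1, 1         # ties between labels -> smaller
        lab[0, 5], lab[1, 5] = 4, 4
        small = downsample_labels(lab)
        assert small[0, 0] == 0 and small[0, 1] == 2 and small[0, 2] == 1


def test_full_chain_is_deterministic(clean_bundle):
    a = preprocess_image(clean_bundle.image, labels=clean_bundle.labels)
    b = preprocess_image(clean_bundle.image, labels=clean_bundle.labels)
    assert np.array_equal(a.packed, b.packed)
    assert np.array_equal(a.mask299, b.mask299)
    assert np.array_equal(a.labels299, b.labels299)
    assert a.packed.dtype == np.uint8
    assert a.packed.min() == 0 and a.packed.max() == 254


def test_user_supplied_mask_bypasses_generation(clean_bundle):
    res = preprocess_image(clean_bundle.image, mask=clean_bundle.mask)
    auto = preprocess_image(clean_bundle.image)
    assert np.array_equal(res.packed, auto.packed)
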