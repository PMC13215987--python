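import numpy as np
import pytest

from slicefat.anatomy import (
    DelineationWarning,
    apply_abdominal_mask,
    build_abdominal_mask,
    delineate_vat_sat,
    image_center,
    label_regions,
    region_props,
)
from slicefat.phantom import PhantomSpec, generate_slice_phantom


def props_bruteforce(labeled, center):
    """Per-pixel accumulation oracle for area/centroid/distance."""
    out = {}
    for lab in np.unique(labeled):
        if lab == 0:
            continue
        pix = np.argwhere(labeled == lab).astype(float)
        c = pix.mean(axis=0)
        out[int(lab)] = (
            len(pix),
            tuple(c),
            float(np.hypot(c[0] - center[0], c[1] - center[1])),
        )
    return out


class TestLabeling:
    def test_diagonal_pixels_are_one_region(self):
        mask = np.zeros((3, 3), dtype=np.uint8)
        mask[0, 0] = mask[1, 1] = 1
        assert label_regions(mask).max() == 1

    def test_separated_blocks_are_two_regions(self):
        mask = np.zeros((6, 6), dtype=np.uint8)
        mask[0:2, 0:2] = 1
        mask[4:6, 4:6] = 0
        mask[0:2, 4:6] = 1
        assert label_regions(mask).max() == 2

    def test_empty_mask_has_no_regions(self):
        assert label_regions(np.zeros((4, 4), dtype=np.uint8)).max() == 0


class TestRegionProps:
    def test_square_block_centroid(self):
        mask = np.zeros((4, 4), dtype=np.uint8)
        mask[0:2, 0:2] = 1
        props = region_props(label_regions(mask))
        assert props[0].area_px == 4
        assert props[0].centroid == (0.5, 0.5)

    def test_three_four_five_distance(self):
        mask = np.zeros((8, 8), dtype=np.uint8)
        mask[3, 4] = 1
        props = region_props(label_regions(mask), center=(0.0, 0.0))
        assert props[0].centroid_center_distance_px == pytest.approx(5.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_per_pixel_accumulation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = (rng.random((16, 16)) > 0.6).astype(np.uint8)
        labeled = label_regions(mask)
        center = image_center(mask.shape)
        expected = props_bruteforce(labeled, center)
        got = region_props(labeled, center)
        assert len(got) == len(expected)
        areas = sorted(p.area_px for p in got)
        assert areas == sorted(v[0] for v in expected.values())
        for p in got:
            area, centroid, dist = expected[p.label]
            assert p.area_px == area
            np.testing.assert_allclose(p.centroid, centroid)
            assert p.centroid_center_distance_px == pytest.approx(dist)

    def test_sorted_by_area_descending(self, rng):
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask[0:3, 0:3] = 1
        mask[8, 8] = 1
        props = region_props(label_regions(mask))
        assert props[0].area_px >= props[1].area_px


class TestAbdominalMask:
    def test_all_ones_mask_is_identity(self, rng):
        mask = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        np.testing.assert_array_equal(
            apply_abdominal_mask(mask, np.ones_like(mask)), mask
        )

    def test_all_zeros_mask_empties(self, rng):
        mask = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        assert apply_abdominal_mask(mask, np.zeros_like(mask)).sum() == 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            apply_abdominal_mask(np.ones((3, 3)), np.ones((4, 4)))

    def test_phantom_arm_fat_removed_sat_vat_kept(self, noiseless_phantom):
        img, masks, arms, abdominal = noiseless_phantom
        fat = ((img > 0.5) & True).astype(np.uint8)
        cleaned = apply_abdominal_mask(fat, abdominal)
        assert not np.any(cleaned & arms)
        assert np.all(cleaned[masks.tat > 0] == 1)

    def test_built_mask_covers_compartments_without_arms(self):
        img, masks, _, _ = generate_slice_phantom(
            PhantomSpec(noise_sd=0.0, include_arms=False, seed=4)
        )
        built = build_abdominal_mask(img)
        assert not np.any(masks.tat & ~built)

    def test_built_mask_excludes_arms(self, noiseless_phantom):
        img, masks, arms, _ = noiseless_phantom
        built = build_abdominal_mask(img)
        assert np.sum(built & arms) == 0
        assert not np.any(masks.tat & ~built)

    def test_blank_image_raises_helpful_error(self):
        with pytest.raises(ValueError):
            build_abdominal_mask(np.zeros((10, 10)))


class TestDelineation:
    def test_far_region_is_sat_others_vat(self):
        mask = np.zeros((21, 21), dtype=np.uint8)
        center = (10.0, 10.0)
        mask[10, 20] = 1  # distance 10 -> SAT
        mask[10, 12] = 1  # distance 2 -> VAT
        mask[12, 10] = 1  # third tiny region -> VAT
        comps = delineate_vat_sat(mask, center)
        assert comps.sat[10, 20] == 1 and comps.sat.sum() == 1
        assert comps.vat[10, 12] == 1 and comps.vat[12, 10] == 1

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            delineate_vat_sat(np.zeros((5, 5), dtype=np.uint8))

    def test_single_region_becomes_sat_with_warning(self):
        mask = np.zeros((9, 9), dtype=np.uint8)
        mask[2:4, 2:4] = 1
        with pytest.warns(DelineationWarning, match="one adipose region"):
            comps = delineate_vat_sat(mask)
        assert comps.sat.sum() == 4 and comps.vat.sum() == 0

    def test_distance_tie_broken_by_area_with_warning(self):
        # regions at equal centroid distance 5 from (5,5): areas 3 vs 1
        mask = np.zeros((11, 11), dtype=np.uint8)
        mask[0, 5] = 1  # centroid (0,5), distance 5, area 1
        mask[10, 4:7] = 1  # centroid (10,5), distance 5, area 3
        with pytest.warns(DelineationWarning, match="tie"):
            comps = delineate_vat_sat(mask, (5.0, 5.0))
        assert comps.sat.sum() == 3 and comps.sat[10, 5] == 1
        assert comps.vat.sum() == 1 and comps.vat[0, 5] == 1

    def test_phantom_ground_truth_recovered(self, noiseless_phantom):
        _, masks, _, _ = noiseless_phantom
        comps = delineate_vat_sat(masks.tat)
        np.testing.assert_array_equal(comps.sat, masks.sat)
        np.testing.assert_array_equal(comps.vat, masks.vat)

    def test_pixel_conservation(self, rng):
        mask = (rng.random((20, 20)) > 0.7).astype(np.uint8)
        if mask.sum() == 0:
            mask[3, 3] = 1
        comps = delineate_vat_sat(mask)
        np.testing.assert_array_equal((comps.sat | comps.vat), mask)
        assert not np.any(comps.sat & comps.vat)

    @pytest.mark.parametrize("seed", range(40))
    def test_randomized_phantoms_assign_ring_to_sat(self, seed):
        # property: asymmetric phantoms with modest noise keep the ring SAT
        _, masks, _, _ = generate_slice_phantom(
            PhantomSpec(noise_sd=0.05, seed=1000 + seed)
        )
        comps = delineate_vat_sat(masks.tat)
        np.testing.assert_array_equal(comps.sat, masks.sat)
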