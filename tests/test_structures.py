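"""Retinal structure localisation: optic disc, vessels, macula, fovea."""

import math

import numpy as np
import pytest

from fundus_screen.preprocess import complement, enhance
from fundus_screen.structures import (
    VesselParams,
    crop_circular_roi,
    detect_optic_disc,
    locate_macula_geometric,
    locate_macula_image_centre,
    locate_macula_morphological,
    remove_vessels,
    segment_vessels,
)
from fundus_screen.types import Circle, MaculaOutOfFrameError, NoDiscFoundError, OpticDisc
from fundus_screen.synthetic import SyntheticSpec, generate


def _disc_image(h, w, bg, discs):
    """Flat background with anti-aliased discs: (row, col, radius, value)."""
    img = np.full((h, w), float(bg))
    rr, cc = np.mgrid[0:h, 0:w]
    for r, c, rad, val in discs:
        d = np.hypot(rr - r, cc - c)
        profile = np.clip((rad + 1.0 - d) / 2.0, 0.0, 1.0)
        img = img + (val - img) * profile
    return np.clip(img, 0, 255).astype(np.uint8)


class TestOpticDisc:
    def test_planted_disc_recovered(self, clean_image_and_truth):
        img, truth = clean_image_and_truth
        od = detect_optic_disc(enhance(img.rgb[:, :, 1], mask=img.fov_mask))
        assert math.hypot(od.row - truth.od.row, od.col - truth.od.col) <= 3.0
        assert abs(od.radius - truth.od.radius) <= 0.1 * truth.od.radius
        assert od.dd == 2 * od.radius

    def test_blank_image_raises(self):
        with pytest.raises(NoDiscFoundError):
            detect_optic_disc(np.zeros((300, 400), np.uint8))

    def test_bright_disc_preferred_over_dark(self):
        img = _disc_image(600, 900, 95, [(150, 200, 40, 200), (420, 620, 40, 25)])
        od = detect_optic_disc(img)
        assert math.hypot(od.row - 150, od.col - 200) <= 3.0

    def test_invalid_radius_order_rejected(self):
        with pytest.raises(ValueError):
            detect_optic_disc(np.zeros((50, 50), np.uint8), rmin_frac=0.2, rmax_frac=0.1)


class TestVessels:
    def test_blank_image_gives_empty_mask(self):
        assert not segment_vessels(np.full((60, 80), 120, np.uint8)).any()

    def test_planted_tree_overlaps_truth(self, clean_image_and_truth):
        img, truth = clean_image_and_truth
        comp = enhance(complement(img.rgb[:, :, 1]), mask=img.fov_mask)
        mask = segment_vessels(comp) & img.fov_mask
        inter = np.sum(mask & truth.vessels)
        dice = 2 * inter / (mask.sum() + truth.vessels.sum())
        assert dice >= 0.6

    def test_small_speck_removed_by_area_rule(self):
        img = np.full((80, 80), 100, np.uint8)
        img[40, 40:43] = 200  # 3-px bright speck
        mask = segment_vessels(img, VesselParams(min_object=30))
        assert not mask.any()

    def test_otsu_invariant_to_constant_offset(self, clean_image_and_truth):
        img, _ = clean_image_and_truth
        base = (img.rgb[:, :, 1] // 2 + 40).astype(np.uint8)  # headroom for +20
        m1 = segment_vessels(base)
        m2 = segment_vessels((base + 20).astype(np.uint8))
        assert np.array_equal(m1, m2)


class TestRemoveVessels:
    def test_empty_mask_is_identity(self, smooth_image):
        out = remove_vessels(smooth_image, np.zeros_like(smooth_image, bool))
        assert np.array_equal(out, smooth_image)

    def test_full_mask_is_plain_gaussian(self, smooth_image):
        from scipy import ndimage

        out = remove_vessels(smooth_image, np.ones_like(smooth_image, bool), sigma=2.0)
        expect = ndimage.gaussian_filter(smooth_image.astype(float), 2.0)
        assert np.abs(out.astype(float) - expect).max() <= 1.0

    def test_line_on_constant_field_filled_exactly(self):
        img = np.full((40, 60), 120, np.uint8)
        img[20, :] = 60
        mask = np.zeros_like(img, bool)
        mask[20, :] = True
        out = remove_vessels(img, mask, sigma=3.0)
        assert np.abs(out.astype(int) - 120).max() <= 1

    def test_shape_mismatch_rejected(self, smooth_image):
        with pytest.raises(ValueError):
            remove_vessels(smooth_image, np.zeros((2, 2), bool))


class TestMaculaGeometric:
    def test_region_radius_is_065_dd(self):
        img = _disc_image(600, 900, 100, [(300, 460, 20, 40)])
        od = OpticDisc(Circle(300, 650, 50))  # DD = 100
        mac = locate_macula_geometric(img, od)
        assert mac.circle.radius == pytest.approx(65.0)

    def test_planted_macula_at_2dd_found_within_5px(self, clean_image_and_truth):
        img, truth = clean_image_and_truth
        enhanced = enhance(img.rgb[:, :, 1], mask=img.fov_mask)
        mac = locate_macula_geometric(enhanced, truth.od)
        tf = truth.macula.fovea
        assert math.hypot(mac.fovea[0] - tf[0], mac.fovea[1] - tf[1]) <= 5.0

    def test_distractor_outside_wedge_rejected(self):
        od = OpticDisc(Circle(300, 650, 45))  # DD=90, search leftwards
        dd = 90.0
        true_r = 300 - 2 * dd * math.sin(math.radians(10))
        true_c = 650 - 2 * dd * math.cos(math.radians(10))
        distract_r = 300 - 2 * dd * math.sin(math.radians(45))
        distract_c = 650 - 2 * dd * math.cos(math.radians(45))
        img = _disc_image(
            600, 900, 100, [(true_r, true_c, 25, 60), (distract_r, distract_c, 25, 10)]
        )
        mac = locate_macula_geometric(img, od)
        assert math.hypot(mac.fovea[0] - true_r, mac.fovea[1] - true_c) <= 6.0
        assert abs(mac.angle_deg) <= 37.0

    def test_geometry_invariants_hold(self, clean_image_and_truth):
        img, truth = clean_image_and_truth
        enhanced = enhance(img.rgb[:, :, 1], mask=img.fov_mask)
        mac = locate_macula_geometric(enhanced, truth.od)
        dist = math.hypot(mac.fovea[0] - truth.od.row, mac.fovea[1] - truth.od.col)
        assert 1.5 * truth.od.dd - 1e-6 <= dist <= 2.5 * truth.od.dd + 1e-6
        assert abs(mac.angle_deg) <= 37.0

    def test_wedge_outside_image_raises(self):
        img = np.full((100, 120), 90, np.uint8)
        od = OpticDisc(Circle(50, 5, 40))  # search wedge falls off the left edge
        with pytest.raises(MaculaOutOfFrameError):
            locate_macula_geometric(img, od, side="left")


class TestMaculaCentreAndMorph:
    def test_centre_method_uses_raster_centre(self):
        img = np.full((600, 900), 80, np.uint8)
        mac = locate_macula_image_centre(img, 60)
        assert mac.fovea == (300, 450)
        assert mac.circle.radius == 60

    def test_centre_mask_area_matches_distance_oracle(self):
        img = np.full((50, 70), 80, np.uint8)
        mac = locate_macula_image_centre(img, 11)
        mask = mac.circle.mask(img.shape)
        count = sum(
            1
            for i in range(50)
            for j in range(70)
            if (i - 25) ** 2 + (j - 35) ** 2 <= 11**2
        )
        assert mask.sum() == count

    def test_oversized_or_zero_radius_rejected(self):
        img = np.full((50, 70), 80, np.uint8)
        with pytest.raises(ValueError):
            locate_macula_image_centre(img, 30)
        with pytest.raises(ValueError):
            locate_macula_image_centre(img, 0)

    def test_morph_constant_image_enhanced_unchanged(self):
        # tophat and bottomhat of a constant image are zero, so the darkest
        # decile is the whole frame and the mask is one big component
        img = np.full((40, 40), 90, np.uint8)
        mask = locate_macula_morphological(img, se_radius=5)
        assert mask.all()

    def test_morph_dark_blob_centroid_recovered(self):
        img = _disc_image(200, 260, 140, [(120, 90, 14, 30)])
        mask = locate_macula_morphological(img, se_radius=8)
        rows, cols = np.nonzero(mask)
        assert math.hypot(rows.mean() - 120, cols.mean() - 90) <= 5.0


class TestCropCircularRoi:
    def test_covering_circle_is_identity(self, smooth_image):
        c = Circle(60, 80, 300)
        assert np.array_equal(crop_circular_roi(smooth_image, c), smooth_image)

    def test_radius_one_keeps_at_most_five_pixels(self):
        img = np.full((20, 20), 200, np.uint8)
        out = crop_circular_roi(img, Circle(10, 10, 1))
        assert 0 < np.count_nonzero(out) <= 5

    def test_matches_distance_oracle_and_is_bit_exact(self, rng):
        img = rng.integers(1, 256, (30, 40), dtype=np.uint8)
        c = Circle(12.0, 25.0, 7.5)
        out = crop_circular_roi(img, c)
        for i in range(30):
            for j in range(40):
                inside = (i - 12.0) ** 2 + (j - 25.0) ** 2 <= 7.5**2
                assert out[i, j] == (img[i, j] if inside else 0)

    def test_disjoint_circle_warns_and_zeroes(self, smooth_image):
        with pytest.warns(UserWarning):
            out = crop_circular_roi(smooth_image, Circle(-500, -500, 10))
        assert not out.any()
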