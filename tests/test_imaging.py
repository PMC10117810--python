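"""Segmentation pipeline: each stage against constructed masks and the
generator's exact ground truth."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from filamentry import (
    BinaryMask,
    ColonyImage,
    NoColonyFound,
    OpeningTooAggressive,
    PreprocessConfig,
    SyntheticColonySpec,
    binarize,
    extract_boundaries,
    fill_voids,
    generate_colony_image,
    measure_image,
    standardize,
)


def disk_image(radius=120, size=(480, 640), fg=60, bg=210):
    yy, xx = np.mgrid[0 : size[0], 0 : size[1]]
    cy, cx = (size[0] - 1) / 2, (size[1] - 1) / 2
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
    return np.where(mask, fg, bg).astype(np.uint8), mask


class TestStandardize:
    def test_grayscale_at_target_unchanged(self, small_config):
        px = np.random.default_rng(0).integers(0, 255, (480, 640)).astype(np.uint8)
        out = standardize(ColonyImage(pixels=px), small_config)
        assert out.pixels.shape == (480, 640)
        np.testing.assert_allclose(out.pixels, px.astype(float))

    def test_achromatic_color_maps_to_same_gray(self, small_config):
        px = np.full((480, 640, 3), 137, dtype=np.uint8)
        out = standardize(ColonyImage(pixels=px), small_config)
        np.testing.assert_allclose(out.pixels, 137.0, atol=1e-6)

    def test_rescales_to_full_working_resolution(self):
        config = PreprocessConfig()  # 2560 x 1920 default
        px = np.random.default_rng(1).integers(0, 255, (960, 1280, 3)).astype(np.uint8)
        out = standardize(ColonyImage(pixels=px), config)
        assert out.pixels.shape == (1920, 2560)
        assert out.is_grayscale

    def test_empty_image_rejected(self):
        from filamentry import InputError

        with pytest.raises(InputError):
            ColonyImage(pixels=np.zeros((0, 0)))


class TestBinarize:
    def test_two_level_image_recovers_painted_region(self, small_config):
        # half-plane colony: blur is symmetric across the straight edge, so
        # the midpoint threshold reproduces the painted region exactly
        px = np.full((480, 640), 220, dtype=np.uint8)
        px[:, :320] = 40
        config = small_config.with_(threshold_method="fixed", threshold_value=130.0)
        mask = binarize(ColonyImage(pixels=px), config)
        expected = np.zeros((480, 640), dtype=bool)
        expected[:, :320] = True
        np.testing.assert_array_equal(mask.pixels, expected)

    def test_uniform_image_raises(self, small_config):
        px = np.full((480, 640), 200, dtype=np.uint8)
        with pytest.raises(NoColonyFound):
            binarize(ColonyImage(pixels=px), small_config)

    def test_light_polarity_flips_foreground(self, small_config):
        px, painted = disk_image(fg=220, bg=40)
        config = small_config.with_(colony_polarity="light")
        mask = binarize(ColonyImage(pixels=px), config)
        overlap = (mask.pixels & painted).sum() / painted.sum()
        assert overlap > 0.98

    def test_noisy_synthetic_total_area_within_5pct(self, small_config):
        spec = SyntheticColonySpec(noise_sd=8.0, rng_seed=17)
        image, truth = generate_colony_image(spec)
        std = standardize(image, small_config)
        mask = binarize(std, small_config)
        assert mask.area_px2 == pytest.approx(truth.total_area_px2, rel=0.05)


class TestFillVoids:
    def test_annulus_becomes_solid_disk(self, small_config):
        yy, xx = np.mgrid[0:200, 0:200]
        r2 = (xx - 100) ** 2 + (yy - 100) ** 2
        annulus = (r2 <= 80**2) & (r2 >= 40**2)
        filled = fill_voids(BinaryMask(pixels=annulus), small_config)
        disk = r2 <= 80**2
        np.testing.assert_array_equal(filled.pixels, disk)

    def test_mask_without_holes_unchanged(self, small_config):
        _, disk = disk_image(radius=50, size=(200, 200))
        out = fill_voids(BinaryMask(pixels=disk), small_config)
        np.testing.assert_array_equal(out.pixels, disk)

    def test_area_cutoff_fills_only_small_voids(self, small_config):
        # connected-component oracle: build a slab with one ~50 px^2 hole and
        # one ~5000 px^2 hole, then check each against ndi.label
        mask = np.ones((200, 300), dtype=bool)
        mask[20:25, 20:30] = False      # 50 px^2
        mask[100:150, 100:200] = False  # 5000 px^2
        config = small_config.with_(fill_all_holes=False, min_void_area_px2=100.0)
        out = fill_voids(BinaryMask(pixels=mask), config)
        holes = ~out.pixels
        labels, n = ndi.label(holes)
        assert n == 1
        assert (~out.pixels).sum() == 5000
        assert out.pixels[22, 25]  # small hole filled
        assert not out.pixels[120, 150]  # large hole kept


class TestExtractBoundaries:
    def test_solid_disk_has_negligible_f(self, small_config):
        px, _ = disk_image(radius=120)
        mask = binarize(ColonyImage(pixels=px), small_config)
        mask = fill_voids(mask, small_config)
        res = extract_boundaries(mask, small_config)
        assert res.a_outer_px2 == pytest.approx(np.pi * 120**2, rel=0.02)
        assert res.f_measure_px2 <= 0.02 * res.a_inner_px2

    def test_inner_area_recovers_core(self, small_config):
        spec = SyntheticColonySpec(filament_width_px=10.0, rng_seed=23)
        image, truth = generate_colony_image(spec)
        std = standardize(image, small_config)
        mask = fill_voids(binarize(std, small_config), small_config)
        res = extract_boundaries(mask, small_config)  # opening radius 12
        assert res.a_inner_px2 == pytest.approx(truth.core_area_px2, rel=0.05)

    def test_object_smaller_than_structuring_element(self, small_config):
        tiny = np.zeros((100, 100), dtype=bool)
        tiny[50:54, 50:54] = True  # 4x4 blob vs radius-12 disk
        with pytest.raises(OpeningTooAggressive):
            extract_boundaries(BinaryMask(pixels=tiny), small_config)

    def test_empty_mask_raises(self, small_config):
        with pytest.raises(NoColonyFound):
            extract_boundaries(
                BinaryMask(pixels=np.zeros((50, 50), dtype=bool)), small_config
            )

    def test_qc_contours_present(self, small_config):
        px, _ = disk_image(radius=100)
        mask = fill_voids(binarize(ColonyImage(pixels=px), small_config), small_config)
        res = extract_boundaries(mask, small_config, keep_qc=True)
        assert res.qc["outer_contour"] is not None
        assert res.qc["inner_contour"] is not None


class TestMeasureImage:
    def test_featureless_image_raises(self, small_config):
        px = np.full((480, 640), 180, dtype=np.uint8)
        with pytest.raises(NoColonyFound):
            measure_image(ColonyImage(pixels=px), small_config)

    def test_f_measure_recovers_ground_truth(self, small_config):
        spec = SyntheticColonySpec(n_filaments=12, filament_width_px=10.0, rng_seed=29)
        image, truth = generate_colony_image(spec)
        res = measure_image(image, small_config, keep_qc=False)
        assert res.f_measure_px2 == pytest.approx(
            truth.filament_area_px2, rel=0.15
        )
        assert res.a_outer_px2 >= res.a_inner_px2 >= 0

    def test_solid_disk_f_below_2pct_of_inner(self, small_config):
        px, _ = disk_image(radius=130)
        res = measure_image(ColonyImage(pixels=px), small_config)
        assert res.f_measure_px2 <= 0.02 * res.a_inner_px2

    def test_calibrated_output_in_mm2(self, small_config):
        px, _ = disk_image(radius=100)
        img = ColonyImage(pixels=px, pixel_size_um=0.88)
        res = measure_image(img, small_config)
        assert res.f_measure_calibrated == pytest.approx(
            res.f_measure_px2 * (0.88 / 1000.0) ** 2
        )

    @pytest.mark.parametrize("seed", [31, 37])
    def test_rotation_robustness(self, small_config, seed):
        """A 90-degree rotation changes f by < 3%."""
        spec = SyntheticColonySpec(
            image_width_px=480, image_height_px=480, rng_seed=seed
        )
        config = PreprocessConfig(target_resolution=(480, 480), opening_radius_px=12)
        image, _ = generate_colony_image(spec)
        res = measure_image(image, config, keep_qc=False)
        rot = ColonyImage(pixels=np.rot90(image.pixels).copy(), source_id="rot")
        res_rot = measure_image(rot, config, keep_qc=False)
        assert res_rot.f_measure_px2 == pytest.approx(res.f_measure_px2, rel=0.03)

    @pytest.mark.parametrize("seed", [41, 43, 47])
    def test_extra_filament_never_decreases_f(self, small_config, seed):
        """Monotonicity: appending one more protrusion (same first angles)
        cannot lower the measured filamentous area."""
        base = SyntheticColonySpec(n_filaments=6, noise_sd=0.0, rng_seed=seed)
        more = SyntheticColonySpec(n_filaments=7, noise_sd=0.0, rng_seed=seed)
        img_a, _ = generate_colony_image(base)
        img_b, _ = generate_colony_image(more)
        f_a = measure_image(img_a, small_config, keep_qc=False).f_measure_px2
        f_b = measure_image(img_b, small_config, keep_qc=False).f_measure_px2
        assert f_b >= f_a - 1e-9
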