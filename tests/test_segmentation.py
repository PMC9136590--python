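from dataclasses import replace

import numpy as np
import pytest

from chemotax import (
    GrayscaleImage,
    SegmentationConfig,
    SpotRing,
    ValidationError,
    filter_objects,
    generate_synthetic_plate,
    preprocess,
    segment_foreground,
)

from conftest import small_spec


def run_segmentation(image, geometry, config=None):
    cfg = config or SegmentationConfig()
    flat = preprocess(image, geometry, cfg)
    fg = segment_foreground(flat, geometry, cfg)
    return fg, filter_objects(fg, geometry, cfg)


class TestPreprocess:
    def test_constant_image_maps_to_constant(self, centered_geometry):
        img = GrayscaleImage(pixels=np.full((384, 384), 0.7))
        out = preprocess(img, centered_geometry)
        inside = np.isclose(out.pixels, out.pixels[192, 192])
        assert inside.all()

    def test_pure_vignette_flattens_below_residual_bound(self, centered_geometry):
        spec = small_spec(worms_per_quadrant=(0, 0, 0, 0), vignette_strength=0.5,
                          noise_sd=0.0, blur_sigma=0.0, seed=1)
        image, gt = generate_synthetic_plate(spec)
        out = preprocess(image, gt.true_geometry)
        rows = np.arange(384)[:, None] - gt.true_geometry.center[0]
        cols = np.arange(384)[None, :] - gt.true_geometry.center[1]
        inside = np.hypot(rows, cols) <= gt.true_geometry.scoring_radius
        assert np.ptp(out.pixels[inside]) < 0.05

    def test_blob_contrast_preserved_within_20_percent(self):
        spec = small_spec(worms_per_quadrant=(5, 5, 5, 5), vignette_strength=0.3,
                          noise_sd=0.0, blur_sigma=0.0, seed=2)
        image, gt = generate_synthetic_plate(spec)
        geo = gt.true_geometry
        rows = np.arange(384)[:, None] - geo.center[0]
        cols = np.arange(384)[None, :] - geo.center[1]
        inside = np.hypot(rows, cols) <= geo.scoring_radius
        bg = inside & ~gt.worm_mask

        def contrast(px):
            return px[bg].mean() - px[gt.worm_mask].mean()

        before = contrast(image.pixels)
        after = contrast(preprocess(image, geo).pixels)
        assert abs(after - before) <= 0.2 * before


class TestSegmentForeground:
    def test_blank_plate_yields_empty_mask_with_warning(self, centered_geometry):
        spec = small_spec(worms_per_quadrant=(0, 0, 0, 0), seed=3)
        image, gt = generate_synthetic_plate(spec)
        flat = preprocess(image, gt.true_geometry)
        with pytest.warns(UserWarning):
            mask = segment_foreground(flat, gt.true_geometry)
        assert mask.sum() == 0

    def test_degenerate_histogram_warns_not_raises(self, centered_geometry):
        img = GrayscaleImage(pixels=np.full((384, 384), 0.5))
        with pytest.warns(UserWarning):
            mask = segment_foreground(img, centered_geometry)
        assert mask.sum() == 0

    def test_recovered_area_within_10_percent(self, default_plate):
        _, image, gt = default_plate
        fg, seg = run_segmentation(image, gt.true_geometry)
        true_area = gt.worm_mask.sum()
        assert abs(seg.kept_pixels - true_area) <= 0.1 * true_area

    def test_mask_zero_outside_plate(self, default_plate):
        _, image, gt = default_plate
        geo = gt.true_geometry
        fg, _ = run_segmentation(image, geo)
        rows = np.arange(384)[:, None] - geo.center[0]
        cols = np.arange(384)[None, :] - geo.center[1]
        outside = np.hypot(rows, cols) > geo.scoring_radius
        assert not fg[outside].any()

    def test_polarity_flag_on_inverted_image_gives_identical_mask(self):
        dark = small_spec(worms_per_quadrant=(6, 2, 5, 3), seed=4)
        light = replace(dark, foreground_polarity="light_on_dark")
        img_d, gt = generate_synthetic_plate(dark)
        img_l, _ = generate_synthetic_plate(light)
        geo = gt.true_geometry
        mask_d, _ = run_segmentation(img_d, geo, SegmentationConfig(polarity="dark"))
        mask_l, _ = run_segmentation(img_l, geo, SegmentationConfig(polarity="light"))
        np.testing.assert_array_equal(mask_d, mask_l)

    def test_fixed_threshold_method(self, clean_plate):
        _, image, gt = clean_plate
        cfg = SegmentationConfig(threshold_method="fixed", fixed_threshold=0.25)
        flat = preprocess(image, gt.true_geometry, cfg)
        mask = segment_foreground(flat, gt.true_geometry, cfg)
        np.testing.assert_array_equal(mask, gt.worm_mask)


class TestFilterObjects:
    def test_speck_below_floor_filtered_entirely(self, centered_geometry):
        mask = np.zeros((384, 384), bool)
        mask[190, 250:252] = True  # 2-pixel speck inside the plate
        cfg = SegmentationConfig(min_area_px=10)
        res = filter_objects(mask, centered_geometry, cfg)
        assert res.mask.sum() == 0
        assert res.filtered_pixels == 2

    def test_debris_specks_filtered_worm_area_preserved(self):
        spec = small_spec(worms_per_quadrant=(4, 4, 4, 4), debris_count=5,
                          debris_area_px=3, noise_sd=0.0, blur_sigma=0.0,
                          vignette_strength=0.0, seed=5)
        image, gt = generate_synthetic_plate(spec)
        fg, seg = run_segmentation(image, gt.true_geometry)
        assert seg.filtered_pixels == 15
        assert seg.kept_pixels == gt.worm_mask.sum()

    def test_spot_ring_filtered_out(self):
        spec = small_spec(worms_per_quadrant=(4, 4, 4, 4), noise_sd=0.0,
                          blur_sigma=0.0, vignette_strength=0.0,
                          spot_ring=SpotRing(quadrant=1, radius=16, thickness=3),
                          seed=6)
        image, gt = generate_synthetic_plate(spec)
        fg, seg = run_segmentation(image, gt.true_geometry)
        ring_px = gt.artifact_mask.sum()
        assert seg.filtered_pixels == ring_px
        assert seg.kept_pixels == gt.worm_mask.sum()

    def test_ring_kept_when_filter_disabled(self):
        spec = small_spec(worms_per_quadrant=(0, 0, 0, 0), noise_sd=0.0,
                          blur_sigma=0.0, vignette_strength=0.0,
                          spot_ring=SpotRing(quadrant=1, radius=16, thickness=3),
                          seed=6)
        image, gt = generate_synthetic_plate(spec)
        cfg = SegmentationConfig(ring_filter=False)
        fg, seg = run_segmentation(image, gt.true_geometry, cfg)
        assert seg.kept_pixels == gt.artifact_mask.sum()

    def test_large_clump_kept_whole(self):
        spec = small_spec(worms_per_quadrant=(0, 0, 0, 0),
                          clumps_per_quadrant=(1, 0, 0, 0), clump_size=4,
                          noise_sd=0.0, blur_sigma=0.0, vignette_strength=0.0, seed=7)
        image, gt = generate_synthetic_plate(spec)
        fg, seg = run_segmentation(image, gt.true_geometry)
        assert seg.kept_pixels == gt.worm_mask.sum()
        assert len(seg.objects) == 1

    def test_empty_mask_gives_empty_result(self, centered_geometry):
        res = filter_objects(np.zeros((384, 384), bool), centered_geometry)
        assert res.filtered_pixels == 0
        assert res.kept_pixels == 0
        assert res.objects == ()


class TestInvariants:
    def test_pixel_conservation_exact(self, default_plate):
        _, image, gt = default_plate
        fg, seg = run_segmentation(image, gt.true_geometry)
        assert seg.kept_pixels + seg.filtered_pixels == int(fg.sum())

    def test_raising_min_area_never_decreases_filtered(self, default_plate):
        _, image, gt = default_plate
        fg, _ = run_segmentation(image, gt.true_geometry)
        prev = -1
        for min_area in (0, 5, 20, 60, 200, 10_000):
            cfg = SegmentationConfig(min_area_px=min_area)
            filtered = filter_objects(fg, gt.true_geometry, cfg).filtered_pixels
            assert filtered >= prev
            prev = filtered

    def test_filtering_is_idempotent(self, default_plate):
        _, image, gt = default_plate
        cfg = SegmentationConfig()
        fg, seg = run_segmentation(image, gt.true_geometry, cfg)
        again = filter_objects(seg.mask, gt.true_geometry, cfg)
        assert again.filtered_pixels == 0
        np.testing.assert_array_equal(again.mask, seg.mask)


class TestConfigValidation:
    def test_fixed_method_requires_value(self):
        with pytest.raises(ValidationError):
            SegmentationConfig(threshold_method="fixed")

    def test_unknown_polarity_rejected(self):
        with pytest.raises(ValidationError):
            SegmentationConfig(polarity="sideways")
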