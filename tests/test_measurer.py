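"""Crop extraction, resize round-trips, morphological center isolation,
area counting and calibration."""

import numpy as np
import pytest

from eyespot.boxes import Box
from eyespot.measurer import (
    CropGeometry,
    extract_crop,
    inverse_resize_mask,
    isolate_center,
    measure,
    resize_crop,
    strip_padding,
    whole_wing_split,
)
from eyespot.synthetic import CENTER, RINGS


def _annulus(size=128, outer=40, inner=20):
    rr, cc = np.mgrid[0:size, 0:size]
    d2 = (rr - size // 2) ** 2 + (cc - size // 2) ** 2
    return ((d2 <= outer**2) & (d2 > inner**2)).astype(np.uint8)


class TestExtractCrop:
    def test_centered_crop_arithmetic(self, rng):
        img = rng.random((128, 128, 3)).astype(np.float32)
        crop, geom = extract_crop(img, center=(64, 64), side=50)
        assert crop.shape[:2] == (50, 50)
        assert np.array_equal(crop, img[39:89, 39:89])
        assert (geom.pad_top, geom.pad_left, geom.pad_bottom, geom.pad_right) == (0, 0, 0, 0)

    def test_margin_one_square_box_equals_box(self, rng):
        img = rng.random((100, 100, 3)).astype(np.float32)
        box = Box(20, 30, 60, 70, "eyespot")
        crop, geom = extract_crop(img, box=box, margin_factor=1.0)
        assert geom.side == 40
        assert np.array_equal(crop, img[30:70, 20:60])

    def test_border_padding_recorded(self, rng):
        img = rng.random((100, 100, 3)).astype(np.float32)
        crop, geom = extract_crop(img, center=(50, 10), side=50)
        assert geom.pad_left == 15
        assert crop.shape[:2] == (50, 50)
        # replicated edge pixels on the padded band
        assert np.array_equal(crop[:, 0], crop[:, geom.pad_left - 1])

    def test_degenerate_rejected(self, rng):
        img = rng.random((10, 10, 3)).astype(np.float32)
        with pytest.raises(ValueError):
            extract_crop(img, center=(5, 5), side=0)


class TestResizeRoundTrips:
    def test_block_constant_mask_is_exact(self):
        base = np.arange(32 * 32).reshape(32, 32) % 3
        mask = base.repeat(4, axis=0).repeat(4, axis=1).astype(np.uint8)  # 128²
        geom = CropGeometry("x", (0, 0), 256, model_input_size=128)
        up = inverse_resize_mask(mask, geom)
        geom_back = CropGeometry("x", (0, 0), 128, model_input_size=128)
        # nearest-neighbor up and back down reproduces the block mask
        back = inverse_resize_mask(up, geom_back)
        assert np.array_equal(back, mask)

    def test_identity_when_sizes_match(self, rng):
        mask = rng.integers(0, 3, (128, 128)).astype(np.uint8)
        geom = CropGeometry("x", (0, 0), 128, model_input_size=128)
        assert np.array_equal(inverse_resize_mask(mask, geom), mask)

    def test_area_scales_quadratically(self):
        mask = np.zeros((128, 128), np.uint8)
        rr, cc = np.mgrid[0:128, 0:128]
        mask[(rr - 64) ** 2 + (cc - 64) ** 2 <= 30**2] = 1
        k = mask.sum()
        geom = CropGeometry("x", (0, 0), 256, model_input_size=128)
        up = inverse_resize_mask(mask, geom)
        # 2x nearest upsample of a disc: area 4k up to boundary discretization
        assert up.sum() == pytest.approx(4 * k, rel=0.02)

    def test_resize_crop_shape(self, rng):
        crop = rng.random((51, 51, 3)).astype(np.float32)
        assert resize_crop(crop, 128).shape == (128, 128, 3)


class TestIsolateCenter:
    def test_ideal_annulus_recovers_disc_area(self):
        rings = _annulus()
        center = isolate_center(rings)
        assert center.sum() == pytest.approx(np.pi * 20**2, rel=0.02)
        assert (center[rings > 0] == 0).all()

    def test_all_zero_mask_gives_empty_center(self):
        assert isolate_center(np.zeros((64, 64), np.uint8)).sum() == 0

    def test_broken_ring_leaks_to_boundary(self):
        rings = _annulus()
        rings[64 - 1 : 64 + 2, :] = np.where(
            rings[64 - 1 : 64 + 2, :] > 0, 0, rings[64 - 1 : 64 + 2, :]
        )  # 3-px horizontal gap through the annulus
        assert isolate_center(rings).sum() == 0

    def test_matches_generated_ground_truth(self, default_crop):
        _, mask, gt = default_crop
        rings = (mask == RINGS).astype(np.uint8)
        center = isolate_center(rings)
        assert center.sum() == pytest.approx(gt.true_center_area_px[0], rel=0.02)


class TestMeasure:
    def _geom(self, side):
        return CropGeometry("img", (0.0, 0.0), side)

    def test_calibration_constant(self):
        """837.75 ring pixels at 28.944 px/mm -> 1.000 mm²."""
        side = 40
        rings = np.zeros((side, side), np.uint8)
        rings.flat[:838] = 1  # 838 px ≈ 28.944² = 837.75 px per mm²
        m = measure(np.zeros_like(rings), rings, self._geom(side), px_per_mm=28.944)
        assert m.rings_area_mm2 == pytest.approx(1.0, abs=3e-4)

    def test_empty_masks_zero_areas(self):
        z = np.zeros((16, 16), np.uint8)
        m = measure(z, z, self._geom(16))
        assert m.total_area_px == 0 and m.total_area_mm2 == 0

    def test_doubling_scale_quarters_mm2(self):
        rings = np.ones((10, 10), np.uint8)
        m1 = measure(np.zeros_like(rings), rings, self._geom(10), px_per_mm=10)
        m2 = measure(np.zeros_like(rings), rings, self._geom(10), px_per_mm=20)
        assert m2.rings_area_mm2 == pytest.approx(m1.rings_area_mm2 / 4)

    def test_conservation(self, rng):
        center = (rng.random((20, 20)) < 0.2).astype(np.uint8)
        rings = ((rng.random((20, 20)) < 0.3) & (center == 0)).astype(np.uint8)
        m = measure(center, rings, self._geom(20))
        assert m.total_area_px == m.center_area_px + m.rings_area_px
        assert m.total_area_mm2 == pytest.approx(
            m.center_area_mm2 + m.rings_area_mm2, abs=1e-12
        )

    def test_overlap_rejected(self):
        ones = np.ones((8, 8), np.uint8)
        with pytest.raises(ValueError, match="overlap"):
            measure(ones, ones, self._geom(8))

    def test_padding_stripped_before_counting(self):
        side = 20
        rings = np.ones((side, side), np.uint8)
        geom = CropGeometry("img", (0.0, 0.0), side, pad_top=5, pad_left=3)
        m = measure(np.zeros_like(rings), rings, geom)
        assert m.rings_area_px == (side - 5) * (side - 3)


class TestWholeWingSplit:
    def test_two_disjoint_eyespots(self, rng):
        mask = np.zeros((100, 100), np.uint8)
        for ctr in ((25, 25), (75, 75)):
            rr, cc = np.mgrid[0:100, 0:100]
            d2 = (rr - ctr[0]) ** 2 + (cc - ctr[1]) ** 2
            mask[(d2 <= 15**2)] = RINGS
            mask[(d2 <= 6**2)] = CENTER
        comps = whole_wing_split(mask)
        assert len(comps) == 2
        for center, rings in comps:
            assert center.sum() == pytest.approx(np.pi * 36, rel=0.05)
            assert (center & rings).sum() == 0

    def test_empty_mask(self):
        assert whole_wing_split(np.zeros((10, 10), np.uint8)) == []

    def test_component_without_center(self):
        mask = np.zeros((20, 20), np.uint8)
        mask[5:10, 5:10] = RINGS
        comps = whole_wing_split(mask)
        assert len(comps) == 1
        center, rings = comps[0]
        assert center.sum() == 0 and rings.sum() == 25


@pytest.fixture(scope="module")
def tiny_seg_model():
    """Quickly trained small U-Net for pipeline-level measurement tests."""
    from eyespot.nn import TrainConfig
    from eyespot.segmenter import SegmenterConfig, train_segmenter
    from eyespot.synthetic import SceneParams, generate_crop_dataset

    data = generate_crop_dataset(
        10, SceneParams(n_elements=(1, 1), eyespot_outer_radius=(10.0, 14.0)), seed=33
    )
    cfg = SegmenterConfig(
        n_classes=3, input_size=32, base_width=8, depth=2,
        train=TrainConfig(lr=3e-3, max_epochs=25, patience=25, batch_size=4, seed=0),
    )
    model, _ = train_segmenter([c for c, _, _ in data], [m for _, m, _ in data], cfg)
    return model


class TestMeasurementPipeline:
    def test_zero_detections_empty_output(self, rng):
        from eyespot.measurer import run_measurement_pipeline
        from eyespot.segmenter import SegmenterConfig, build_unet

        model = build_unet(SegmenterConfig(input_size=32, base_width=4, depth=2))
        img = rng.random((64, 64, 3)).astype(np.float32)
        assert run_measurement_pipeline(img, [], model) == []

    def test_measurement_scale_invariance(self, tiny_seg_model):
        """Measuring a 2x-upscaled eyespot and dividing by 4 agrees with the
        native-scale measurement within a few percent."""
        from dataclasses import replace as drep

        from skimage.transform import resize as sk_resize

        from eyespot.measurer import run_measurement_pipeline
        from eyespot.synthetic import SceneParams, generate_eyespot_crop

        crop, mask, gt = generate_eyespot_crop(
            SceneParams(n_elements=(1, 1), eyespot_outer_radius=(11.0, 13.0), seed=5)
        )
        box = gt.boxes[0]
        rec1 = run_measurement_pipeline(crop, [box], tiny_seg_model)[0]
        big = sk_resize(crop, (crop.shape[0] * 2, crop.shape[1] * 2), order=1,
                        anti_aliasing=False, preserve_range=True).astype(np.float32)
        box2 = drep(box, x_min=2 * box.x_min, y_min=2 * box.y_min,
                    x_max=2 * box.x_max, y_max=2 * box.y_max)
        rec2 = run_measurement_pipeline(big, [box2], tiny_seg_model)[0]
        assert rec2.total_area_px / 4 == pytest.approx(rec1.total_area_px, rel=0.03)

    def test_same_inputs_identical_measurements(self, tiny_seg_model):
        from eyespot.synthetic import SceneParams, generate_eyespot_crop
        from eyespot.measurer import run_measurement_pipeline

        crop, _, gt = generate_eyespot_crop(SceneParams(n_elements=(1, 1), seed=9))
        r1 = run_measurement_pipeline(crop, gt.boxes, tiny_seg_model)
        r2 = run_measurement_pipeline(crop, gt.boxes, tiny_seg_model)
        assert r1 == r2

    def test_strip_padding_zeroes_bands(self):
        m = np.ones((10, 10), np.uint8)
        geom = CropGeometry("x", (0, 0), 10, pad_top=2, pad_right=3)
        s = strip_padding(m, geom)
        assert s[:2].sum() == 0 and s[:, -3:].sum() == 0 and s.sum() == 8 * 7
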