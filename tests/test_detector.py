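"""Anchors, target assignment, focal loss, augmentation, NMS, letterboxing."""

import math

import numpy as np
import pytest

from eyespot.boxes import Box, mask_to_box
from eyespot.detector import (
    ClassScheme,
    DetectorConfig,
    MiniDetector,
    assign_targets,
    augment,
    detect,
    focal_loss,
    generate_anchors,
    letterbox_image,
    nms,
    train_detector,
)
from eyespot.metrics import iou_boxes
from eyespot.nn import TrainConfig


class TestAnchors:
    def test_count_stride32(self):
        cfg = DetectorConfig(input_size=256, stride=32, anchor_scales=(16.0, 32.0, 64.0))
        a = generate_anchors(cfg, (256, 256))
        assert a.shape == (8 * 8 * 3, 4)

    def test_square_anchor_side_equals_scale(self):
        cfg = DetectorConfig(input_size=256, stride=32, anchor_scales=(24.0,), aspect_ratios=(1.0,))
        a = generate_anchors(cfg, (256, 256))
        interior = a[(a[:, 0] > 0) & (a[:, 1] > 0) & (a[:, 2] < 256) & (a[:, 3] < 256)]
        assert np.allclose(interior[:, 2] - interior[:, 0], 24.0)
        assert np.allclose(interior[:, 3] - interior[:, 1], 24.0)

    def test_deterministic(self):
        cfg = DetectorConfig()
        a1 = generate_anchors(cfg, (256, 256))
        a2 = generate_anchors(cfg, (256, 256))
        assert np.array_equal(a1, a2)

    def test_stride_must_divide(self):
        with pytest.raises(ValueError):
            DetectorConfig(input_size=250, stride=16)


class TestAssignTargets:
    names = ("spot", "eyespot")

    def test_identical_anchor_is_positive_with_zero_regression(self):
        anchors = np.array([[10.0, 10.0, 30.0, 30.0], [100.0, 100.0, 130.0, 130.0]])
        gts = [Box(10, 10, 30, 30, "eyespot")]
        cls, reg = assign_targets(anchors, gts, self.names)
        assert cls[0] == 2  # eyespot = class index 1 -> target 2
        assert np.allclose(reg[0], 0.0)

    def test_empty_gt_all_negative(self):
        anchors = np.array([[0.0, 0.0, 10.0, 10.0]])
        cls, reg = assign_targets(anchors, [], self.names)
        assert (cls == 0).all()

    def test_forced_match_below_pos_iou(self):
        anchors = np.array([[0.0, 0.0, 10.0, 10.0], [50.0, 50.0, 60.0, 60.0]])
        gts = [Box(6, 6, 18, 18, "spot")]  # best anchor IoU < pos threshold
        best_iou = max(
            iou_boxes(Box(*a), gts[0]) for a in anchors  # noqa: B905
        )
        assert best_iou < 0.5
        cls, _ = assign_targets(anchors, gts, self.names, pos_iou=0.5, neg_iou=0.4)
        assert cls[0] == 1

    def test_ignore_band(self):
        anchors = np.array([[0.0, 0.0, 10.0, 10.0]])
        gts = [Box(0, 0, 10, 23, "spot")]  # IoU = 100/230 ≈ 0.435
        cls, _ = assign_targets(np.vstack([anchors, [[50, 50, 60, 60]]]), gts, self.names)
        # forced match wins for the best anchor, so add a second GT-free anchor
        assert cls[1] == 0


class TestFocalLoss:
    def test_confident_correct_is_near_zero(self):
        assert focal_loss(np.array([1.0 - 1e-7]), np.array([1])) < 1e-5

    def test_gamma0_alpha1_is_cross_entropy(self):
        v = focal_loss(np.array([0.5]), np.array([1]), alpha=1.0, gamma=0.0)
        assert v == pytest.approx(math.log(2), abs=1e-6)

    def test_retina_defaults_closed_form(self):
        v = focal_loss(np.array([0.5]), np.array([1]), alpha=0.25, gamma=2.0)
        assert v == pytest.approx(0.25 * 0.25 * math.log(2), abs=1e-6)

    def test_monotone_decreasing_in_pt(self):
        ps = np.linspace(0.05, 0.95, 40)
        losses = [focal_loss(np.array([p]), np.array([1])) for p in ps]
        assert all(a > b for a, b in zip(losses, losses[1:]))


class TestAugment:
    def test_identity_when_disabled(self, rng):
        img = rng.random((16, 20, 3)).astype(np.float32)
        boxes = [Box(2, 3, 10, 8, "spot")]
        out, out_boxes = augment(
            img, boxes, rng=rng, hue_amplitude=0.0, sat_range=(1.0, 1.0),
            val_range=(1.0, 1.0), force_flip=False,
        )
        assert np.allclose(out, img, atol=1e-6)
        assert out_boxes == boxes

    def test_flip_is_involution(self, rng):
        img = rng.random((16, 20, 3)).astype(np.float32)
        boxes = [Box(2, 3, 10, 8, "spot"), Box(0, 0, 5, 5, "eyespot")]
        kwargs = dict(hue_amplitude=0.0, sat_range=(1.0, 1.0), val_range=(1.0, 1.0))
        once_img, once = augment(img, boxes, rng=rng, force_flip=True, **kwargs)
        twice_img, twice = augment(once_img, once, rng=rng, force_flip=True, **kwargs)
        assert np.allclose(twice_img, img, atol=1e-6)
        for b1, b2 in zip(boxes, twice):
            assert b1.as_array() == pytest.approx(b2.as_array())

    def test_flip_formula_matches_mask_flip(self, rng):
        """Flip a rasterized mask and re-extract the tight box: must equal
        the analytic flip of the box."""
        mask = np.zeros((10, 20), np.uint8)
        mask[3:8, 2:10] = 1
        box = mask_to_box(mask, "spot")
        assert box.as_array() == pytest.approx([2, 3, 10, 8])
        img = rng.random((10, 20, 3)).astype(np.float32)
        _, flipped = augment(
            img, [box], rng=rng, hue_amplitude=0.0, sat_range=(1.0, 1.0),
            val_range=(1.0, 1.0), force_flip=True,
        )
        oracle = mask_to_box(mask[:, ::-1], "spot")
        assert flipped[0].as_array() == pytest.approx(oracle.as_array())
        assert flipped[0].as_array() == pytest.approx([10, 3, 18, 8])

    def test_output_clipped_to_unit_range(self, rng):
        img = rng.random((8, 8, 3)).astype(np.float32)
        out, _ = augment(img, [], rng=rng, val_range=(1.5, 1.5))
        assert out.max() <= 1.0 and out.min() >= 0.0


class TestNms:
    def test_single_and_disjoint_kept(self):
        a = Box(0, 0, 10, 10, "spot", 0.9)
        b = Box(50, 50, 60, 60, "spot", 0.8)
        assert nms([a]) == [a]
        assert nms([a, b]) == [a, b]

    def test_overlapping_suppressed(self):
        a = Box(0, 0, 10, 10, "spot", 0.9)
        b = Box(1, 1, 11, 11, "spot", 0.8)
        assert iou_boxes(a, b) == pytest.approx(81 / 119)
        assert nms([a, b], 0.3) == [a]

    def test_classwise_no_cross_suppression(self):
        a = Box(0, 0, 10, 10, "spot", 0.9)
        b = Box(1, 1, 11, 11, "eyespot", 0.8)
        assert nms([a, b], 0.3) == [a, b]

    def test_matches_bruteforce_oracle(self, rng):
        """Greedy NMS equals exhaustive suppression on random sets <= 12 boxes."""

        def oracle(boxes, thr):
            order = sorted(boxes, key=lambda b: -b.score)
            kept = []
            for b in order:
                if all(
                    k.label != b.label or iou_boxes(b, k) <= thr for k in kept
                ):
                    kept.append(b)
            return kept

        for _ in range(100):
            n = rng.integers(0, 13)
            boxes = []
            for _ in range(n):
                x, y = rng.integers(0, 30, 2)
                w, h = rng.integers(2, 15, 2)
                boxes.append(
                    Box(
                        float(x), float(y), float(x + w), float(y + h),
                        label=("spot", "eyespot")[rng.integers(2)],
                        score=float(np.round(rng.random(), 4)),
                    )
                )
            assert nms(boxes, 0.3) == oracle(boxes, 0.3)


class TestLetterboxAndDetect:
    def test_letterbox_roundtrip_within_half_pixel(self):
        img = np.zeros((100, 200, 3), np.float32)
        _, lb = letterbox_image(img, 256)
        box = Box(10, 20, 50, 60, "spot", 0.5)
        back = lb.to_image(lb.to_model(box))
        assert back.as_array() == pytest.approx(box.as_array(), abs=0.5)

    def test_score_threshold_one_yields_empty(self):
        cfg = DetectorConfig(train=TrainConfig(seed=0))
        model = MiniDetector(cfg, ClassScheme("one_class_all"))
        img = np.full((256, 256, 3), 0.5, np.float32)
        assert detect(model, img, score_threshold=1.0) == []

    def test_training_smoke_and_log(self):
        """Two-epoch training on four tiny scenes runs end to end and logs."""
        from eyespot.synthetic import SceneParams, generate_scene_dataset

        params = SceneParams(image_size=(64, 64), n_elements=(1, 1),
                             eyespot_outer_radius=(8.0, 12.0), spot_radius=(5.0, 8.0))
        scenes = generate_scene_dataset(4, params, seed=0)
        scheme = ClassScheme("one_class_all")
        cfg = DetectorConfig(
            input_size=64, stride=16, anchor_scales=(16.0, 24.0),
            train=TrainConfig(max_epochs=2, patience=2, batch_size=2, seed=0),
        )
        pairs = [(img, scheme.map_gt_boxes(gt)) for img, gt in scenes]
        model, log = train_detector(pairs[:3], pairs[3:], scheme, cfg)
        assert log.n_epochs == 2
        assert all("val_loss" in e for e in log.epochs)
        dets = detect(model, pairs[0][0], score_threshold=0.0)
        assert all(d.score >= 0.0 and d.label == "element" for d in dets)

    def test_checkpoint_roundtrip(self, tmp_path):
        from eyespot.detector import load_detector, save_detector

        cfg = DetectorConfig(input_size=64, stride=16, train=TrainConfig(seed=1))
        model = MiniDetector(cfg, ClassScheme("two_class"))
        p = tmp_path / "det.npz"
        save_detector(p, model)
        model2 = load_detector(p)
        img = np.random.default_rng(0).random((64, 64, 3)).astype(np.float32)
        d1 = detect(model, img, score_threshold=0.0)
        d2 = detect(model2, img, score_threshold=0.0)
        assert len(d1) == len(d2)
        for a, b in zip(d1, d2):
            assert a.as_array() == pytest.approx(b.as_array(), abs=1e-4)
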