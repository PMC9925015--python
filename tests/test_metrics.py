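"""Evaluation metrics against hand counts and brute-force oracles."""

import numpy as np
import pytest

from eyespot.boxes import Box
from oracles import ap_bruteforce as _ap_oracle
from oracles import iou_raster as _iou_raster_oracle
from oracles import random_box_scene as _random_scene

from eyespot.metrics import (
    DEFAULT_IOU_THRESHOLDS,
    ap_per_class,
    area_error_stats,
    average_precision,
    iou_boxes,
    match_detections,
    mean_ap,
    precision,
    recall,
    segmentation_metrics,
)

# ---------------------------------------------------------------------------
# iou_boxes
# ---------------------------------------------------------------------------

class TestIouBoxes:
    def test_identical_and_disjoint(self):
        a = Box(0, 0, 10, 10)
        assert iou_boxes(a, a) == 1.0
        assert iou_boxes(a, Box(20, 20, 30, 30)) == 0.0

    def test_half_overlap_hand_value(self):
        # (0,0,10,10) vs (5,0,15,10): intersection 50, union 150
        v = iou_boxes(Box(0, 0, 10, 10), Box(5, 0, 15, 10))
        assert v == pytest.approx(50 / 150, abs=1e-12)

    def test_matches_pixel_rasterization_on_random_integer_boxes(self, rng):
        for _ in range(300):
            (a,) = _random_scene(rng, 1, scored=False) or [Box(0, 0, 2, 2)]
            (b,) = _random_scene(rng, 1, scored=False) or [Box(1, 1, 3, 3)]
            assert iou_boxes(a, b) == pytest.approx(_iou_raster_oracle(a, b), abs=1e-12)


# ---------------------------------------------------------------------------
# matching, precision, recall
# ---------------------------------------------------------------------------

class TestMatchDetections:
    def test_duplicate_detection_rule(self):
        """Two detections on one GT: the higher-scoring one is the TP, the
        other a FP; the second GT's detection is also a TP."""
        gts = [Box(0, 0, 10, 10, "eyespot"), Box(30, 30, 40, 40, "eyespot")]
        dets = [
            Box(0, 0, 10, 10, "eyespot", 0.9),
            Box(1, 1, 11, 11, "eyespot", 0.7),
            Box(30, 30, 40, 40, "eyespot", 0.8),
        ]
        r = match_detections(dets, gts, 0.5)
        assert (r.tp("eyespot"), r.fp("eyespot"), r.fn("eyespot")) == (2, 1, 0)

    def test_no_detections(self):
        gts = [Box(0, 0, 5, 5, "spot")] * 0 + [Box(0, 0, 5, 5, "spot"), Box(9, 9, 12, 12, "spot")]
        r = match_detections([], gts, 0.5)
        assert (r.tp("spot"), r.fp("spot"), r.fn("spot")) == (0, 0, 2)

    def test_iou_exactly_at_threshold_is_tp(self):
        gt = [Box(0, 0, 10, 10, "spot")]
        det = [Box(0, 0, 10, 5, "spot", 0.9)]  # IoU exactly 0.5
        assert iou_boxes(det[0], gt[0]) == 0.5
        r = match_detections(det, gt, 0.5)
        assert r.tp("spot") == 1

    def test_counts_conservation_random(self, rng):
        for _ in range(50):
            gts = _random_scene(rng, scored=False)
            dets = _random_scene(rng)
            r = match_detections(dets, gts, 0.5)
            for lbl in ("spot", "eyespot"):
                n_gt = sum(1 for g in gts if g.label == lbl)
                n_det = sum(1 for d in dets if d.label == lbl)
                assert r.tp(lbl) + r.fn(lbl) == n_gt
                assert r.tp(lbl) + r.fp(lbl) == n_det


class TestPrecisionRecall:
    def test_values_and_conventions(self):
        assert precision(3, 1) == 0.75
        assert precision(0, 0) == 1.0
        assert recall(0, 5) == 0.0
        assert recall(3, 1) == 0.75


# ---------------------------------------------------------------------------
# AP / mAP
# ---------------------------------------------------------------------------

class TestAveragePrecision:
    def test_perfect_detections(self):
        gts = [Box(0, 0, 10, 10, "spot"), Box(20, 20, 28, 28, "spot")]
        dets = [Box(0, 0, 10, 10, "spot", 0.9), Box(20, 20, 28, 28, "spot", 0.8)]
        assert average_precision(dets, gts) == pytest.approx(1.0)

    def test_no_detections(self):
        assert average_precision([], [Box(0, 0, 5, 5, "spot")]) == 0.0

    def test_single_detection_iou_062(self):
        """IoU ~0.615 passes thresholds {0.50, 0.55, 0.60} only -> AP = 0.30."""
        gt = [Box(0, 0, 10, 10, "spot")]
        det = [Box(0, 2, 10, 12, "spot", 0.9)]  # IoU = 80/120 = 0.6667
        # choose overlap with IoU in [0.60, 0.65): shift by 2.4 rows
        det = [Box(0.0, 2.4, 10.0, 12.4, "spot", 0.9)]
        iou = iou_boxes(det[0], gt[0])
        assert 0.60 <= iou < 0.65
        assert average_precision(det, gt) == pytest.approx(0.30)

    def test_matches_bruteforce_oracle_on_random_scenes(self, rng):
        for _ in range(60):
            n_imgs = rng.integers(1, 4)
            det_imgs = [_random_scene(rng) for _ in range(n_imgs)]
            gt_imgs = [_random_scene(rng, scored=False) for _ in range(n_imgs)]
            for label in ("spot", "eyespot"):
                if not any(g.label == label for img in gt_imgs for g in img):
                    continue
                mine = average_precision(det_imgs, gt_imgs, label=label)
                oracle = _ap_oracle(det_imgs, gt_imgs, label, DEFAULT_IOU_THRESHOLDS)
                assert mine == pytest.approx(oracle, abs=1e-9)

    def test_ap_nonincreasing_in_threshold(self, rng):
        det_imgs = [_random_scene(rng) for _ in range(3)]
        gt_imgs = [_random_scene(rng, scored=False) for _ in range(3)]
        if not any(g.label == "spot" for img in gt_imgs for g in img):
            gt_imgs[0].append(Box(0, 0, 5, 5, "spot"))
        prev = 1.0
        for thr in (0.5, 0.6, 0.7, 0.8, 0.9):
            ap = average_precision(det_imgs, gt_imgs, label="spot", iou_thresholds=[thr])
            assert ap <= prev + 1e-12
            prev = ap

    def test_map_is_unweighted_mean(self):
        assert mean_ap({"spot": 0.4, "eyespot": 0.8}) == pytest.approx(0.6)
        with pytest.raises(ValueError):
            mean_ap({})

    def test_ap_per_class_keys(self, rng):
        gt_imgs = [[Box(0, 0, 5, 5, "spot"), Box(8, 8, 14, 14, "eyespot")]]
        det_imgs = [[Box(0, 0, 5, 5, "spot", 0.9)]]
        per = ap_per_class(det_imgs, gt_imgs)
        assert set(per) == {"spot", "eyespot"}
        assert per["eyespot"] == 0.0


# ---------------------------------------------------------------------------
# segmentation metrics
# ---------------------------------------------------------------------------

class TestSegmentationMetrics:
    def test_perfect(self, rng):
        m = rng.integers(0, 3, (16, 16))
        assert segmentation_metrics(m, m, 3) == (1.0, 1.0, 1.0)

    def test_complement_binary(self):
        gt = np.array([[0, 1], [0, 1]])
        assert segmentation_metrics(1 - gt, gt, 2)[0] == 0.0

    def test_hand_counted_2x2(self):
        gt = np.array([[0, 0], [1, 1]])
        pred = np.array([[0, 1], [1, 1]])
        acc, f1, iou = segmentation_metrics(pred, gt, 2)
        assert acc == 0.75
        assert f1 == pytest.approx((2 / 3 + 4 / 5) / 2)
        assert iou == pytest.approx((1 / 2 + 2 / 3) / 2)

    def test_macro_f1_invariant_under_relabeling(self, rng):
        gt = rng.integers(0, 3, (20, 20))
        pred = rng.integers(0, 3, (20, 20))
        perm = np.array([2, 0, 1])
        _, f1a, ioua = segmentation_metrics(pred, gt, 3)
        _, f1b, ioub = segmentation_metrics(perm[pred], perm[gt], 3)
        assert f1a == pytest.approx(f1b)
        assert ioua == pytest.approx(ioub)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            segmentation_metrics(np.zeros((2, 2)), np.zeros((3, 3)), 2)


# ---------------------------------------------------------------------------
# area error statistics
# ---------------------------------------------------------------------------

class TestAreaErrorStats:
    def test_zero_error(self):
        s = area_error_stats([1.0, 2.0], [1.0, 2.0])
        assert s.relative_avg_error_pct == 0.0 and s.error_std == 0.0

    def test_hand_values(self):
        s = area_error_stats([1.0, 2.0], [1.1, 1.8])
        assert s.relative_avg_error_pct == pytest.approx(10.0)
        assert s.relative_error_std_pct == pytest.approx(0.0, abs=1e-9)
        assert s.avg_error == pytest.approx(0.15)
        assert s.n == 2

    def test_single_pair(self):
        s = area_error_stats([2.0], [2.5])
        assert s.relative_avg_error_pct == pytest.approx(25.0)
        assert s.error_std == 0.0

    def test_errors(self):
        with pytest.raises(ValueError):
            area_error_stats([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            area_error_stats([0.0], [1.0])
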