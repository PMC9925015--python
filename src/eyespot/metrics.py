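"""Detection and segmentation evaluation.

Detection quality is scored with COCO-style average precision: the area
under the precision–recall curve, averaged over IoU thresholds 0.50:0.05:0.95,
and mAP as the unweighted mean over classes.  Matching is greedy by
descending confidence; each ground-truth box may be matched at most once, so
duplicate detections of the same object count as false positives.

Segmentation is scored per pixel (accuracy, macro-F1, mean IoU), and area
measurements are compared with manual values as mean/std of absolute and
relative errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from .boxes import Box, iou_matrix

logger = logging.getLogger(__name__)

#: The ten IoU thresholds 0.50, 0.55, ..., 0.95.
DEFAULT_IOU_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))


def iou_boxes(a: Box, b: Box) -> float:
    """Intersection over union of two boxes; 0 when disjoint, 1 iff equal."""
    return float(iou_matrix(a.as_array(), b.as_array())[0, 0])


def precision(tp: int, fp: int) -> float:
    """TP / (TP + FP); defined as 1.0 when there are no detections at all."""
    return tp / (tp + fp) if (tp + fp) > 0 else 1.0


def recall(tp: int, fn: int) -> float:
    """TP / (TP + FN); defined as 1.0 when there is nothing to find."""
    return tp / (tp + fn) if (tp + fn) > 0 else 1.0


@dataclass
class MatchResult:
    """Per-class TP/FP/FN counts at one IoU threshold plus the scored
    detection list with match flags (descending score order).

    TN is undefined for detection (no negatives are enumerated) and is not
    recorded.
    """

    iou_threshold: float
    counts: Dict[str, dict] = field(default_factory=dict)
    flagged: list = field(default_factory=list)  # (score, label, is_tp)

    def tp(self, label: str) -> int:
        return self.counts.get(label, {"tp": 0})["tp"]

    def fp(self, label: str) -> int:
        return self.counts.get(label, {"fp": 0})["fp"]

    def fn(self, label: str) -> int:
        return self.counts.get(label, {"fn": 0})["fn"]


def _as_image_lists(seq):
    """Accept one image's box list or a per-image list of lists."""
    if len(seq) == 0:
        return [[]]
    if isinstance(seq[0], Box):
        return [list(seq)]
    return [list(s) for s in seq]


def _greedy_match_image(dets: Sequence[Box], gts: Sequence[Box], thr: float):
    """Greedy same-class matching in one image.

    Returns per-detection TP flags in descending-score order together with
    the sorted detections, plus the number of unmatched GTs.
    """
    order = sorted(range(len(dets)), key=lambda i: (-(dets[i].score or 0.0), i))
    gt_used = [False] * len(gts)
    flags = []
    for i in order:
        d = dets[i]
        best_j, best_iou = -1, 0.0
        for j, g in enumerate(gts):
            if gt_used[j] or g.label != d.label:
                continue
            iou = iou_boxes(d, g)
            if iou > best_iou:
                best_iou, best_j = iou, j
        is_tp = best_j >= 0 and best_iou >= thr
        if is_tp:
            gt_used[best_j] = True
        flags.append((d, is_tp))
    fn = sum(1 for u in gt_used if not u)
    return flags, fn


def match_detections(
    detections, gts, iou_threshold: float = 0.5
) -> MatchResult:
    """Match scored detections to ground truth at one IoU threshold.

    ``detections``/``gts`` are either one image's box lists or parallel
    per-image lists of lists.  A detection whose IoU with an unmatched
    same-class GT is >= the threshold is a TP; extra detections of an
    already-matched object are FPs; unmatched GTs are FNs.
    """
    det_imgs = _as_image_lists(detections)
    gt_imgs = _as_image_lists(gts)
    if len(det_imgs) != len(gt_imgs):
        raise ValueError("detections and ground truth must cover the same images")
    result = MatchResult(iou_threshold=iou_threshold)
    labels = {b.label for img in det_imgs for b in img} | {
        b.label for img in gt_imgs for b in img
    }
    for lbl in labels:
        result.counts[lbl] = {"tp": 0, "fp": 0, "fn": 0}
    for dets, gt in zip(det_imgs, gt_imgs):
        flags, _ = _greedy_match_image(dets, gt, iou_threshold)
        matched_per_label: Dict[str, int] = {}
        for d, is_tp in flags:
            key = "tp" if is_tp else "fp"
            result.counts[d.label][key] += 1
            result.flagged.append((d.score or 0.0, d.label, is_tp))
            if is_tp:
                matched_per_label[d.label] = matched_per_label.get(d.label, 0) + 1
        for lbl in {b.label for b in gt}:
            n_gt = sum(1 for b in gt if b.label == lbl)
            result.counts[lbl]["fn"] += n_gt - matched_per_label.get(lbl, 0)
    result.flagged.sort(key=lambda t: -t[0])
    return result


def _ap_single_threshold(det_imgs, gt_imgs, label: str, thr: float) -> float:
    n_gt = sum(sum(1 for b in img if b.label == label) for img in gt_imgs)
    if n_gt == 0:
        raise ValueError(f"no ground truth of class {label!r}")
    scored = []  # (score, image index, tp flag)
    for idx, (dets, gt) in enumerate(zip(det_imgs, gt_imgs)):
        dets_l = [d for d in dets if d.label == label]
        gt_l = [g for g in gt if g.label == label]
        flags, _ = _greedy_match_image(dets_l, gt_l, thr)
        for rank, (d, is_tp) in enumerate(flags):
            scored.append((-(d.score or 0.0), idx, rank, is_tp))
    if not scored:
        return 0.0
    scored.sort()
    tp = np.cumsum([s[3] for s in scored])
    fp = np.cumsum([not s[3] for s in scored])
    rec = tp / n_gt
    prec = tp / (tp + fp)
    # precision envelope + all-point interpolation of the area under PR
    prec_env = np.maximum.accumulate(prec[::-1])[::-1]
    rec_prev = np.concatenate([[0.0], rec[:-1]])
    return float(np.sum((rec - rec_prev) * prec_env))


def average_precision(
    detections,
    gts,
    label: Optional[str] = None,
    iou_thresholds: Sequence[float] = DEFAULT_IOU_THRESHOLDS,
) -> float:
    """AP of one class: mean over IoU thresholds of the PR-curve area.

    When ``label`` is None the ground truth must contain a single class.
    """
    det_imgs = _as_image_lists(detections)
    gt_imgs = _as_image_lists(gts)
    if label is None:
        labels = {b.label for img in gt_imgs for b in img}
        if len(labels) != 1:
            raise ValueError(f"ambiguous class for AP: ground truth has {sorted(labels)}")
        label = labels.pop()
    return float(
        np.mean([_ap_single_threshold(det_imgs, gt_imgs, label, t) for t in iou_thresholds])
    )


def ap_per_class(
    detections, gts, iou_thresholds: Sequence[float] = DEFAULT_IOU_THRESHOLDS
) -> Dict[str, float]:
    """AP for every class present in the ground truth."""
    gt_imgs = _as_image_lists(gts)
    labels = sorted({b.label for img in gt_imgs for b in img})
    return {
        lbl: average_precision(detections, gts, label=lbl, iou_thresholds=iou_thresholds)
        for lbl in labels
    }


def mean_ap(per_class: Dict[str, float]) -> float:
    """Unweighted mean of per-class APs."""
    if not per_class:
        raise ValueError("no classes to average")
    return float(np.mean(list(per_class.values())))


# ---------------------------------------------------------------------------
# Segmentation metrics
# ---------------------------------------------------------------------------

def segmentation_metrics(
    pred: np.ndarray, gt: np.ndarray, n_classes: int
) -> tuple[float, float, float]:
    """Pixel accuracy, macro-F1 and mean IoU from the confusion matrix.

    A class absent from both prediction and ground truth contributes a
    perfect score (F1 = IoU = 1), so comparing identical masks always yields
    (1, 1, 1) regardless of which labels appear.
    """
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    if pred.max(initial=0) >= n_classes or gt.max(initial=0) >= n_classes:
        raise ValueError("labels exceed n_classes")
    cm = np.bincount(
        (gt.ravel().astype(np.int64) * n_classes + pred.ravel()), minlength=n_classes**2
    ).reshape(n_classes, n_classes)
    total = cm.sum()
    accuracy = float(np.trace(cm) / total)
    f1s, ious = [], []
    for c in range(n_classes):
        tp = cm[c, c]
        fp = cm[:, c].sum() - tp
        fn = cm[c, :].sum() - tp
        if tp + fp + fn == 0:
            f1s.append(1.0)
            ious.append(1.0)
            continue
        f1s.append(2 * tp / (2 * tp + fp + fn))
        ious.append(tp / (tp + fp + fn))
    return accuracy, float(np.mean(f1s)), float(np.mean(ious))


# ---------------------------------------------------------------------------
# Area error statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AreaErrorStats:
    """Mean and spread of |automatic − manual| area errors.

    Relative errors are percentages of the manual value; absolute errors are
    in the unit of the inputs (mm² in the pipeline).  The std is the
    population standard deviation unless ``sample_std`` was requested.
    """

    relative_avg_error_pct: float
    relative_error_std_pct: float
    avg_error: float
    error_std: float
    n: int
    signed_relative_error_std_pct: float = 0.0

    def to_dict(self) -> dict:
        return {
            "relative_avg_error_pct": self.relative_avg_error_pct,
            "relative_error_std_pct": self.relative_error_std_pct,
            "avg_error": self.avg_error,
            "error_std": self.error_std,
            "n": self.n,
            "signed_relative_error_std_pct": self.signed_relative_error_std_pct,
        }


def area_error_stats(
    manual: Sequence[float], auto: Sequence[float], sample_std: bool = False
) -> AreaErrorStats:
    """Compare automatic with manual area measurements pair by pair."""
    manual = np.asarray(manual, dtype=float)
    auto = np.asarray(auto, dtype=float)
    if manual.shape != auto.shape:
        raise ValueError("manual and automatic sequences differ in length")
    if manual.size == 0:
        raise ValueError("need at least one pair")
    if np.any(manual <= 0):
        raise ValueError("manual areas must be positive")
    ddof = 1 if (sample_std and manual.size > 1) else 0
    abs_err = np.abs(auto - manual)
    rel = 100.0 * abs_err / manual
    rel_signed = 100.0 * (auto - manual) / manual
    return AreaErrorStats(
        relative_avg_error_pct=float(rel.mean()),
        relative_error_std_pct=float(rel.std(ddof=ddof)),
        avg_error=float(abs_err.mean()),
        error_std=float(abs_err.std(ddof=ddof)),
        n=int(manual.size),
        signed_relative_error_std_pct=float(rel_signed.std(ddof=ddof)),
    )
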