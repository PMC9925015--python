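"""Independent brute-force oracles shared by the unit and acceptance tests.

These deliberately re-derive quantities with the plainest possible code
(python loops, pixel rasterization) so they stay independent of the
vectorized implementations they check.
"""

import numpy as np

from eyespot.boxes import Box
from eyespot.metrics import iou_boxes


def disc_pixel_count(shape, center, a, b, angle):
    """Count pixels whose center lies inside a rotated ellipse (python loop)."""
    count = 0
    ca, sa = np.cos(angle), np.sin(angle)
    for r in range(shape[0]):
        for c in range(shape[1]):
            dx, dy = c - center[1], r - center[0]
            u = dx * ca + dy * sa
            v = -dx * sa + dy * ca
            if (u / a) ** 2 + (v / b) ** 2 <= 1.0:
                count += 1
    return count


def iou_raster(a: Box, b: Box) -> float:
    """Pixel-count IoU for integer-coordinate boxes."""
    W = int(max(a.x_max, b.x_max)) + 1
    H = int(max(a.y_max, b.y_max)) + 1
    ra = np.zeros((H, W), bool)
    rb = np.zeros((H, W), bool)
    ra[int(a.y_min) : int(a.y_max), int(a.x_min) : int(a.x_max)] = True
    rb[int(b.y_min) : int(b.y_max), int(b.x_min) : int(b.x_max)] = True
    union = (ra | rb).sum()
    return (ra & rb).sum() / union if union else 0.0


def _is_int(a: Box, b: Box) -> bool:
    return all(
        float(v).is_integer()
        for box in (a, b)
        for v in (box.x_min, box.y_min, box.x_max, box.y_max)
    )


def ap_bruteforce(det_imgs, gt_imgs, label, thresholds):
    """Brute-force AP: per threshold, walk detections in score order, greedily
    match, then sum precision-envelope areas point by point."""
    aps = []
    for thr in thresholds:
        n_gt = 0
        scored = []
        for img_idx, (dets, gts) in enumerate(zip(det_imgs, gt_imgs)):
            gts_l = [g for g in gts if g.label == label]
            n_gt += len(gts_l)
            used = [False] * len(gts_l)
            dets_l = sorted([d for d in dets if d.label == label], key=lambda d: -d.score)
            for rank, d in enumerate(dets_l):
                best, best_iou = -1, 0.0
                for j, g in enumerate(gts_l):
                    if used[j]:
                        continue
                    iou = iou_raster(d, g) if _is_int(d, g) else iou_boxes(d, g)
                    if iou > best_iou:
                        best_iou, best = iou, j
                tp = best >= 0 and best_iou >= thr
                if tp:
                    used[best] = True
                scored.append((-d.score, img_idx, rank, tp))
        scored.sort()
        tps = [s[3] for s in scored]
        if n_gt == 0 or not tps:
            aps.append(0.0)
            continue
        precisions = []
        t = 0
        for k, f in enumerate(tps, start=1):
            t += f
            precisions.append(t / k)
        ap = 0.0
        for k, f in enumerate(tps):
            if f:
                ap += max(precisions[k:]) / n_gt
        aps.append(ap)
    return float(np.mean(aps))


def random_box_scene(rng, n_max=10, labels=("spot", "eyespot"), scored=True):
    """A random list of integer boxes for matching/AP oracle tests."""
    n = rng.integers(0, n_max + 1)
    boxes = []
    for _ in range(n):
        x = rng.integers(0, 40)
        y = rng.integers(0, 40)
        w = rng.integers(2, 20)
        h = rng.integers(2, 20)
        boxes.append(
            Box(
                float(x), float(y), float(x + w), float(y + h),
                label=labels[rng.integers(len(labels))],
                score=float(np.round(rng.random(), 3)) if scored else None,
            )
        )
    return boxes
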