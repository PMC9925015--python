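"""Single-stage anchor-based detection of spots and eyespots.

A desk-scale stand-in for heavyweight one-stage detectors (RetinaNet-style):
a small strided convolutional backbone produces one feature level, on which
per-anchor classification (trained with the focal loss, to counter the
foreground/background anchor imbalance) and box regression heads predict
scored boxes.  Duplicates are removed by class-wise greedy non-maximum
suppression with an IoU threshold of 0.3.

Three class schemes are supported: ``two_class`` (spot vs eyespot),
``one_class_all`` (any pattern element) and ``one_class_marginal``
(marginal eyespots only).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from skimage import color as skcolor
from skimage.transform import resize as _sk_resize

from . import nn
from .boxes import Box, boxes_to_array, iou_matrix
from .nn import TrainConfig
from .synthetic import SceneGroundTruth

EPS = 1e-7

_SCHEME_CLASSES = {
    "two_class": ("spot", "eyespot"),
    "one_class_all": ("element",),
    "one_class_marginal": ("marginal_eyespot",),
}


@dataclass(frozen=True)
class ClassScheme:
    """Which detection task is being trained; fixes the class vocabulary."""

    mode: str = "two_class"

    def __post_init__(self) -> None:
        if self.mode not in _SCHEME_CLASSES:
            raise ValueError(f"unknown scheme {self.mode!r}")

    @property
    def class_names(self) -> tuple[str, ...]:
        return _SCHEME_CLASSES[self.mode]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def map_gt_boxes(self, gt: SceneGroundTruth) -> list[Box]:
        """Ground-truth boxes relabelled for this scheme.

        ``one_class_marginal`` keeps only marginal eyespots; everything else
        becomes background.
        """
        out = []
        for spec, box in zip(gt.elements, gt.boxes):
            if self.mode == "two_class":
                out.append(replace(box, label=spec.kind))
            elif self.mode == "one_class_all":
                out.append(replace(box, label="element"))
            elif spec.kind == "eyespot" and spec.subtype == "marginal":
                out.append(replace(box, label="marginal_eyespot"))
        return out


@dataclass
class DetectorConfig:
    input_size: int = 256
    stride: int = 16
    anchor_scales: tuple[float, ...] = (12.0, 17.0, 24.0, 34.0, 48.0)
    aspect_ratios: tuple[float, ...] = (1.0,)
    pos_iou: float = 0.5
    neg_iou: float = 0.4
    focal_alpha: float = 0.25
    focal_gamma: float = 2.0
    score_threshold: float = 0.5
    nms_iou_threshold: float = 0.3
    hue_amplitude: float = 0.03
    sat_range: tuple[float, float] = (0.8, 1.2)
    val_range: tuple[float, float] = (0.8, 1.2)
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self) -> None:
        if self.input_size % self.stride != 0:
            raise ValueError("stride must divide input_size")
        if not (0.0 < self.nms_iou_threshold < 1.0):
            raise ValueError("nms_iou_threshold must lie in (0, 1)")
        if self.pos_iou <= self.neg_iou:
            raise ValueError("pos_iou must exceed neg_iou")
        if len(self.anchor_scales) * len(self.aspect_ratios) < 1:
            raise ValueError("need at least one anchor per location")

    @property
    def anchors_per_cell(self) -> int:
        return len(self.anchor_scales) * len(self.aspect_ratios)


# ---------------------------------------------------------------------------
# Anchors and target assignment
# ---------------------------------------------------------------------------

def generate_anchors(config: DetectorConfig, image_size: tuple[int, int]) -> np.ndarray:
    """(A, 4) anchor boxes centered on feature-map cell centers, clipped.

    A = (H / stride) * (W / stride) * anchors_per_cell; the per-cell order is
    scales x ratios, row-major over cells.
    """
    h, w = image_size
    s = config.stride
    if h % s or w % s:
        raise ValueError("stride must divide the image size")
    cy = (np.arange(h // s) + 0.5) * s
    cx = (np.arange(w // s) + 0.5) * s
    shapes = []
    for scale in config.anchor_scales:
        for ratio in config.aspect_ratios:
            shapes.append((scale * np.sqrt(ratio), scale / np.sqrt(ratio)))
    anchors = np.empty((h // s, w // s, len(shapes), 4))
    for k, (aw, ah) in enumerate(shapes):
        anchors[:, :, k, 0] = cx[None, :] - aw / 2
        anchors[:, :, k, 1] = cy[:, None] - ah / 2
        anchors[:, :, k, 2] = cx[None, :] + aw / 2
        anchors[:, :, k, 3] = cy[:, None] + ah / 2
    anchors = anchors.reshape(-1, 4)
    anchors[:, 0::2] = anchors[:, 0::2].clip(0, w)
    anchors[:, 1::2] = anchors[:, 1::2].clip(0, h)
    return anchors


def _encode(anchors: np.ndarray, gt: np.ndarray) -> np.ndarray:
    """Normalized center/size offsets from anchors to target boxes."""
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    acx = anchors[:, 0] + aw / 2
    acy = anchors[:, 1] + ah / 2
    gw = gt[:, 2] - gt[:, 0]
    gh = gt[:, 3] - gt[:, 1]
    gcx = gt[:, 0] + gw / 2
    gcy = gt[:, 1] + gh / 2
    return np.stack(
        [(gcx - acx) / aw, (gcy - acy) / ah, np.log(gw / aw), np.log(gh / ah)], axis=1
    )


def _decode(anchors: np.ndarray, deltas: np.ndarray) -> np.ndarray:
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    acx = anchors[:, 0] + aw / 2
    acy = anchors[:, 1] + ah / 2
    cx = acx + deltas[:, 0] * aw
    cy = acy + deltas[:, 1] * ah
    w = aw * np.exp(np.clip(deltas[:, 2], -4, 4))
    h = ah * np.exp(np.clip(deltas[:, 3], -4, 4))
    return np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=1)


def assign_targets(
    anchors: np.ndarray,
    gt_boxes: Sequence[Box],
    class_names: Sequence[str],
    pos_iou: float = 0.5,
    neg_iou: float = 0.4,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-anchor class target and box regression target.

    Class targets: ``0`` background, ``1..C`` positive (class index + 1),
    ``-1`` ignored (IoU between the thresholds).  Each GT is force-matched to
    its highest-IoU anchor even below ``pos_iou``, so no object goes
    unsupervised.
    """
    if pos_iou <= neg_iou:
        raise ValueError("pos_iou must exceed neg_iou")
    a = np.asarray(anchors, dtype=float)
    cls = np.zeros(len(a), dtype=np.int64)
    reg = np.zeros((len(a), 4), dtype=np.float64)
    if len(gt_boxes) == 0:
        return cls, reg
    g = boxes_to_array(gt_boxes)
    labels = np.array([list(class_names).index(b.label) + 1 for b in gt_boxes])
    iou = iou_matrix(a, g)  # (A, G)
    best_gt = iou.argmax(axis=1)
    best_iou = iou[np.arange(len(a)), best_gt]
    cls[best_iou >= pos_iou] = labels[best_gt[best_iou >= pos_iou]]
    cls[(best_iou < pos_iou) & (best_iou >= neg_iou)] = -1
    # forced match: every GT claims its best anchor
    forced = iou.argmax(axis=0)
    cls[forced] = labels
    best_gt[forced] = np.arange(len(g))
    pos = cls > 0
    reg[pos] = _encode(a[pos], g[best_gt[pos]])
    return cls, reg


# ---------------------------------------------------------------------------
# Focal loss
# ---------------------------------------------------------------------------

def focal_loss(
    pred_prob: np.ndarray, target: np.ndarray, alpha: float = 0.25, gamma: float = 2.0
) -> float:
    """Mean over anchors of -alpha_t (1 - p_t)^gamma log(p_t).

    ``pred_prob`` is the predicted probability of the positive class,
    ``target`` is binary; ``alpha_t`` is ``alpha`` for positives and
    ``1 - alpha`` for negatives.  With gamma = 0 and alpha_t = 1 this reduces
    to the binary cross-entropy.
    """
    p = np.clip(np.asarray(pred_prob, dtype=np.float64), EPS, 1.0 - EPS)
    t = np.asarray(target, dtype=np.float64)
    p_t = np.where(t > 0, p, 1.0 - p)
    alpha_t = np.where(t > 0, alpha, 1.0 - alpha)
    return float(np.mean(-alpha_t * (1.0 - p_t) ** gamma * np.log(p_t)))


def _focal_value_and_grad(logits, targets, alpha, gamma, norm, mask=None):
    """Focal loss summed over (unmasked) entries / norm, with gradient
    w.r.t. logits."""
    p = 1.0 / (1.0 + np.exp(-logits.astype(np.float64)))
    p = np.clip(p, EPS, 1.0 - EPS)
    t = targets
    p_t = np.where(t > 0, p, 1.0 - p)
    alpha_t = np.where(t > 0, alpha, 1.0 - alpha)
    one_m = 1.0 - p_t
    elem = -alpha_t * one_m**gamma * np.log(p_t)
    # d/dp_t of -(1-p_t)^g log p_t = g(1-p_t)^(g-1) log p_t - (1-p_t)^g / p_t
    dl_dpt = alpha_t * (gamma * one_m ** max(gamma - 1.0, 0.0) * np.log(p_t) - one_m**gamma / p_t)
    dpt_dz = np.where(t > 0, 1.0, -1.0) * p * (1.0 - p)
    grad = dl_dpt * dpt_dz
    if mask is not None:
        elem = elem * mask
        grad = grad * mask
    return float(elem.sum() / norm), (grad / norm).astype(nn.DTYPE)


def _smooth_l1_value_and_grad(pred, target, norm):
    d = pred.astype(np.float64) - target
    ad = np.abs(d)
    loss = float(np.sum(np.where(ad < 1.0, 0.5 * d**2, ad - 0.5)) / norm)
    grad = np.where(ad < 1.0, d, np.sign(d)) / norm
    return loss, grad.astype(nn.DTYPE)


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def augment(
    image: np.ndarray,
    boxes: Sequence[Box],
    rng: Optional[np.random.Generator] = None,
    hue_amplitude: float = 0.03,
    sat_range: tuple[float, float] = (0.8, 1.2),
    val_range: tuple[float, float] = (0.8, 1.2),
    flip_prob: float = 0.5,
    force_flip: Optional[bool] = None,
) -> tuple[np.ndarray, list[Box]]:
    """Random HSV distortion plus horizontal flipping.

    A flip maps a box to ``x'_min = W - x_max``, ``x'_max = W - x_min``; the
    pixel array is reversed along columns, so flipping twice is the identity.
    """
    rng = rng or np.random.default_rng(0)
    out = np.asarray(image, dtype=np.float64)
    dh = rng.uniform(-hue_amplitude, hue_amplitude)
    ds = rng.uniform(*sat_range)
    dv = rng.uniform(*val_range)
    if dh != 0.0 or ds != 1.0 or dv != 1.0:
        hsv = skcolor.rgb2hsv(out)
        hsv[..., 0] = (hsv[..., 0] + dh) % 1.0
        hsv[..., 1] = np.clip(hsv[..., 1] * ds, 0.0, 1.0)
        hsv[..., 2] = np.clip(hsv[..., 2] * dv, 0.0, 1.0)
        out = skcolor.hsv2rgb(hsv)
    flip = force_flip if force_flip is not None else bool(rng.random() < flip_prob)
    new_boxes = list(boxes)
    if flip:
        w = out.shape[1]
        out = out[:, ::-1]
        new_boxes = [
            replace(b, x_min=w - b.x_max, x_max=w - b.x_min) for b in boxes
        ]
    return np.clip(out, 0.0, 1.0).astype(np.float32), new_boxes


# ---------------------------------------------------------------------------
# Letterboxing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Letterbox:
    scale: float
    pad_x: float
    pad_y: float

    def to_model(self, b: Box) -> Box:
        return replace(
            b,
            x_min=b.x_min * self.scale + self.pad_x,
            y_min=b.y_min * self.scale + self.pad_y,
            x_max=b.x_max * self.scale + self.pad_x,
            y_max=b.y_max * self.scale + self.pad_y,
        )

    def to_image(self, b: Box) -> Box:
        return replace(
            b,
            x_min=(b.x_min - self.pad_x) / self.scale,
            y_min=(b.y_min - self.pad_y) / self.scale,
            x_max=(b.x_max - self.pad_x) / self.scale,
            y_max=(b.y_max - self.pad_y) / self.scale,
        )


def letterbox_image(image: np.ndarray, size: int) -> tuple[np.ndarray, Letterbox]:
    """Aspect-preserving resize onto a gray square canvas of side ``size``."""
    h, w = image.shape[:2]
    scale = size / max(h, w)
    nh, nw = int(round(h * scale)), int(round(w * scale))
    if (nh, nw) != (h, w):
        resized = _sk_resize(image, (nh, nw), order=1, anti_aliasing=False, preserve_range=True)
    else:
        resized = image
    canvas = np.full((size, size, 3), 0.5, dtype=np.float32)
    pad_y = (size - nh) // 2
    pad_x = (size - nw) // 2
    canvas[pad_y : pad_y + nh, pad_x : pad_x + nw] = resized
    return canvas, Letterbox(scale=scale, pad_x=float(pad_x), pad_y=float(pad_y))


# ---------------------------------------------------------------------------
# The reference mini-detector
# ---------------------------------------------------------------------------

class MiniDetector(nn.Layer):
    """Small conv trunk (log2(stride) stride-2 blocks, one feature level)
    plus classification and box-regression heads."""

    def __init__(self, config: DetectorConfig, scheme: ClassScheme,
                 rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng(config.train.seed)
        self.config = config
        self.scheme = scheme
        a, c = config.anchors_per_cell, scheme.n_classes
        n_down = int(np.log2(config.stride))
        if 2**n_down != config.stride or n_down < 2:
            raise ValueError("stride must be a power of two >= 4")
        widths = (16, 32, 64, 96, 128, 128)[:n_down]
        trunk = []
        cin = 3
        for wd in widths:
            trunk += [nn.Conv2d(cin, wd, 3, stride=2, rng=rng), nn.BatchNorm2d(wd), nn.ReLU()]
            cin = wd
        trunk += [nn.Conv2d(cin, cin, 3, rng=rng), nn.BatchNorm2d(cin), nn.ReLU()]
        self.trunk = nn.Sequential(*trunk)
        # bias init so initial foreground probability is ~0.1 (focal-loss prior)
        self.cls_head = nn.Conv2d(cin, a * c, 3, rng=rng, bias_init=-2.2)
        self.box_head = nn.Conv2d(cin, a * 4, 3, rng=rng)

    @property
    def layers(self):
        return [self.trunk, self.cls_head, self.box_head]

    def parameters(self):
        return [p for l in self.layers for p in l.parameters()]

    def buffers(self):
        return [b for l in self.layers for b in l.buffers()]

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Input (N, 3, H, W); returns per-anchor class logits (N, A, C) and
        box deltas (N, A, 4) in the anchor order of :func:`generate_anchors`."""
        n = x.shape[0]
        f = self.trunk.forward(np.ascontiguousarray(x.transpose(1, 0, 2, 3)))
        a, c = self.config.anchors_per_cell, self.scheme.n_classes
        cls = self.cls_head.forward(f)  # (A*C, N, hf, wf)
        box = self.box_head.forward(f)
        hf, wf = cls.shape[2], cls.shape[3]
        cls = cls.reshape(a, c, n, hf, wf).transpose(2, 3, 4, 0, 1).reshape(n, -1, c)
        box = box.reshape(a, 4, n, hf, wf).transpose(2, 3, 4, 0, 1).reshape(n, -1, 4)
        self._shape = (n, a, c, hf, wf)
        return cls, box

    def backward(self, d_cls: np.ndarray, d_box: np.ndarray) -> np.ndarray:
        n, a, c, hf, wf = self._shape
        d_cls = d_cls.reshape(n, hf, wf, a, c).transpose(3, 4, 0, 1, 2).reshape(a * c, n, hf, wf)
        d_box = d_box.reshape(n, hf, wf, a, 4).transpose(3, 4, 0, 1, 2).reshape(a * 4, n, hf, wf)
        df = self.cls_head.backward(np.ascontiguousarray(d_cls)) + self.box_head.backward(
            np.ascontiguousarray(d_box)
        )
        return self.trunk.backward(df)


def build_detector(config: DetectorConfig, scheme: ClassScheme) -> MiniDetector:
    return MiniDetector(config, scheme)


def train_detector(
    train_scenes: Sequence[tuple[np.ndarray, Sequence[Box]]],
    val_scenes: Sequence[tuple[np.ndarray, Sequence[Box]]],
    scheme: ClassScheme,
    config: DetectorConfig,
    augment_data: bool = True,
) -> tuple[MiniDetector, nn.TrainingLog]:
    """Train the mini-detector on (image, gt boxes) pairs.

    Images are float RGB in [0, 1] (already /255-normalized); boxes use the
    scheme's class names.  Loss = focal classification + smooth-L1 box
    regression, both normalized by the number of positive anchors.
    """
    if len(train_scenes) == 0:
        raise ValueError("empty training manifest")
    size = config.input_size
    model = MiniDetector(config, scheme)
    anchors = generate_anchors(config, (size, size))
    opt = nn.Adam(model.parameters(), config.train)
    aug_rng = np.random.default_rng(config.train.seed + 104729)
    cnames = scheme.class_names
    a_count, n_cls = len(anchors), scheme.n_classes

    def _prep(image, boxes, do_aug):
        if do_aug:
            image, boxes = augment(
                image, boxes, rng=aug_rng,
                hue_amplitude=config.hue_amplitude,
                sat_range=config.sat_range, val_range=config.val_range,
            )
        if image.shape[0] != size or image.shape[1] != size:
            image, lb = letterbox_image(image, size)
            boxes = [lb.to_model(b) for b in boxes]
        cls_t, reg_t = assign_targets(anchors, boxes, cnames, config.pos_iou, config.neg_iou)
        return np.moveaxis(image.astype(np.float32), -1, 0), cls_t, reg_t

    def _batch_loss(batch, train_mode):
        xs, clss, regs = zip(*batch)
        x = np.stack(xs)
        cls_t = np.stack(clss)  # (N, A)
        reg_t = np.stack(regs)  # (N, A, 4)
        nn.set_training(model, train_mode)
        cls_logits, box_pred = model.forward(x)
        valid = cls_t >= 0
        pos = cls_t > 0
        n_pos = max(1, int(pos.sum()))
        onehot = np.zeros_like(cls_logits)
        ii, jj = np.nonzero(pos)
        onehot[ii, jj, cls_t[ii, jj] - 1] = 1.0
        cls_loss, d_cls = _focal_value_and_grad(
            cls_logits, onehot, config.focal_alpha, config.focal_gamma, n_pos,
            mask=valid[..., None].astype(np.float64),
        )
        box_loss, d_box = _smooth_l1_value_and_grad(box_pred[pos], reg_t[pos], n_pos)
        d_box_full = np.zeros_like(box_pred)
        d_box_full[pos] = d_box
        return cls_loss + box_loss, d_cls, d_box_full

    prepped_train = [_prep(img, bx, False) for img, bx in train_scenes]
    prepped_val = [_prep(img, bx, False) for img, bx in val_scenes]

    def step_fn(idx):
        if augment_data:
            batch = [_prep(*train_scenes[i], True) for i in idx]
        else:
            batch = [prepped_train[i] for i in idx]
        loss, d_cls, d_box = _batch_loss(batch, True)
        opt.zero_grad()
        model.backward(d_cls, d_box)
        opt.step()
        return loss

    def val_fn():
        losses = []
        bs = config.train.batch_size
        for start in range(0, len(prepped_val), bs):
            chunk = prepped_val[start : start + bs]
            loss, _, _ = _batch_loss(chunk, False)
            losses.append(loss * len(chunk))
        return float(np.sum(losses) / len(prepped_val))

    log = nn.run_training(
        model, step_fn, val_fn if len(val_scenes) else None, len(train_scenes), config.train
    )
    nn.set_training(model, False)
    return model, log


def detect(
    model: MiniDetector, image: np.ndarray, score_threshold: Optional[float] = None
) -> list[Box]:
    """Scored boxes above the threshold, in original image coordinates.

    NMS is *not* applied here; pass the result through :func:`nms`.
    """
    config = model.config
    thr = config.score_threshold if score_threshold is None else score_threshold
    h, w = image.shape[:2]
    size = config.input_size
    lb = None
    if (h, w) != (size, size):
        image, lb = letterbox_image(image, size)
    nn.set_training(model, False)
    x = np.moveaxis(image.astype(np.float32), -1, 0)[None]
    cls_logits, box_pred = model.forward(x)
    probs = 1.0 / (1.0 + np.exp(-cls_logits[0]))  # (A, C)
    anchors = generate_anchors(config, (size, size))
    decoded = _decode(anchors, box_pred[0].astype(np.float64))
    out: list[Box] = []
    for a_idx, c_idx in zip(*np.nonzero(probs >= thr)):
        x1, y1, x2, y2 = decoded[a_idx]
        if x2 - x1 < 1e-3 or y2 - y1 < 1e-3:
            continue
        b = Box(
            x_min=float(x1), y_min=float(y1), x_max=float(x2), y_max=float(y2),
            label=model.scheme.class_names[c_idx], score=float(min(1.0, probs[a_idx, c_idx])),
        )
        if lb is not None:
            b = lb.to_image(b)
        try:
            b = b.clipped(w, h)
        except ValueError:
            continue
        out.append(b)
    out.sort(key=lambda b: -b.score)
    return out


def nms(boxes: Sequence[Box], iou_threshold: float = 0.3, class_wise: bool = True) -> list[Box]:
    """Greedy non-maximum suppression by descending score.

    A box is suppressed iff its IoU with an already kept box of the same
    class exceeds the threshold.
    """
    order = sorted(boxes, key=lambda b: -(b.score if b.score is not None else 1.0))
    kept: list[Box] = []
    for b in order:
        suppressed = False
        for k in kept:
            if class_wise and k.label != b.label:
                continue
            if iou_matrix(b.as_array(), k.as_array())[0, 0] > iou_threshold:
                suppressed = True
                break
        if not suppressed:
            kept.append(b)
    return kept


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_detector(path, model: MiniDetector) -> None:
    cfg = {
        "scheme": model.scheme.mode,
        "input_size": model.config.input_size,
        "stride": model.config.stride,
        "anchor_scales": list(model.config.anchor_scales),
        "aspect_ratios": list(model.config.aspect_ratios),
        "pos_iou": model.config.pos_iou,
        "neg_iou": model.config.neg_iou,
        "focal_alpha": model.config.focal_alpha,
        "focal_gamma": model.config.focal_gamma,
        "score_threshold": model.config.score_threshold,
        "nms_iou_threshold": model.config.nms_iou_threshold,
        "train": vars(model.config.train),
    }
    state = nn.snapshot(model)
    np.savez(
        str(path),
        config=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8),
        **{f"arr_{i}": a for i, a in enumerate(state)},
    )


def load_detector(path) -> MiniDetector:
    with np.load(str(path)) as data:
        cfg = json.loads(bytes(data["config"]).decode())
        scheme = ClassScheme(cfg.pop("scheme"))
        train = TrainConfig(**cfg.pop("train"))
        cfg["anchor_scales"] = tuple(cfg["anchor_scales"])
        cfg["aspect_ratios"] = tuple(cfg["aspect_ratios"])
        config = DetectorConfig(train=train, **cfg)
        model = MiniDetector(config, scheme)
        state = [data[f"arr_{i}"] for i in range(len(data.files) - 1)]
    nn.restore(model, state)
    nn.set_training(model, False)
    return model
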