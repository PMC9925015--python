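"""U-Net semantic segmentation of eyespot crops.

Two operating modes share one architecture: *three-class* (background /
rings / center, labels 0/1/2) and *two-class* (everything-else / rings,
labels 0/1).  Training minimizes categorical cross-entropy, optionally
weighted per class (WCCE) to counter the extreme pixel imbalance of the
small white center.  Class weights follow the internal label order
(background, rings, center): crops default to (1, 1.75) / (1, 2, 25), the
whole-wing baseline to (1, 50) / (1, 600, 25).

The reference network is a reduced U-Net: encoder blocks of two 3x3
convolutions with BatchNorm/ReLU and 2x2 max pooling, a symmetric decoder
using 1x1 channel reduction, nearest-neighbor upsampling, skip
concatenation and one 3x3 convolution per stage, and a 1x1 classification
head with softmax.  Default depth 4, base width 16.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skimage.transform import resize as _sk_resize

from . import nn
from .nn import TrainConfig

EPS = 1e-7


def default_class_weights(n_classes: int, whole_wing: bool = False) -> tuple[float, ...]:
    """WCCE weights in internal label order (background, rings[, center])."""
    if n_classes == 2:
        return (1.0, 50.0) if whole_wing else (1.0, 1.75)
    if n_classes == 3:
        return (1.0, 600.0, 25.0) if whole_wing else (1.0, 2.0, 25.0)
    raise ValueError("n_classes must be 2 or 3")


@dataclass
class SegmenterConfig:
    n_classes: int = 3
    input_size: int = 128  # whole-wing baseline uses 640
    base_width: int = 16
    depth: int = 4
    loss: str = "wcce"  # "cce" | "wcce"
    class_weights: Optional[tuple[float, ...]] = None
    whole_wing: bool = False
    augment: bool = False
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self) -> None:
        if self.n_classes not in (2, 3):
            raise ValueError("n_classes must be 2 or 3")
        if self.loss not in ("cce", "wcce"):
            raise ValueError("loss must be 'cce' or 'wcce'")
        if self.input_size % (2**self.depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^depth = {2**self.depth}"
            )
        if self.class_weights is None:
            if self.loss == "wcce":
                self.class_weights = default_class_weights(self.n_classes, self.whole_wing)
            else:
                self.class_weights = (1.0,) * self.n_classes
        self.class_weights = tuple(float(w) for w in self.class_weights)
        if len(self.class_weights) != self.n_classes:
            raise ValueError("class_weights length must equal n_classes")
        if any(w <= 0 for w in self.class_weights):
            raise ValueError("class_weights must be positive")


class UNet(nn.Layer):
    """Encoder-decoder with skip connections; output = per-pixel logits."""

    def __init__(self, config: SegmenterConfig, rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng(config.train.seed)
        self.config = config
        b, d = config.base_width, config.depth
        chans = [b * 2**i for i in range(d + 1)]
        self.enc, self.pools, self.reduces, self.ups, self.dec = [], [], [], [], []
        cin = 3
        for i in range(d):
            self.enc.append(
                nn.Sequential(
                    nn.Conv2d(cin, chans[i], 3, rng=rng),
                    nn.BatchNorm2d(chans[i]),
                    nn.ReLU(),
                    nn.Conv2d(chans[i], chans[i], 3, rng=rng),
                    nn.BatchNorm2d(chans[i]),
                    nn.ReLU(),
                )
            )
            self.pools.append(nn.MaxPool2())
            cin = chans[i]
        self.bottleneck = nn.Sequential(
            nn.Conv2d(chans[d - 1], chans[d], 3, rng=rng),
            nn.BatchNorm2d(chans[d]),
            nn.ReLU(),
            nn.Conv2d(chans[d], chans[d], 3, rng=rng),
            nn.BatchNorm2d(chans[d]),
            nn.ReLU(),
        )
        for i in range(d):
            deep = chans[i + 1]
            self.reduces.append(nn.Conv2d(deep, chans[i], 1, rng=rng))
            self.ups.append(nn.UpNearest2())
            self.dec.append(
                nn.Sequential(
                    nn.Conv2d(2 * chans[i], chans[i], 3, rng=rng),
                    nn.BatchNorm2d(chans[i]),
                    nn.ReLU(),
                )
            )
        self.head = nn.Conv2d(chans[0], config.n_classes, 1, rng=rng)
        self._chans = chans

    @property
    def layers(self):
        return (
            self.enc + self.pools + [self.bottleneck] + self.reduces + self.ups + self.dec + [self.head]
        )

    def parameters(self):
        return [p for l in self.layers for p in l.parameters()]

    def buffers(self):
        return [b for l in self.layers for b in l.buffers()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        d = self.config.depth
        skips = []
        for i in range(d):
            x = self.enc[i].forward(x)
            skips.append(x)
            x = self.pools[i].forward(x)
        x = self.bottleneck.forward(x)
        for i in reversed(range(d)):
            up = self.ups[i].forward(self.reduces[i].forward(x))
            x = self.dec[i].forward(np.concatenate([up, skips[i]], axis=0))
        return self.head.forward(x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.config.depth
        dy = self.head.backward(dy)
        dskips = [None] * d
        for i in range(d):  # reverse of decoder execution (shallowest first)
            c = self._chans[i]
            dcat = self.dec[i].backward(dy)
            dskips[i] = dcat[c:]
            dy = self.reduces[i].backward(self.ups[i].backward(dcat[:c]))
        dy = self.bottleneck.backward(dy)
        for i in reversed(range(d)):
            dy = self.pools[i].backward(dy) + dskips[i]
            dy = self.enc[i].backward(dy)
        return dy


def build_unet(config: SegmenterConfig) -> UNet:
    """Construct the reference U-Net for the given configuration."""
    return UNet(config)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def wcce_loss(
    pred_probs: np.ndarray, target_labels: np.ndarray, class_weights: Sequence[float]
) -> float:
    """Weighted categorical cross-entropy, averaged over pixels.

    ``pred_probs`` has classes on axis 1 (NCHW) or last axis for flat input;
    probabilities are clipped to [EPS, 1-EPS].  With all weights equal to 1
    this is the plain categorical cross-entropy.
    """
    probs = np.asarray(pred_probs, dtype=np.float64)
    t = np.asarray(target_labels).astype(np.int64)
    w = np.asarray(class_weights, dtype=np.float64)
    if probs.ndim != t.ndim + 1:
        raise ValueError("pred_probs must have one more axis (classes) than targets")
    if t.max(initial=0) >= w.size:
        raise ValueError("target label exceeds class_weights length")
    # class axis: 1 for NCHW rasters, last for channel-last / flat inputs
    axis = 1 if probs.shape[1] == w.size else probs.ndim - 1
    p_true = np.squeeze(np.take_along_axis(probs, np.expand_dims(t, axis), axis=axis), axis)
    p_true = np.clip(p_true, EPS, 1.0 - EPS)
    return float(np.mean(w[t] * -np.log(p_true)))


def cce_loss(pred_probs: np.ndarray, target_labels: np.ndarray) -> float:
    """Unweighted categorical cross-entropy."""
    n = pred_probs.shape[1] if pred_probs.ndim == target_labels.ndim + 1 else pred_probs.shape[-1]
    return wcce_loss(pred_probs, target_labels, np.ones(n))


def _loss_and_grad(logits: np.ndarray, targets: np.ndarray, weights: np.ndarray):
    """Softmax + WCCE value and gradient w.r.t. logits ((C, N, H, W) layout)."""
    probs = nn.softmax(logits, axis=0)
    t = targets[None].astype(np.int64)  # (1, N, H, W)
    onehot = np.zeros_like(probs)
    np.put_along_axis(onehot, t, 1.0, axis=0)
    wpix = weights[targets]  # (N, H, W)
    npix = targets.size
    p_true = np.clip(np.take_along_axis(probs, t, axis=0)[0], EPS, 1 - EPS)
    loss = float(np.mean(wpix * -np.log(p_true)))
    grad = (probs - onehot) * wpix[None].astype(nn.DTYPE) / npix
    return loss, grad.astype(nn.DTYPE)


# ---------------------------------------------------------------------------
# Data preparation, training, inference
# ---------------------------------------------------------------------------

def prepare_crops(
    crops: Sequence[np.ndarray], masks: Sequence[np.ndarray], size: int
) -> tuple[np.ndarray, np.ndarray]:
    """Resize crops (bilinear) and masks (nearest) to the model input size.

    Returns float32 NCHW images and integer (N, H, W) label masks.
    """
    xs, ts = [], []
    for crop, mask in zip(crops, masks):
        if crop.shape[0] != size or crop.shape[1] != size:
            crop = _sk_resize(crop, (size, size), order=1, anti_aliasing=False, preserve_range=True)
            mask = _sk_resize(mask, (size, size), order=0, anti_aliasing=False, preserve_range=True)
        xs.append(np.moveaxis(crop.astype(np.float32), -1, 0))
        ts.append(mask.astype(np.int64))
    return np.stack(xs), np.stack(ts)


def to_two_class(mask: np.ndarray) -> np.ndarray:
    """Collapse a three-class mask to rings-vs-rest (center becomes 'rest')."""
    return (np.asarray(mask) == 1).astype(np.uint8)


def train_segmenter(
    crops: Sequence[np.ndarray],
    masks: Sequence[np.ndarray],
    config: SegmenterConfig,
    val_crops: Optional[Sequence[np.ndarray]] = None,
    val_masks: Optional[Sequence[np.ndarray]] = None,
) -> tuple[UNet, nn.TrainingLog]:
    """Train a U-Net on eyespot crops with early stopping.

    Crops are float RGB in [0, 1]; masks carry labels < ``n_classes``.
    """
    size = config.input_size
    X, T = prepare_crops(crops, masks, size)
    if T.max(initial=0) >= config.n_classes:
        raise ValueError(
            f"masks contain label {int(T.max())} but config declares {config.n_classes} classes"
        )
    has_val = val_crops is not None and len(val_crops) > 0
    if has_val:
        Xv, Tv = prepare_crops(val_crops, val_masks, size)

    model = build_unet(config)
    opt = nn.Adam(model.parameters(), config.train)
    weights = np.asarray(config.class_weights, dtype=np.float64)
    aug_rng = np.random.default_rng(config.train.seed + 7919)

    def step_fn(idx: np.ndarray) -> float:
        xb, tb = X[idx], T[idx]
        if config.augment:
            flip = aug_rng.random(len(idx)) < 0.5
            xb = xb.copy()
            tb = tb.copy()
            xb[flip] = xb[flip, :, :, ::-1]
            tb[flip] = tb[flip, :, ::-1]
        nn.set_training(model, True)
        logits = model.forward(np.ascontiguousarray(xb.transpose(1, 0, 2, 3)))
        loss, grad = _loss_and_grad(logits, tb, weights)
        opt.zero_grad()
        model.backward(grad)
        opt.step()
        return loss

    def val_fn() -> float:
        nn.set_training(model, False)
        losses = []
        for start in range(0, len(Xv), config.train.batch_size):
            xb = Xv[start : start + config.train.batch_size]
            tb = Tv[start : start + config.train.batch_size]
            logits = model.forward(np.ascontiguousarray(xb.transpose(1, 0, 2, 3)))
            loss, _ = _loss_and_grad(logits, tb, weights)
            losses.append(loss * len(xb))
        return float(np.sum(losses) / len(Xv))

    log = nn.run_training(model, step_fn, val_fn if has_val else None, len(X), config.train)
    nn.set_training(model, False)
    return model, log


def predict_probs(model: UNet, crop: np.ndarray) -> np.ndarray:
    """Per-pixel class probabilities (C, H, W) for one crop at input size."""
    nn.set_training(model, False)
    x = np.ascontiguousarray(np.moveaxis(crop.astype(np.float32), -1, 0))[:, None]
    return nn.softmax(model.forward(x), axis=0)[:, 0]


def segment(model: UNet, crop: np.ndarray) -> np.ndarray:
    """Argmax label mask for one crop; ties break toward the lower label."""
    return predict_probs(model, crop).argmax(axis=0).astype(np.uint8)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_segmenter(path, model: UNet, config: Optional[SegmenterConfig] = None) -> None:
    """Single-file .npz checkpoint with the config embedded as JSON."""
    config = config or model.config
    cfg = {
        "n_classes": config.n_classes,
        "input_size": config.input_size,
        "base_width": config.base_width,
        "depth": config.depth,
        "loss": config.loss,
        "class_weights": list(config.class_weights),
        "whole_wing": config.whole_wing,
        "augment": config.augment,
        "train": vars(config.train),
    }
    state = nn.snapshot(model)
    np.savez(
        str(path),
        config=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8),
        **{f"arr_{i}": a for i, a in enumerate(state)},
    )


def load_segmenter(path) -> UNet:
    with np.load(str(path)) as data:
        cfg = json.loads(bytes(data["config"]).decode())
        train = TrainConfig(**cfg.pop("train"))
        config = SegmenterConfig(train=train, **{k: v for k, v in cfg.items() if k != "class_weights"},
                                 class_weights=tuple(cfg["class_weights"]))
        model = build_unet(config)
        state = [data[f"arr_{i}"] for i in range(len(data.files) - 1)]
    nn.restore(model, state)
    nn.set_training(model, False)
    return model
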