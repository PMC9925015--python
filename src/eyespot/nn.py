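"""A compact CPU neural-network core built on numpy.

Implements exactly the pieces the detector and the U-Net need: 2-D
convolutions (im2col + BLAS matmul), batch normalization, ReLU, 2x2 max
pooling, 2x nearest-neighbor upsampling, the Adam optimizer and an early
stopping training loop.  Everything runs in float32 and is deterministic
given the seeds in :class:`TrainConfig`.  Activations use channel-first
(C, N, H, W) layout internally, which keeps im2col writes contiguous and
the convolution GEMMs transpose-free.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence

import numpy as np

DTYPE = np.float32


@dataclass
class TrainConfig:
    """Optimizer and schedule hyperparameters shared by both networks."""

    lr: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.9999
    batch_size: int = 8
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise ValueError("betas must lie in (0, 1)")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)


class Layer:
    training: bool = True

    def parameters(self) -> List[Param]:
        return []

    def buffers(self) -> List[np.ndarray]:
        """Non-trainable state (e.g. BatchNorm running stats)."""
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


def _im2col(xp: np.ndarray, k: int, stride: int, ho: int, wo: int,
            out: Optional[np.ndarray] = None) -> np.ndarray:
    """(C, N, Hp, Wp) -> (k*k*C, N*ho*wo) patch matrix.

    Channel-first layout makes every per-tap write a contiguous block; the
    ``out`` buffer is reused across calls to avoid repeated large
    allocations (page-fault churn dominates otherwise).
    """
    c, n = xp.shape[:2]
    shape = (k, k, c, n, ho, wo)
    cols = out if out is not None and out.shape == shape else np.empty(shape, dtype=xp.dtype)
    for ki in range(k):
        for kj in range(k):
            cols[ki, kj] = xp[
                :, :, ki : ki + ho * stride : stride, kj : kj + wo * stride : stride
            ]
    return cols


class Conv2d(Layer):
    """k x k convolution with 'same' zero padding (for odd k) and He init.

    Activations flow in (C, N, H, W) layout throughout the core.
    """

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 rng: Optional[np.random.Generator] = None, bias_init: float = 0.0):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (cin * k * k))
        self.w = Param(rng.normal(0.0, scale, size=(cout, cin, k, k)))
        self.b = Param(np.full(cout, bias_init, dtype=DTYPE))
        self.k, self.stride, self.pad = k, stride, k // 2
        self._cache = None
        self._cols_buf: Optional[np.ndarray] = None
        self._dcols_buf: Optional[np.ndarray] = None
        self._dxp_buf: Optional[np.ndarray] = None

    def parameters(self) -> List[Param]:
        return [self.w, self.b]

    def _wmat(self) -> np.ndarray:
        # (cout, cin, k, k) -> (cout, k*k*cin) matching the im2col tap order
        return np.ascontiguousarray(self.w.data.transpose(0, 2, 3, 1)).reshape(
            self.w.data.shape[0], -1
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, n, h, w = x.shape
        p, k, s = self.pad, self.k, self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        if k == 1 and s == 1:
            cols = xp.reshape(c, -1)
        else:
            self._cols_buf = _im2col(xp, k, s, ho, wo, out=self._cols_buf)
            cols = self._cols_buf.reshape(k * k * c, n * ho * wo)
        y = self._wmat() @ cols + self.b.data[:, None]
        self._cache = (cols, x.shape, ho, wo)
        return y.reshape(-1, n, ho, wo)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xshape, ho, wo = self._cache
        c, n, h, w = xshape
        p, k, s = self.pad, self.k, self.stride
        cout = self.w.data.shape[0]
        dym = dy.reshape(cout, -1)
        dwm = dym @ cols.T  # (cout, k*k*cin)
        self.w.grad += dwm.reshape(cout, k, k, c).transpose(0, 3, 1, 2)
        self.b.grad += dym.sum(axis=1)
        if k == 1 and s == 1:
            return (self._wmat().T @ dym).reshape(c, n, h, w)
        shape = (k, k, c, n, ho, wo)
        if self._dcols_buf is None or self._dcols_buf.shape != (k * k * c, n * ho * wo):
            self._dcols_buf = np.empty((k * k * c, n * ho * wo), dtype=DTYPE)
        np.matmul(self._wmat().T, dym, out=self._dcols_buf)
        dcols = self._dcols_buf.reshape(shape)
        pshape = (c, n, h + 2 * p, w + 2 * p)
        if self._dxp_buf is None or self._dxp_buf.shape != pshape:
            self._dxp_buf = np.zeros(pshape, dtype=DTYPE)
        else:
            self._dxp_buf[...] = 0.0
        dxp = self._dxp_buf
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki : ki + ho * s : s, kj : kj + wo * s : s] += dcols[ki, kj]
        self._cache = None
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c, dtype=DTYPE))
        self.beta = Param(np.zeros(c, dtype=DTYPE))
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def parameters(self) -> List[Param]:
        return [self.gamma, self.beta]

    def buffers(self) -> List[np.ndarray]:
        return [self.running_mean, self.running_var]

    def forward(self, x: np.ndarray) -> np.ndarray:
        # x is (C, N, H, W); statistics are per channel (axis 0)
        if self.training:
            mean = x.mean(axis=(1, 2, 3))
            var = x.var(axis=(1, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(DTYPE)
        xhat = (x - mean.astype(DTYPE)[:, None, None, None]) * inv[:, None, None, None]
        self._cache = (xhat, inv)
        return self.gamma.data[:, None, None, None] * xhat + self.beta.data[:, None, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self._cache = None
        m = dy.shape[1] * dy.shape[2] * dy.shape[3]
        dgamma = (dy * xhat).sum(axis=(1, 2, 3))
        dbeta = dy.sum(axis=(1, 2, 3))
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        g = self.gamma.data[:, None, None, None] * inv[:, None, None, None]
        if not self.training:
            return g * dy
        return g * (
            dy
            - (dbeta / m).astype(DTYPE)[:, None, None, None]
            - xhat * (dgamma / m).astype(DTYPE)[:, None, None, None]
        )


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2(Layer):
    """2x2 max pooling with stride 2; ties resolve to the first maximum."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, n, h, w = x.shape
        xr = x.reshape(c, n, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = np.ascontiguousarray(xr).reshape(c, n, h // 2, w // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, n, h, w = self._shape
        flat = np.zeros((c, n, h // 2, w // 2, 4), dtype=DTYPE)
        np.put_along_axis(flat, self._idx[..., None], dy[..., None], axis=-1)
        return (
            flat.reshape(c, n, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(c, n, h, w)
        )


class UpNearest2(Layer):
    """2x nearest-neighbor upsampling; backward sums each 2x2 block."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, n, h, w = dy.shape
        return dy.reshape(c, n, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def parameters(self) -> List[Param]:
        return [p for l in self.layers for p in l.parameters()]

    def buffers(self) -> List[np.ndarray]:
        return [b for l in self.layers for b in l.buffers()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


def set_training(layer: Layer, flag: bool) -> None:
    layer.training = flag
    for sub in getattr(layer, "layers", []):
        set_training(sub, flag)
    for name in ("blocks",):
        for sub in getattr(layer, name, []):
            set_training(sub, flag)


def softmax(z: np.ndarray, axis: int = 1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Adam:
    def __init__(self, params: Sequence[Param], config: TrainConfig):
        self.params = list(params)
        self.lr = config.lr
        self.b1, self.b2 = config.beta1, config.beta2
        self.eps = 1e-8
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (p.grad - m)
            v += (1.0 - self.b2) * (p.grad**2 - v)
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


# ---------------------------------------------------------------------------
# Model state snapshots and the training loop
# ---------------------------------------------------------------------------

def snapshot(model: Layer) -> list[np.ndarray]:
    return [p.data.copy() for p in model.parameters()] + [
        b.copy() for b in model.buffers()
    ]


def restore(model: Layer, state: list[np.ndarray]) -> None:
    params = model.parameters()
    buffers = model.buffers()
    for p, s in zip(params, state[: len(params)]):
        p.data[...] = s
    for b, s in zip(buffers, state[len(params) :]):
        b[...] = s


@dataclass
class TrainingLog:
    """Per-epoch losses plus why and when training stopped."""

    epochs: list = field(default_factory=list)  # dicts: epoch, train_loss, val_loss
    stop_reason: str = ""
    best_epoch: int = 0

    @property
    def n_epochs(self) -> int:
        return len(self.epochs)


def run_training(
    model: Layer,
    step_fn: Callable[[np.ndarray], float],
    val_fn: Optional[Callable[[], float]],
    n_items: int,
    config: TrainConfig,
) -> TrainingLog:
    """Generic epoch loop with early stopping on the validation loss.

    ``step_fn`` consumes one batch of item indices, performs the gradient
    step and returns the batch loss.  Training stops at ``max_epochs`` or
    once the validation loss has not improved for ``patience`` consecutive
    epochs; the best-validation weights are restored at the end.  With no
    validation function, early stopping is disabled.
    """
    import logging

    rng = np.random.default_rng(config.seed)
    log = TrainingLog()
    best_val = np.inf
    best_state = None
    since_best = 0
    if val_fn is None:
        logging.getLogger(__name__).warning(
            "no validation set: early stopping disabled, training to max_epochs"
        )
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n_items)
        losses = []
        for start in range(0, n_items, config.batch_size):
            idx = order[start : start + config.batch_size]
            losses.append(step_fn(idx))
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if val_fn is not None:
            val = float(val_fn())
            entry["val_loss"] = val
            if val < best_val - 1e-12:
                best_val = val
                best_state = snapshot(model)
                log.best_epoch = epoch
                since_best = 0
            else:
                since_best += 1
        log.epochs.append(entry)
        if val_fn is not None and since_best >= config.patience:
            log.stop_reason = f"early stop: no val improvement for {config.patience} epochs"
            break
    else:
        log.stop_reason = f"reached max_epochs = {config.max_epochs}"
    if best_state is not None:
        restore(model, best_state)
    return log
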