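"""Compact NumPy convolutional-network backend.

A small encoder–decoder ("U"-shaped) fully convolutional network with
hand-written forward/backward passes, used by the probability-map module to
train a toy-scale provider: paired 3x3 convolutions + ReLU per level, 2x2
max-pooling on the way down, 2x2 nearest-neighbour up-sampling with skip
concatenation on the way up, and a final 1x1 convolution with a sigmoid
producing the per-pixel kidney probability. Optimised with Adam on binary
cross-entropy. Everything is seeded and deterministic.

This backend targets desk-scale experiments (tens of 64x64 images, a
handful of epochs); it is not a performance-oriented deep-learning stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["TinyUNet", "AdamState", "train", "TrainingCurves"]


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, H*W) patches of a zero-padded input."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # N,C,H,W,k,k
    n, c, h, w = x.shape
    return win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, h * w)


def _col2im(cols: np.ndarray, x_shape, k: int) -> np.ndarray:
    """Adjoint of _im2col: scatter (N, C*k*k, H*W) back to (N, C, H, W)."""
    n, c, h, w = x_shape
    p = k // 2
    out = np.zeros((n, c, h + 2 * p, w + 2 * p))
    cols = cols.reshape(n, c, k, k, h, w)
    for i in range(k):
        for j in range(k):
            out[:, :, i:i + h, j:j + w] += cols[:, :, i, j]
    return out[:, :, p:p + h, p:p + w]


class _Conv:
    """k x k same-padding convolution with optional ReLU."""

    def __init__(self, rng, c_in, c_out, k=3, relu=True):
        fan_in = c_in * k * k
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, c_in * k * k))
        self.b = np.zeros(c_out)
        self.k, self.relu = k, relu
        self.c_in = c_in

    def forward(self, x):
        self._x_shape = x.shape
        self._cols = _im2col(x, self.k)
        n, _, hw = self._cols.shape
        h, w = x.shape[2], x.shape[3]
        z = np.einsum("oc,ncp->nop", self.w, self._cols) + self.b[None, :, None]
        z = z.reshape(n, -1, h, w)
        if self.relu:
            self._pre = z
            z = np.maximum(z, 0.0)
        return z

    def backward(self, dz):
        n, c_out, h, w = dz.shape
        if self.relu:
            dz = dz * (self._pre > 0)
        dzf = dz.reshape(n, c_out, h * w)
        self.dw = np.einsum("nop,ncp->oc", dzf, self._cols) / n
        self.db = dzf.sum(axis=(0, 2)) / n
        dcols = np.einsum("oc,nop->ncp", self.w, dzf)
        return _col2im(dcols, self._x_shape, self.k)

    def params(self):
        return [("w", self), ("b", self)]


def _maxpool2(x):
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
    out = xr.max(axis=(3, 5))
    mask = xr == out[:, :, :, None, :, None]
    return out, mask


def _maxpool2_back(dout, mask):
    n, c, h2, _, w2, _ = mask.shape
    grad = mask * dout[:, :, :, None, :, None]
    # ties split the gradient; normalise by the tie count
    counts = mask.sum(axis=(3, 5), keepdims=True)
    grad = grad / counts
    return grad.reshape(n, c, h2 * 2, w2 * 2)


def _upsample2(x):
    return x.repeat(2, axis=2).repeat(2, axis=3)


def _upsample2_back(dout):
    n, c, h, w = dout.shape
    return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class TinyUNet:
    """Encoder–decoder network; ``depth`` pooling stages, ``base`` filters."""

    def __init__(self, depth: int = 2, base: int = 4, seed: int = 0):
        if depth < 1:
            raise ValueError("depth must be >= 1")
        rng = np.random.default_rng(seed)
        self.depth, self.base = depth, base
        self.enc = []
        c_in = 1
        for d in range(depth):
            c_out = base * 2 ** d
            self.enc.append((_Conv(rng, c_in, c_out), _Conv(rng, c_out, c_out)))
            c_in = c_out
        c_bot = base * 2 ** depth
        self.bottleneck = (_Conv(rng, c_in, c_bot), _Conv(rng, c_bot, c_bot))
        self.dec = []
        c_in = c_bot
        for d in reversed(range(depth)):
            c_skip = base * 2 ** d
            self.dec.append((_Conv(rng, c_in + c_skip, c_skip),
                             _Conv(rng, c_skip, c_skip)))
            c_in = c_skip
        self.head = _Conv(rng, c_in, 1, k=1, relu=False)

    def _convs(self):
        for pair in self.enc:
            yield from pair
        yield from self.bottleneck
        for pair in self.dec:
            yield from pair
        yield self.head

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (N, 1, H, W) with H, W divisible by 2**depth -> logits."""
        h, w = x.shape[2], x.shape[3]
        if h % 2 ** self.depth or w % 2 ** self.depth:
            raise ValueError(
                f"input size {h}x{w} not divisible by 2^{self.depth}")
        self._skips, self._pool_masks = [], []
        for c1, c2 in self.enc:
            x = c2.forward(c1.forward(x))
            self._skips.append(x)
            x, m = _maxpool2(x)
            self._pool_masks.append(m)
        c1, c2 = self.bottleneck
        x = c2.forward(c1.forward(x))
        self._concat_splits = []
        for (c1, c2), skip in zip(self.dec, reversed(self._skips)):
            x = _upsample2(x)
            self._concat_splits.append(x.shape[1])
            x = np.concatenate([x, skip], axis=1)
            x = c2.forward(c1.forward(x))
        return self.head.forward(x)

    def backward(self, dlogits: np.ndarray) -> None:
        dx = self.head.backward(dlogits)
        dskips = [None] * len(self.enc)
        for i, (c1, c2) in reversed(list(enumerate(self.dec))):
            dx = c1.backward(c2.backward(dx))
            split = self._concat_splits[i]
            dup, dskip = dx[:, :split], dx[:, split:]
            dskips[len(self.enc) - 1 - i] = dskip
            dx = _upsample2_back(dup)
        c1, c2 = self.bottleneck
        dx = c1.backward(c2.backward(dx))
        for i, (c1, c2) in reversed(list(enumerate(self.enc))):
            dx = _maxpool2_back(dx, self._pool_masks[i])
            dx = dx + dskips[i] if dskips[i] is not None else dx
            dx = c1.backward(c2.backward(dx))

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Per-pixel probabilities in (0, 1)."""
        return 1.0 / (1.0 + np.exp(-self.forward(x)))


@dataclass
class AdamState:
    lr: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    t: int = 0
    m: dict = field(default_factory=dict)
    v: dict = field(default_factory=dict)

    def step(self, model: TinyUNet) -> None:
        self.t += 1
        for i, conv in enumerate(model._convs()):
            for name, grad in (("w", conv.dw), ("b", conv.db)):
                key = (i, name)
                m = self.m.get(key, np.zeros_like(grad))
                v = self.v.get(key, np.zeros_like(grad))
                m = self.beta1 * m + (1 - self.beta1) * grad
                v = self.beta2 * v + (1 - self.beta2) * grad ** 2
                self.m[key], self.v[key] = m, v
                mhat = m / (1 - self.beta1 ** self.t)
                vhat = v / (1 - self.beta2 ** self.t)
                param = getattr(conv, name)
                param -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def bce_loss(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Stable mean binary cross-entropy and its gradient w.r.t. logits."""
    z = logits
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    sig = 1.0 / (1.0 + np.exp(-z))
    n = y.size / y.shape[0]  # per-sample pixel count; batch mean taken in backward
    return float(loss.mean()), (sig - y) / n


@dataclass
class TrainingCurves:
    epoch: list = field(default_factory=list)
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    train_acc: list = field(default_factory=list)
    val_acc: list = field(default_factory=list)

    def to_csv(self, path) -> None:
        lines = ["epoch,train_loss,val_loss,train_acc,val_acc"]
        for row in zip(self.epoch, self.train_loss, self.val_loss,
                       self.train_acc, self.val_acc):
            lines.append(",".join(f"{v:.6g}" for v in row))
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def _evaluate(model, x, y, batch=8):
    losses, accs = [], []
    for i in range(0, len(x), batch):
        logits = model.forward(x[i:i + batch])
        loss, _ = bce_loss(logits, y[i:i + batch])
        prob = 1.0 / (1.0 + np.exp(-logits))
        accs.append(np.mean((prob > 0.5) == (y[i:i + batch] > 0.5)))
        losses.append(loss)
    return float(np.mean(losses)), float(np.mean(accs))


def train(model: TinyUNet, x_train, y_train, x_val, y_val, *,
          epochs: int = 10, batch_size: int = 8, lr: float = 1e-4,
          lr_decay_factor: float = 0.9, patience: int = 10,
          seed: int = 0) -> TrainingCurves:
    """Adam/BCE training with plateau learning-rate decay.

    The learning rate is multiplied by ``lr_decay_factor`` whenever the
    validation loss has not improved for ``patience`` consecutive epochs.
    Curves include an epoch-0 row (pre-training evaluation). Raises
    FloatingPointError on a divergent (non-finite) loss.
    """
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("training and validation sets must be non-empty")
    rng = np.random.default_rng(seed)
    opt = AdamState(lr=lr)
    curves = TrainingCurves()

    tl, ta = _evaluate(model, x_train, y_train)
    vl, va = _evaluate(model, x_val, y_val)
    curves.epoch.append(0)
    curves.train_loss.append(tl)
    curves.val_loss.append(vl)
    curves.train_acc.append(ta)
    curves.val_acc.append(va)

    best_val = vl
    stale = 0
    for epoch in range(1, epochs + 1):
        order = rng.permutation(len(x_train))
        for i in range(0, len(order), batch_size):
            idx = order[i:i + batch_size]
            logits = model.forward(x_train[idx])
            loss, dlogits = bce_loss(logits, y_train[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"divergent loss at epoch {epoch} (loss={loss})")
            model.backward(dlogits)
            opt.step(model)
        tl, ta = _evaluate(model, x_train, y_train)
        vl, va = _evaluate(model, x_val, y_val)
        curves.epoch.append(epoch)
        curves.train_loss.append(tl)
        curves.val_loss.append(vl)
        curves.train_acc.append(ta)
        curves.val_acc.append(va)
        if vl < best_val - 1e-12:
            best_val = vl
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                opt.lr *= lr_decay_factor
                stale = 0
    return curves
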