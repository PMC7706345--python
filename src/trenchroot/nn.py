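"""Minimal NumPy neural-network primitives for the root segmenter.

A small, dependency-light layer library — zero-padded 3x3 convolutions
via im2col, batch normalization, ReLU, 2x2 max pooling, nearest-neighbor
2x upsampling, channel concatenation — each with a hand-written backward
pass, plus Adam.  Everything is float32, NCHW, and fully deterministic
given a seeded ``numpy.random.Generator``: repeated runs produce
bit-identical weights and predictions, which the training and checkpoint
contracts rely on.

This is deliberately scoped to what the U-shaped segmentation network
needs; it is not a general autodiff framework.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(F32)
        self.grad = np.zeros_like(self.value)


class Layer:
    """Base: forward caches what backward needs; params() lists Params."""

    def params(self) -> list[Param]:
        return []

    def buffers(self) -> list[np.ndarray]:
        """Non-trained state (batch-norm running stats)."""
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N*H*W, C*k*k) patch matrix for 'same' convolution."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # win: (N, C, H, W, k, k) -> (N, H, W, C, k, k)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * h * w, c * k * k)


class Conv2d(Layer):
    """k x k convolution with zero padding that keeps the spatial size."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, k: int = 3):
        self.cin, self.cout, self.k = cin, cout, k
        self.pad = k // 2
        std = np.sqrt(2.0 / (cin * k * k))
        self.w = Param(rng.normal(0.0, std, size=(cout, cin, k, k)))
        self.b = Param(np.zeros(cout))
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training):
        n, c, h, w = x.shape
        col = _im2col(x, self.k, self.pad)
        wmat = self.w.value.reshape(self.cout, -1).T  # (C*k*k, cout)
        y = col @ wmat + self.b.value
        self._cache = (col, x.shape)
        return y.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2)

    def backward(self, grad):
        col, xshape = self._cache
        n, c, h, w = xshape
        gflat = np.ascontiguousarray(grad.transpose(0, 2, 3, 1)).reshape(-1, self.cout)
        self.w.grad += (col.T @ gflat).T.reshape(self.w.value.shape)
        self.b.grad += gflat.sum(axis=0)
        dcol = gflat @ self.w.value.reshape(self.cout, -1)  # (N*H*W, C*k*k)
        d = dcol.reshape(n, h, w, c, self.k, self.k).transpose(0, 3, 1, 2, 4, 5)
        p = self.pad
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=F32)
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i:i + h, j:j + w] += d[:, :, :, :, i, j]
        self._cache = None
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return [self.running_mean, self.running_var]

    def forward(self, x, training):
        if training:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[:, None, None]) * ivar[:, None, None]
        if training:
            self._cache = (xhat, ivar)
        return (self.gamma.value[:, None, None] * xhat
                + self.beta.value[:, None, None]).astype(F32)

    def backward(self, grad):
        xhat, ivar = self._cache
        self._cache = None
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        dxhat = grad * self.gamma.value[:, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3))
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3))
        dx = (ivar[:, None, None] / m) * (m * dxhat - s1[:, None, None]
                                          - xhat * s2[:, None, None])
        return dx.astype(F32)


class ReLU(Layer):
    def forward(self, x, training):
        mask = x > 0
        self._mask = mask if training else None
        return np.where(mask, x, 0).astype(F32)

    def backward(self, grad):
        g = grad * self._mask
        self._mask = None
        return g


class MaxPool2(Layer):
    """2x2 max pooling, stride 2."""

    def forward(self, x, training):
        n, c, h, w = x.shape
        r = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        r = r.reshape(n, c, h // 2, w // 2, 4)
        idx = r.argmax(axis=-1)
        if training:
            self._cache = (idx, x.shape)
        return np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        idx, (n, c, h, w) = self._cache
        self._cache = None
        d = np.zeros((n, c, h // 2, w // 2, 4), dtype=F32)
        np.put_along_axis(d, idx[..., None], grad[..., None], axis=-1)
        return d.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5) \
                .reshape(n, c, h, w)


class Upsample2(Layer):
    """Nearest-neighbor 2x upsampling."""

    def forward(self, x, training):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, grad):
        n, c, h, w = grad.shape
        return grad.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5)).astype(F32)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def buffers(self):
        return [b for l in self.layers for b in l.buffers()]

    def forward(self, x, training):
        for l in self.layers:
            x = l.forward(x, training)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


def double_conv(cin: int, cout: int, rng: np.random.Generator) -> Sequential:
    """Two (3x3 zero-padded conv -> batch norm -> ReLU) stages."""
    return Sequential([
        Conv2d(cin, cout, rng), BatchNorm2d(cout), ReLU(),
        Conv2d(cout, cout, rng), BatchNorm2d(cout), ReLU(),
    ])


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=F32)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dloss/dz)."""
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    grad = (sigmoid(z) - y) / z.size
    return loss, grad.astype(F32)


def soft_dice_loss(z: np.ndarray, y: np.ndarray, eps: float = 1.0) -> tuple[float, np.ndarray]:
    """1 - soft Dice on sigmoid probabilities; returns (loss, dloss/dz)."""
    p = sigmoid(z)
    inter = float((p * y).sum())
    denom = float(p.sum() + y.sum()) + eps
    loss = 1.0 - (2.0 * inter + eps) / denom
    # d(2A+eps)/B wrt p_i = (2 y_i B - (2A+eps)) / B^2 ;  dz = -that * p(1-p)
    dp = -(2.0 * y * denom - (2.0 * inter + eps)) / denom ** 2
    return loss, (dp * p * (1.0 - p)).astype(F32)


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (p.grad - m)
            v += (1.0 - self.b2) * (p.grad ** 2 - v)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
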