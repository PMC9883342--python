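"""Minimal numpy neural-network layers with hand-written backprop.

Just enough machinery for the desk-scale models in this package: 3x3
convolutions (im2col), ReLU, exact integer-factor average pooling,
linear layers, and Adam. Layers cache their forward inputs, so a layer
instance serves one forward/backward pair at a time — fine for the
sequential training loops used here.
"""
from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Param", "Conv2d", "ReLU", "AvgPool2d", "Upsample2d", "Linear", "Adam"]


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    ho, wo = win.shape[2], win.shape[3]
    cols = np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3)).reshape(
        n, c * k * k, ho * wo
    )
    return cols, ho, wo


def _col2im(dcols: np.ndarray, xshape, k: int, stride: int, pad: int, ho: int, wo: int):
    n, c, h, w = xshape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=np.float32)
    d = dcols.reshape(n, c, k, k, ho, wo)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += d[
                :, :, i, j
            ]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


class Conv2d:
    """k x k convolution, 'same'-style padding k//2, optional stride."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        k: int = 3,
        stride: int = 1,
        rng=None,
        init_scale: float = 1.0,
    ):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k * k
        w = init_scale * rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k))
        self.W = Param(w)
        self.b = Param(np.zeros(c_out))
        self.k, self.stride, self.pad = k, stride, k // 2
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        cols, ho, wo = _im2col(x, self.k, self.stride, self.pad)
        w2 = self.W.value.reshape(self.W.value.shape[0], -1)
        out = np.matmul(w2, cols) + self.b.value[:, None]
        self._cache = (x.shape, cols, ho, wo)
        return out.reshape(x.shape[0], -1, ho, wo)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xshape, cols, ho, wo = self._cache
        n, c_out = dout.shape[0], dout.shape[1]
        dflat = dout.reshape(n, c_out, -1)
        self.W.grad += np.einsum("nol,nfl->of", dflat, cols).reshape(self.W.value.shape)
        self.b.grad += dflat.sum(axis=(0, 2))
        w2 = self.W.value.reshape(c_out, -1)
        dcols = np.matmul(w2.T, dflat)
        return _col2im(dcols, xshape, self.k, self.stride, self.pad, ho, wo)


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0)


class AvgPool2d:
    """Exact factor-f average pooling (identity when f == 1)."""

    def __init__(self, factor: int):
        self.f = int(factor)
        self._shape = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.f == 1:
            return x
        n, c, h, w = x.shape
        self._shape = x.shape
        f = self.f
        return x.reshape(n, c, h // f, f, w // f, f).mean(axis=(3, 5))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.f == 1:
            return dout
        f = self.f
        up = np.repeat(np.repeat(dout, f, axis=2), f, axis=3) / (f * f)
        return up.astype(np.float32)


class Upsample2d:
    """Nearest-neighbor factor-f upsampling (exact sum-pooling backward)."""

    def __init__(self, factor: int):
        self.f = int(factor)

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.f == 1:
            return x
        return np.repeat(np.repeat(x, self.f, axis=2), self.f, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.f == 1:
            return dout
        n, c, h, w = dout.shape
        f = self.f
        return (
            dout.reshape(n, c, h // f, f, w // f, f).sum(axis=(3, 5)).astype(np.float32)
        )


class Linear:
    def __init__(self, d_in: int, d_out: int, rng=None):
        rng = rng or np.random.default_rng(0)
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out)))
        self.b = Param(np.zeros(d_out))
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = np.asarray(x, dtype=np.float32)
        return self._x @ self.W.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


class Adam:
    """Adam optimizer over a list of :class:`Param`."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
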