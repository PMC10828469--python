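"""Minimal NumPy neural-network layers with explicit forward/backward.

Provides exactly the primitives a LinkNet-style encoder-decoder needs:
2-D convolution and transposed convolution (im2col/col2im + GEMM),
batch normalization, ReLU, max-pooling, and the Adadelta optimizer.
All tensors are NCHW ``float32``; every layer caches what its backward
pass needs, so the network graph is composed by hand in ``linknet``.

Gradient correctness is verified against central finite differences in
the test suite; single-threaded execution is bit-deterministic.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


class Param:
    """A learnable tensor and its gradient accumulator."""

    __slots__ = ("name", "data", "grad")

    def __init__(self, name: str, data: np.ndarray):
        self.name = name
        self.data = np.ascontiguousarray(data, dtype=F32)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return self.data.size


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int, pad_value: float = 0.0):
    """(N,C,H,W) -> (N*OH*OW, C*kh*kw) patch matrix, plus OH, OW."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)), constant_values=pad_value)
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    oh, ow = win.shape[2], win.shape[3]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * oh * ow, c * kh * kw)
    return cols, oh, ow


def _col2im(
    cols: np.ndarray,
    n: int,
    c: int,
    out_h: int,
    out_w: int,
    kh: int,
    kw: int,
    stride: int,
    pad: int,
    grid_h: int,
    grid_w: int,
) -> np.ndarray:
    """Scatter-add (N*grid_h*grid_w, C*kh*kw) patches onto an (N,C,out_h,out_w) canvas."""
    canvas_h, canvas_w = out_h + 2 * pad, out_w + 2 * pad
    out = np.zeros((n, c, canvas_h, canvas_w), dtype=cols.dtype)
    d = cols.reshape(n, grid_h, grid_w, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i : i + stride * grid_h : stride, j : j + stride * grid_w : stride] += d[
                :, :, i, j
            ]
    if pad:
        out = out[:, :, pad : pad + out_h, pad : pad + out_w]
    return out


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """Cross-correlation convolution; weights He-initialized from ``rng``."""

    def __init__(
        self,
        cin: int,
        cout: int,
        k: int,
        stride: int = 1,
        pad: int = 0,
        bias: bool = True,
        rng: np.random.Generator | None = None,
        name: str = "conv",
    ):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (cin * k * k))
        self.w = Param(f"{name}.w", rng.normal(0.0, scale, size=(cout, cin, k, k)))
        self.b = Param(f"{name}.b", np.zeros(cout)) if bias else None
        self.k, self.stride, self.pad = k, stride, pad
        self.cin, self.cout = cin, cout
        self._cache = None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x, training=False):
        n = x.shape[0]
        cols, oh, ow = _im2col(x, self.k, self.k, self.stride, self.pad)
        wmat = self.w.data.reshape(self.cout, -1)
        y = cols @ wmat.T
        if self.b is not None:
            y += self.b.data
        y = y.reshape(n, oh, ow, self.cout).transpose(0, 3, 1, 2)
        self._cache = (cols, x.shape, oh, ow)
        return np.ascontiguousarray(y)

    def backward(self, dy):
        cols, x_shape, oh, ow = self._cache
        n, cin, h, w = x_shape
        dy_mat = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, self.cout)
        self.w.grad += (dy_mat.T @ cols).reshape(self.w.data.shape)
        if self.b is not None:
            self.b.grad += dy_mat.sum(axis=0)
        dcols = dy_mat @ self.w.data.reshape(self.cout, -1)
        return _col2im(dcols, n, cin, h, w, self.k, self.k, self.stride, self.pad, oh, ow)


class ConvTranspose2d(Layer):
    """Transposed convolution (fractionally strided); upsamples by ``stride``."""

    def __init__(
        self,
        cin: int,
        cout: int,
        k: int,
        stride: int = 1,
        pad: int = 0,
        output_padding: int = 0,
        bias: bool = True,
        rng: np.random.Generator | None = None,
        name: str = "convT",
    ):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (cin * k * k))
        # stored as (cin, cout, k, k), matching the transposed-conv convention
        self.w = Param(f"{name}.w", rng.normal(0.0, scale, size=(cin, cout, k, k)))
        self.b = Param(f"{name}.b", np.zeros(cout)) if bias else None
        self.k, self.stride, self.pad, self.outpad = k, stride, pad, output_padding
        self.cin, self.cout = cin, cout
        if output_padding >= stride:
            raise ValueError("output_padding must be < stride")
        self._cache = None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def out_size(self, size: int) -> int:
        return (size - 1) * self.stride - 2 * self.pad + self.k + self.outpad

    def forward(self, x, training=False):
        n, cin, h, w = x.shape
        oh, ow = self.out_size(h), self.out_size(w)
        x_mat = np.ascontiguousarray(x.transpose(0, 2, 3, 1)).reshape(-1, cin)
        cols = x_mat @ self.w.data.reshape(cin, -1)  # -> (N*H*W, cout*k*k)
        # extend canvas by outpad so every kernel slice fits, then crop
        y = _col2im(
            cols, n, self.cout, oh, ow, self.k, self.k, self.stride, self.pad, h, w
        )
        if self.b is not None:
            y += self.b.data[None, :, None, None]
        self._cache = (x_mat, x.shape, oh, ow)
        return y

    def backward(self, dy):
        x_mat, x_shape, oh, ow = self._cache
        n, cin, h, w = x_shape
        if self.b is not None:
            self.b.grad += dy.sum(axis=(0, 2, 3))
        # grad wrt input = ordinary convolution of dy with the same kernel
        dy_cols, gh, gw = _im2col(dy, self.k, self.k, self.stride, self.pad)
        dy_cols = dy_cols[: n * gh * gw]
        if (gh, gw) != (h, w):  # output_padding leaves extra window rows; drop them
            dy_cols = (
                dy_cols.reshape(n, gh, gw, -1)[:, :h, :w].reshape(n * h * w, -1)
            )
        self.w.grad += (x_mat.T @ dy_cols).reshape(self.w.data.shape)
        dx = (dy_cols @ self.w.data.reshape(cin, -1).T).reshape(n, h, w, cin)
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))


class BatchNorm2d(Layer):
    """Per-channel batch normalization (batch stats in training, running in eval)."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5, name: str = "bn"):
        self.gamma = Param(f"{name}.gamma", np.ones(c))
        self.beta = Param(f"{name}.beta", np.zeros(c))
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)
        self.momentum, self.eps = momentum, eps
        self.update_stats = True
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            if self.update_stats:
                m = self.momentum
                self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(F32)
                self.running_var = ((1 - m) * self.running_var + m * var).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std, training)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, dy):
        xhat, inv_std, training = self._cache
        axes = (0, 2, 3)
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        g = self.gamma.data[None, :, None, None] * inv_std[None, :, None, None]
        if not training:
            return dy * g
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dy_sum = dy.sum(axis=axes, keepdims=True)
        dyxhat_sum = (dy * xhat).sum(axis=axes, keepdims=True)
        return g * (dy - dy_sum / m - xhat * dyxhat_sum / m)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class MaxPool2d(Layer):
    def __init__(self, k: int = 3, stride: int = 2, pad: int = 1):
        self.k, self.stride, self.pad = k, stride, pad
        self._cache = None

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        cols, oh, ow = _im2col(x, self.k, self.k, self.stride, self.pad, pad_value=-np.inf)
        cols = cols.reshape(n * oh * ow, c, self.k * self.k)
        idx = cols.argmax(axis=2)
        y = np.take_along_axis(cols, idx[:, :, None], axis=2)[:, :, 0]
        y = y.reshape(n, oh, ow, c).transpose(0, 3, 1, 2)
        self._cache = (idx, x.shape, oh, ow)
        return np.ascontiguousarray(y)

    def backward(self, dy):
        idx, x_shape, oh, ow = self._cache
        n, c, h, w = x_shape
        dy_mat = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(n * oh * ow, c)
        dcols = np.zeros((n * oh * ow, c, self.k * self.k), dtype=dy_mat.dtype)
        np.put_along_axis(dcols, idx[:, :, None], dy_mat[:, :, None], axis=2)
        dcols = dcols.reshape(n * oh * ow, c * self.k * self.k)
        return _col2im(dcols, n, c, h, w, self.k, self.k, self.stride, self.pad, oh, ow)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax_channels(z: np.ndarray) -> np.ndarray:
    """Softmax across the channel axis of an (N,C,H,W) or (C,H,W) array."""
    axis = 1 if z.ndim == 4 else 0
    zmax = z.max(axis=axis, keepdims=True)
    e = np.exp(z - zmax)
    return e / e.sum(axis=axis, keepdims=True)


class Adadelta:
    """Adadelta: per-parameter adaptive steps from running squared-gradient
    and squared-update averages; ``lr`` is an overall scale (1.0 = classic)."""

    def __init__(self, params: list[Param], rho: float = 0.9, eps: float = 1e-6, lr: float = 1.0):
        self.params = params
        self.rho, self.eps, self.lr = rho, eps, lr
        self._eg2 = [np.zeros_like(p.data) for p in params]
        self._ed2 = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        if self.lr == 0.0:
            for p in self.params:
                p.grad[...] = 0.0
            return
        rho, eps = self.rho, self.eps
        for p, eg2, ed2 in zip(self.params, self._eg2, self._ed2):
            g = p.grad
            eg2 *= rho
            eg2 += (1 - rho) * g * g
            delta = np.sqrt((ed2 + eps) / (eg2 + eps)) * g
            ed2 *= rho
            ed2 += (1 - rho) * delta * delta
            p.data -= (self.lr * delta).astype(F32)
            p.grad[...] = 0.0
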