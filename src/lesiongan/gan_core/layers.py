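"""Minimal convolutional-network layer algebra with manual backprop.

Tensors are NCHW ``float32`` (``float64`` supported for gradient checking).
Convolutions are evaluated through an im2col/col2im lowering whose column
layout is ``(C·k·k, N·L)`` — the whole minibatch becomes a single large
matrix product, which keeps the arithmetic in one well-shaped GEMM per
layer instead of many skinny batched ones. The transposed convolution is
implemented as the exact adjoint of the strided convolution with the same
geometry, so the two layers' gradients are symmetric by construction.

Each layer caches what its backward pass needs during ``forward`` and
exposes its parameters as :class:`Param` objects (``data`` + accumulated
``grad``), which the optimizer updates in place.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "ReLU",
    "LeakyReLU",
    "Tanh",
    "Sequential",
    "im2col",
    "col2im",
]


class Param:
    """A learnable array and its gradient accumulator."""

    __slots__ = ("name", "data", "grad")

    def __init__(self, name: str, data: np.ndarray):
        self.name = name
        self.data = data
        self.grad = np.zeros_like(data)

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


def _out_size(n: int, k: int, s: int, p: int) -> int:
    return (n + 2 * p - k) // s + 1


def im2col(x: np.ndarray, k: int, s: int, p: int) -> np.ndarray:
    """Lower (N,C,H,W) to patch columns (C·k·k, N·oh·ow)."""
    n, c, h, w = x.shape
    oh, ow = _out_size(h, k, s, p), _out_size(w, k, s, p)
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
    cols = np.empty((c, k, k, n, oh, ow), dtype=x.dtype)
    for ky in range(k):
        for kx in range(k):
            cols[:, ky, kx] = xp[
                :, :, ky : ky + s * oh : s, kx : kx + s * ow : s
            ].transpose(1, 0, 2, 3)
    return cols.reshape(c * k * k, n * oh * ow)


def col2im(
    cols: np.ndarray, x_shape: tuple[int, int, int, int], k: int, s: int, p: int
) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add columns back to (N,C,H,W)."""
    n, c, h, w = x_shape
    oh, ow = _out_size(h, k, s, p), _out_size(w, k, s, p)
    c6 = cols.reshape(c, k, k, n, oh, ow)
    xp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=cols.dtype)
    for ky in range(k):
        for kx in range(k):
            xp[:, :, ky : ky + s * oh : s, kx : kx + s * ow : s] += c6[
                :, ky, kx
            ].transpose(1, 0, 2, 3)
    return xp[:, :, p : p + h, p : p + w] if p else xp


def _split_channels_first(y2d: np.ndarray, n: int, c: int, oh: int, ow: int) -> np.ndarray:
    """(C, N·oh·ow) → (N, C, oh, ow)."""
    return np.ascontiguousarray(
        y2d.reshape(c, n, oh, ow).transpose(1, 0, 2, 3)
    )


def _merge_channels_first(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) → (C, N·H·W)."""
    n, c, h, w = x.shape
    return np.ascontiguousarray(x.transpose(1, 0, 2, 3)).reshape(c, n * h * w)


class Layer:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


class Conv2d(Layer):
    """Strided 2-D convolution (cross-correlation), weight (O, I, k, k)."""

    def __init__(self, in_c: int, out_c: int, k: int, stride: int, pad: int,
                 bias: bool = True, dtype=np.float32):
        self.k, self.stride, self.pad = k, stride, pad
        self.in_c, self.out_c = in_c, out_c
        self.W = Param("W", np.zeros((out_c, in_c, k, k), dtype=dtype))
        self.b = Param("b", np.zeros(out_c, dtype=dtype)) if bias else None
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, _, h, w = x.shape
        oh = _out_size(h, self.k, self.stride, self.pad)
        ow = _out_size(w, self.k, self.stride, self.pad)
        cols = im2col(x, self.k, self.stride, self.pad)  # (I·k·k, N·L)
        w2 = self.W.data.reshape(self.out_c, -1)
        y2d = w2 @ cols  # (O, N·L)
        if self.b is not None:
            y2d += self.b.data[:, None]
        self._cache = (cols, x.shape)
        return _split_channels_first(y2d, n, self.out_c, oh, ow)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, x_shape = self._cache
        dy2d = _merge_channels_first(dout.astype(self.W.data.dtype, copy=False))
        if self.b is not None:
            self.b.grad += dy2d.sum(axis=1)
        self.W.grad += (dy2d @ cols.T).reshape(self.W.data.shape)
        w2 = self.W.data.reshape(self.out_c, -1)
        return col2im(w2.T @ dy2d, x_shape, self.k, self.stride, self.pad)

    def params(self) -> list[Param]:
        return [self.W] + ([self.b] if self.b is not None else [])


class ConvTranspose2d(Layer):
    """Fractional-stride (transposed) convolution, weight (I, O, k, k).

    Output size is ``stride·(h−1) + k − 2·pad``; the forward pass is the
    adjoint of :class:`Conv2d` with the same geometry (learned upsampling).
    """

    def __init__(self, in_c: int, out_c: int, k: int, stride: int, pad: int,
                 bias: bool = True, dtype=np.float32):
        self.k, self.stride, self.pad = k, stride, pad
        self.in_c, self.out_c = in_c, out_c
        self.W = Param("W", np.zeros((in_c, out_c, k, k), dtype=dtype))
        self.b = Param("b", np.zeros(out_c, dtype=dtype)) if bias else None
        self._cache: tuple | None = None

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        s, k, p = self.stride, self.k, self.pad
        return s * (h - 1) + k - 2 * p, s * (w - 1) + k - 2 * p

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, _, h, w = x.shape
        oh, ow = self.out_shape(h, w)
        x2d = _merge_channels_first(x)  # (I, N·h·w)
        m = self.W.data.reshape(self.in_c, -1)  # (I, O·k·k)
        cols = m.T @ x2d  # (O·k·k, N·h·w)
        y = col2im(cols, (n, self.out_c, oh, ow), self.k, self.stride, self.pad)
        if self.b is not None:
            y += self.b.data[None, :, None, None]
        self._cache = (x2d, (n, self.in_c, h, w))
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x2d, x_shape = self._cache
        dout = dout.astype(self.W.data.dtype, copy=False)
        if self.b is not None:
            self.b.grad += dout.sum(axis=(0, 2, 3))
        cols_dy = im2col(dout, self.k, self.stride, self.pad)  # (O·k·k, N·h·w)
        self.W.grad += (x2d @ cols_dy.T).reshape(self.W.data.shape)
        m = self.W.data.reshape(self.in_c, -1)
        dx2d = m @ cols_dy  # (I, N·h·w)
        n, i, h, w = x_shape
        return _split_channels_first(dx2d, n, i, h, w)

    def params(self) -> list[Param]:
        return [self.W] + ([self.b] if self.b is not None else [])


class BatchNorm2d(Layer):
    """Per-channel batch normalization with learned scale/shift.

    Training mode normalizes by batch statistics and tracks running
    estimates (momentum 0.9) for eval mode.
    """

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.9, dtype=np.float32):
        self.eps, self.momentum = eps, momentum
        self.gamma = Param("gamma", np.ones(c, dtype=dtype))
        self.beta = Param("beta", np.zeros(c, dtype=dtype))
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        # which training batches update the running estimates; the training
        # loop disables tracking on generated-image batches so eval-mode
        # statistics reflect the real-image distribution the classifier sees
        self.track_running = True
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            if self.track_running:
                self.running_mean = (
                    self.momentum * self.running_mean + (1 - self.momentum) * mean
                ).astype(x.dtype)
                self.running_var = (
                    self.momentum * self.running_var + (1 - self.momentum) * var
                ).astype(x.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps).astype(x.dtype)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        self._cache = (xhat, std, train)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, std, train = self._cache
        dout = dout.astype(xhat.dtype, copy=False)
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma.data[None, :, None, None]
        if not train:
            return dxhat / std[None, :, None, None]
        mean_dxhat = dxhat.mean(axis=(0, 2, 3), keepdims=True)
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        return (dxhat - mean_dxhat - xhat * mean_dxhat_xhat) / std[None, :, None, None]

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, x * self.slope)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, dout * self.slope)


class Tanh(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._y = np.tanh(x)
        return self._y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * (1.0 - self._y**2)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()
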