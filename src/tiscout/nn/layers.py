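"""Feed-forward layers: convolution, normalisation, pooling, linear, SE block.

Convolutions use im2col + matmul; the col2im of the backward pass is a short
loop over the k*k kernel offsets (vectorised strided adds), which is both
fast and free of the overlapping-write hazards of scatter tricks.
Array layout is NCHW throughout.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import DEFAULT_DTYPE, Module, Parameter, he_init


def _im2col(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(N, C, H, W) -> contiguous (N, C, k, k, OH, OW) patch tensor."""
    windows = sliding_window_view(x, (k, k), axis=(2, 3))  # N,C,H-k+1,W-k+1,k,k
    windows = windows[:, :, ::stride, ::stride, :, :]
    return np.ascontiguousarray(windows.transpose(0, 1, 4, 5, 2, 3))


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, bias: bool = True, *,
                 rng: np.random.Generator, dtype=DEFAULT_DTYPE):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.padding = kernel, stride, padding
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(he_init(rng, (out_ch, in_ch, kernel, kernel), fan_in, dtype))
        self.bias = Parameter(np.zeros(out_ch, dtype=dtype)) if bias else None
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.padding
        if p:
            x_p = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        else:
            x_p = x
        n, c, hp, wp = x_p.shape
        oh = (hp - k) // s + 1
        ow = (wp - k) // s + 1
        cols = _im2col(x_p, k, s)                       # N,C,k,k,OH,OW
        cols2 = cols.reshape(n, c * k * k, oh * ow)
        w2 = self.weight.value.reshape(self.out_ch, c * k * k)
        y = np.einsum("of,nfp->nop", w2, cols2, optimize=True)
        if self.bias is not None:
            y += self.bias.value[None, :, None]
        self._cache = (cols2, x.shape, x_p.shape, oh, ow)
        return np.ascontiguousarray(y.reshape(n, self.out_ch, oh, ow))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols2, x_shape, xp_shape, oh, ow = self._cache
        k, s, p = self.kernel, self.stride, self.padding
        n, c = x_shape[0], x_shape[1]
        dy2 = dy.reshape(n, self.out_ch, oh * ow)
        w2 = self.weight.value.reshape(self.out_ch, c * k * k)
        if self.weight.requires_grad:
            dw = np.einsum("nop,nfp->of", dy2, cols2, optimize=True)
            self.weight.grad += dw.reshape(self.weight.value.shape)
        if self.bias is not None and self.bias.requires_grad:
            self.bias.grad += dy2.sum(axis=(0, 2))
        dcols = np.einsum("of,nop->nfp", w2, dy2, optimize=True)
        dcols = dcols.reshape(n, c, k, k, oh, ow)
        dx_p = np.zeros(xp_shape, dtype=dy.dtype)
        for i in range(k):
            for j in range(k):
                dx_p[:, :, i:i + oh * s:s, j:j + ow * s:s] += dcols[:, :, i, j]
        if p:
            dx_p = dx_p[:, :, p:-p, p:-p]
        return dx_p


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=DEFAULT_DTYPE):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))
        self._buffers = {
            "running_mean": np.zeros(channels, dtype=dtype),
            "running_var": np.ones(channels, dtype=dtype),
        }
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self._buffers["running_mean"] *= 1 - m
            self._buffers["running_mean"] += m * mean
            self._buffers["running_var"] *= 1 - m
            self._buffers["running_var"] += m * var
        else:
            mean = self._buffers["running_mean"]
            var = self._buffers["running_var"]
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        if self.gamma.requires_grad:
            self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        if self.beta.requires_grad:
            self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        if not self.training:
            return dy * g * inv_std[None, :, None, None]
        n = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dxhat = dy * g
        term1 = dxhat
        term2 = dxhat.mean(axis=(0, 2, 3), keepdims=True)
        term3 = xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        return (term1 - term2 - term3) * inv_std[None, :, None, None]


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int | None = None, padding: int = 0):
        super().__init__()
        self.kernel = kernel
        self.stride = stride if stride is not None else kernel
        self.padding = padding

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.padding
        if p:
            x_p = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)),
                         constant_values=-np.inf)
        else:
            x_p = x
        n, c, hp, wp = x_p.shape
        oh = (hp - k) // s + 1
        ow = (wp - k) // s + 1
        cols = _im2col(x_p, k, s).reshape(n, c, k * k, oh, ow)
        arg = cols.argmax(axis=2)
        y = np.take_along_axis(cols, arg[:, :, None], axis=2)[:, :, 0]
        self._cache = (arg, x.shape, (n, c, hp, wp), oh, ow)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        arg, x_shape, xp_shape, oh, ow = self._cache
        k, s, p = self.kernel, self.stride, self.padding
        dx_p = np.zeros(xp_shape, dtype=dy.dtype)
        for idx in range(k * k):
            i, j = divmod(idx, k)
            mask = arg == idx
            if not mask.any():
                continue
            dx_p[:, :, i:i + oh * s:s, j:j + ow * s:s] += dy * mask
        if p:
            dx_p = dx_p[:, :, p:-p, p:-p]
        return dx_p


class GlobalAvgPool(Module):
    """(N, C, H, W) -> (N, C)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / (h * w)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True, *,
                 rng: np.random.Generator, dtype=DEFAULT_DTYPE):
        super().__init__()
        self.weight = Parameter(he_init(rng, (out_features, in_features), in_features, dtype))
        self.bias = Parameter(np.zeros(out_features, dtype=dtype)) if bias else None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        y = x @ self.weight.value.T
        if self.bias is not None:
            y += self.bias.value
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x2 = self._x.reshape(-1, self._x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        if self.weight.requires_grad:
            self.weight.grad += dy2.T @ x2
        if self.bias is not None and self.bias.requires_grad:
            self.bias.grad += dy2.sum(axis=0)
        return (dy2 @ self.weight.value).reshape(self._x.shape)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class SEBlock(Module):
    """Squeeze-and-excitation channel recalibration (global pool -> bottleneck
    MLP -> sigmoid gate -> channel-wise rescale)."""

    def __init__(self, channels: int, reduction: int = 16, *,
                 rng: np.random.Generator, dtype=DEFAULT_DTYPE):
        super().__init__()
        hidden = max(channels // reduction, 1)
        self.fc1 = Linear(channels, hidden, rng=rng, dtype=dtype)
        self.fc2 = Linear(hidden, channels, rng=rng, dtype=dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        z = x.mean(axis=(2, 3))                       # squeeze
        a1 = self.fc1.forward(z)
        r1 = np.maximum(a1, 0)
        a2 = self.fc2.forward(r1)
        s = sigmoid(a2)                               # excitation gate
        self._cache = (x, z, a1, r1, s)
        return x * s[:, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, z, a1, r1, s = self._cache
        n, c, h, w = x.shape
        dx = dy * s[:, :, None, None]
        ds = (dy * x).sum(axis=(2, 3))
        da2 = ds * s * (1 - s)
        dr1 = self.fc2.backward(da2)
        da1 = dr1 * (a1 > 0)
        dz = self.fc1.backward(da1)
        dx += dz[:, :, None, None] / (h * w)
        return dx
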