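"""Convolution, normalization, pooling and linear layers (numpy, CPU).

Convolutions run through an im2col view assembled with k*k strided slices,
so the heavy lifting is a single BLAS contraction per layer. Backward passes
are hand-derived and validated against central differences in the test suite.
"""

from __future__ import annotations

import math
from typing import Optional, Tuple

import numpy as np

from .core import Module, Parameter


def _pair_out(size: int, k: int, stride: int, padding: int) -> int:
    return (size + 2 * padding - k) // stride + 1


def im2col(x: np.ndarray, k: int, stride: int, padding: int,
           pad_value: float = 0.0) -> Tuple[np.ndarray, int, int]:
    """Return patch tensor of shape (N, C, k, k, OH, OW)."""
    n, c, h, w = x.shape
    oh = _pair_out(h, k, stride, padding)
    ow = _pair_out(w, k, stride, padding)
    if padding:
        xp = np.full((n, c, h + 2 * padding, w + 2 * padding), pad_value,
                     dtype=x.dtype)
        xp[:, :, padding:padding + h, padding:padding + w] = x
    else:
        xp = x
    cols = np.empty((n, c, k, k, oh, ow), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i:i + stride * oh:stride,
                                  j:j + stride * ow:stride]
    return cols, oh, ow


def col2im(dcols: np.ndarray, in_shape: Tuple[int, int, int, int], k: int,
           stride: int, padding: int) -> np.ndarray:
    """Scatter-add patch gradients back to the input gradient."""
    n, c, h, w = in_shape
    oh, ow = dcols.shape[-2:]
    dxp = np.zeros((n, c, h + 2 * padding, w + 2 * padding), dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + stride * oh:stride,
                j:j + stride * ow:stride] += dcols[:, :, i, j]
    if padding:
        return dxp[:, :, padding:padding + h, padding:padding + w]
    return dxp


class Conv2d(Module):
    """2-D convolution (cross-correlation) with optional channel groups.

    groups=in_channels gives a depthwise convolution. Residual-network
    convolutions carry no bias (the following batch norm absorbs it).
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, groups: int = 1,
                 bias: bool = False, rng: Optional[np.random.Generator] = None):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError("channel counts must be divisible by groups")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.groups = groups
        rng = rng or np.random.default_rng()
        fan_out = out_channels * kernel_size * kernel_size // groups
        std = math.sqrt(2.0 / fan_out)
        shape = (out_channels, in_channels // groups, kernel_size, kernel_size)
        self.weight = Parameter(rng.normal(0.0, std, shape), "weight")
        self.bias = Parameter(np.zeros(out_channels), "bias") if bias else None
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {x.shape[1]}")
        k, s, p, g = self.kernel_size, self.stride, self.padding, self.groups
        cols, oh, ow = im2col(x, k, s, p)
        n = x.shape[0]
        cg = self.in_channels // g
        og = self.out_channels // g
        if g == 1:
            # (N,C,k,k,OH,OW) x (O,C,k,k) -> (N,OH,OW,O)
            out = np.tensordot(cols, self.weight.data, axes=([1, 2, 3], [1, 2, 3]))
            out = out.transpose(0, 3, 1, 2)
        else:
            colg = cols.reshape(n, g, cg, k, k, oh, ow)
            wg = self.weight.data.reshape(g, og, cg, k, k)
            out = np.einsum("ngcijhw,gocij->ngohw", colg, wg, optimize=True)
            out = out.reshape(n, self.out_channels, oh, ow)
        if self.bias is not None:
            out += self.bias.data[None, :, None, None]
        self._cache = (x.shape, cols)
        return np.ascontiguousarray(out)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        in_shape, cols = self._cache
        k, s, p, g = self.kernel_size, self.stride, self.padding, self.groups
        n, _, oh, ow = grad.shape
        cg = self.in_channels // g
        og = self.out_channels // g
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=(0, 2, 3))
        if g == 1:
            self.weight.grad += np.tensordot(grad, cols, axes=([0, 2, 3], [0, 4, 5]))
            dcols = np.einsum("nohw,ocij->ncijhw", grad, self.weight.data,
                              optimize=True)
        else:
            colg = cols.reshape(n, g, cg, k, k, oh, ow)
            gradg = grad.reshape(n, g, og, oh, ow)
            wg = self.weight.data.reshape(g, og, cg, k, k)
            dwg = np.einsum("ngohw,ngcijhw->gocij", gradg, colg, optimize=True)
            self.weight.grad += dwg.reshape(self.weight.data.shape)
            dcols = np.einsum("ngohw,gocij->ngcijhw", gradg, wg, optimize=True)
            dcols = dcols.reshape(n, self.in_channels, k, k, oh, ow)
        return col2im(dcols, in_shape, k, s, p)

    # deterministic accounting, independent of weights -------------------
    def out_shape(self, in_shape: Tuple[int, int, int]) -> Tuple[int, int, int]:
        _, h, w = in_shape
        return (self.out_channels,
                _pair_out(h, self.kernel_size, self.stride, self.padding),
                _pair_out(w, self.kernel_size, self.stride, self.padding))

    def param_count(self) -> int:
        n = self.weight.size
        if self.bias is not None:
            n += self.bias.size
        return n


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, num_features: int, eps: float = 1e-5,
                 momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features), "weight")
        self.bias = Parameter(np.zeros(num_features), "bias")
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = x.shape[0] * x.shape[2] * x.shape[3]
            unbiased = var * m / max(m - 1, 1)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (unbiased - self.running_var)
        else:
            mean = self.running_mean
            var = self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        self._cache = (xhat, invstd)
        return (self.weight.data[None, :, None, None] * xhat
                + self.bias.data[None, :, None, None])

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, invstd = self._cache
        self.weight.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.bias.grad += grad.sum(axis=(0, 2, 3))
        gw = (self.weight.data * invstd)[None, :, None, None]
        if not self.training:
            return grad * gw
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        grad_sum = grad.sum(axis=(0, 2, 3), keepdims=False)[None, :, None, None]
        proj = (grad * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return gw * (grad - grad_sum / m - xhat * proj / m)


class MaxPool2d(Module):
    def __init__(self, kernel_size: int = 3, stride: int = 2, padding: int = 1):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel_size, self.stride, self.padding
        cols, oh, ow = im2col(x, k, s, p, pad_value=-np.inf)
        n, c = x.shape[:2]
        flat = cols.reshape(n, c, k * k, oh, ow)
        idx = flat.argmax(axis=2)
        out = np.take_along_axis(flat, idx[:, :, None], axis=2)[:, :, 0]
        self._cache = (x.shape, idx)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        in_shape, idx = self._cache
        k, s, p = self.kernel_size, self.stride, self.padding
        n, c, oh, ow = grad.shape
        dflat = np.zeros((n, c, k * k, oh, ow), dtype=grad.dtype)
        np.put_along_axis(dflat, idx[:, :, None], grad[:, :, None], axis=2)
        return col2im(dflat.reshape(n, c, k, k, oh, ow), in_shape, k, s, p)

    def out_shape(self, in_shape: Tuple[int, int, int]) -> Tuple[int, int, int]:
        c, h, w = in_shape
        return (c, _pair_out(h, self.kernel_size, self.stride, self.padding),
                _pair_out(w, self.kernel_size, self.stride, self.padding))


class GlobalAvgPool(Module):
    """Adaptive average pooling to 1x1, returned as (N, C)."""

    def __init__(self):
        super().__init__()
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._cache
        return np.broadcast_to(grad[:, :, None, None] / (h * w),
                               (n, c, h, w)).astype(grad.dtype)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        rng = rng or np.random.default_rng()
        bound = 1.0 / math.sqrt(in_features)
        self.weight = Parameter(rng.uniform(-bound, bound,
                                            (out_features, in_features)), "weight")
        self.bias = Parameter(rng.uniform(-bound, bound, out_features),
                              "bias") if bias else None
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = x
        out = x @ self.weight.data.T
        if self.bias is not None:
            out += self.bias.data
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._cache
        self.weight.grad += grad.T @ x
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.data
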