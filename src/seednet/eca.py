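"""Efficient Channel Attention (ECA).

ECA reweights feature-map channels with almost no added cost: a global
average pool produces one descriptor per channel, a width-k 1-D convolution
shares information between each channel and its k-1 neighbours, and a
sigmoid turns the result into gates in (0, 1) that scale the input channels.

The kernel width adapts to the channel count C through

    k = |log2(C)/gamma + b/gamma|_odd        (gamma=2, b=1 by default)

where |t|_odd rounds down to the nearest integer and then up by one if that
integer is even, so k is always odd and grows logarithmically with C. The
1-D convolution is zero-padded to preserve length C and carries no bias, so
the module adds exactly k trainable scalars.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .nn.core import Module, Parameter

__all__ = ["EcaConfig", "eca_kernel_size", "EcaLayer", "eca_forward"]


@dataclass(frozen=True)
class EcaConfig:
    gamma: int = 2
    b: int = 1
    k_override: Optional[int] = None

    def __post_init__(self) -> None:
        if self.gamma < 1:
            raise ValueError("gamma must be a positive integer")
        if self.k_override is not None:
            if self.k_override < 1 or self.k_override % 2 == 0:
                raise ValueError("k_override must be an odd positive integer")


def eca_kernel_size(channels: int, cfg: EcaConfig = EcaConfig()) -> int:
    """Adaptive 1-D kernel width for a C-channel feature map."""
    if channels < 1:
        raise ValueError("channel count must be >= 1")
    if cfg.k_override is not None:
        return cfg.k_override
    t = abs(math.log2(channels) / cfg.gamma + cfg.b / cfg.gamma)
    k = int(math.floor(t))
    if k % 2 == 0:
        k += 1
    return max(k, 1)


class EcaLayer(Module):
    """Channel-attention gate: x -> sigmoid(conv1d(gap(x))) * x."""

    def __init__(self, channels: int, cfg: EcaConfig = EcaConfig()):
        super().__init__()
        self.channels = channels
        self.cfg = cfg
        self.kernel_size = eca_kernel_size(channels, cfg)
        # identity-like init: centre tap 1, neighbours 0
        w = np.zeros(self.kernel_size, dtype=np.float32)
        w[self.kernel_size // 2] = 1.0
        self.weight = Parameter(w, "weight")
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {c}")
        k = self.kernel_size
        pad = (k - 1) // 2
        y = x.mean(axis=(2, 3))                      # (N, C)
        yp = np.zeros((n, c + 2 * pad), dtype=x.dtype)
        yp[:, pad:pad + c] = y
        z = np.zeros_like(y)
        for j in range(k):
            z += self.weight.data[j] * yp[:, j:j + c]
        omega = 1.0 / (1.0 + np.exp(-z))
        self._cache = (x, yp, omega)
        return x * omega[:, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, yp, omega = self._cache
        n, c, h, w = x.shape
        k = self.kernel_size
        pad = (k - 1) // 2
        dx = grad * omega[:, :, None, None]
        domega = (grad * x).sum(axis=(2, 3))
        dz = domega * omega * (1.0 - omega)
        dyp = np.zeros_like(yp)
        for j in range(k):
            self.weight.grad[j] += float((dz * yp[:, j:j + c]).sum())
            dyp[:, j:j + c] += self.weight.data[j] * dz
        dy = dyp[:, pad:pad + c]
        dx += dy[:, :, None, None] / (h * w)
        return dx


def eca_forward(x: np.ndarray, cfg: EcaConfig = EcaConfig(),
                weight: Optional[np.ndarray] = None) -> np.ndarray:
    """Functional one-shot ECA pass on a (C, H, W) or (N, C, H, W) map."""
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    if not np.all(np.isfinite(x)):
        raise ValueError("feature map must be finite")
    layer = EcaLayer(x.shape[1], cfg)
    if weight is not None:
        weight = np.asarray(weight, dtype=np.float32)
        if weight.shape != (layer.kernel_size,):
            raise ValueError(
                f"weight must have shape ({layer.kernel_size},)")
        layer.weight.data[...] = weight
    out = layer.eval().forward(x)
    return out[0] if squeeze else out
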