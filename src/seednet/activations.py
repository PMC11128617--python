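"""Activation functions (ReLU, PReLU, Swish) and their placement spec.

The network family swaps activations site-by-site: in the mixed scheme the
stem activation and every post-addition (trunk) activation are Swish while
all remaining sites are PReLU with a learnable negative-branch slope; the
plain scheme uses ReLU everywhere. Each site owns its activation instance,
so a PReLU slope is one shared scalar per site rather than per channel —
the handful of extra scalars never moves a parameter count reported in
rounded millions.

Note on PReLU: some descriptions print the parametric rectifier as
``0 for x <= 0, alpha*x for x > 0``, which would be a scaled ReLU. The
standard definition (identity on the positive branch, ``alpha*x`` on the
negative branch) is what the original reference and the function's curve
describe, and is what this module implements.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .nn.core import Module, Parameter

__all__ = [
    "ActivationSpec", "relu", "prelu", "swish", "sigmoid",
    "ReLU", "PReLU", "Swish", "make_activation",
    "RELU_SPEC", "PRELU_SPEC", "SWISH_SPEC",
]


@dataclass(frozen=True)
class ActivationSpec:
    """Which nonlinearity a placement site uses.

    alpha_init and shared_alpha only apply to kind="prelu".
    """

    kind: str  # "relu" | "prelu" | "swish"
    alpha_init: float = 0.25
    shared_alpha: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("relu", "prelu", "swish"):
            raise ValueError(f"unknown activation kind: {self.kind!r}")
        if self.kind == "prelu" and not np.isfinite(self.alpha_init):
            raise ValueError("prelu requires a finite alpha_init")


RELU_SPEC = ActivationSpec("relu")
PRELU_SPEC = ActivationSpec("prelu", alpha_init=0.25)
SWISH_SPEC = ActivationSpec("swish")


# -- scalar/ndarray functional forms ------------------------------------

def relu(x):
    """max(0, x)."""
    return np.maximum(0.0, x)


def prelu(x, alpha):
    """x for x > 0, alpha*x otherwise (parametric rectifier)."""
    x = np.asarray(x)
    return np.where(x > 0, x, alpha * x)


def sigmoid(x):
    """Logistic function, clipped for overflow safety."""
    xa = np.asarray(x, dtype=float)
    out = 1.0 / (1.0 + np.exp(-np.clip(xa, -60.0, 60.0)))
    return out if out.ndim else float(out)


def swish(x):
    """x * sigmoid(x): smooth, lower-bounded, non-monotone below x ~ -1.28."""
    xa = np.asarray(x, dtype=float)
    out = xa * sigmoid(xa)
    return out if out.ndim else float(out)


# -- layer forms with gradients ------------------------------------------

class ReLU(Module):
    def __init__(self):
        super().__init__()
        self._mask = None

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0.0)


class PReLU(Module):
    """Parametric rectifier with one shared learnable slope per site."""

    def __init__(self, alpha_init: float = 0.25):
        super().__init__()
        self.alpha = Parameter(np.array([alpha_init]), "alpha")
        self._cache = None

    def forward(self, x):
        self._cache = x
        a = self.alpha.data[0]
        return np.where(x > 0, x, a * x)

    def backward(self, grad):
        x = self._cache
        neg = x <= 0
        self.alpha.grad[0] += float((grad * np.where(neg, x, 0.0)).sum())
        a = self.alpha.data[0]
        return np.where(neg, a * grad, grad)


class Swish(Module):
    def __init__(self):
        super().__init__()
        self._cache = None

    def forward(self, x):
        s = 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))
        self._cache = (x, s)
        return x * s

    def backward(self, grad):
        x, s = self._cache
        return grad * (s * (1.0 + x * (1.0 - s)))


def make_activation(spec: Optional[ActivationSpec]) -> Module:
    """Instantiate a fresh activation module for one placement site."""
    spec = spec or RELU_SPEC
    if spec.kind == "relu":
        return ReLU()
    if spec.kind == "prelu":
        return PReLU(alpha_init=spec.alpha_init)
    return Swish()
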