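"""Deterministic parameter and multiply-accumulate accounting.

Counts are derived from layer hyperparameters and symbolic shape
propagation, never from running data through the model, so they are exact,
weight-independent and batch-size-independent.

MAC convention (``inclusive``, the default): convolutional and fully
connected layers contribute the classic ``positions x kernel volume``
products; normalization, activation and pooling layers contribute their
per-element work (2 ops/element for an affine batch norm, 1 for a
rectifier, 2 for Swish — one sigmoid plus one product — and 1 per input
element for pooling). This is the convention under which the 6-class
50-layer baseline at 3x224x224 totals 4.12 GMac. A ``conv_fc_only`` mode
restricts the count to convolutions, the attention 1-D conv and the fully
connected head. Elementwise shortcut additions are not counted in either
mode.

Reported millions/GMac are rounded half-away-from-zero to 2 decimals, the
convention used in the printed tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Tuple

import numpy as np

from .activations import PReLU, ReLU, Swish
from .blocks import DepthwiseSeparableConv, _ResidualBase
from .eca import EcaLayer
from .network_builder import SeedNet
from .nn.core import Module, Sequential
from .nn.layers import (BatchNorm2d, Conv2d, GlobalAvgPool, Linear, MaxPool2d)

__all__ = ["ComplexityReport", "count_params", "count_macs", "analyze"]

Shape = Tuple[int, ...]  # (C, H, W) for maps, (C,) for vectors


def round2(x: float) -> float:
    """Round half away from zero to 2 decimals (table convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"),
                                           rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ComplexityReport:
    params_raw: int
    macs_raw: int
    input_shape: Tuple[int, int, int]

    @property
    def params_M(self) -> float:
        return round2(self.params_raw / 1e6)

    @property
    def macs_GMac(self) -> float:
        return round2(self.macs_raw / 1e9)

    def as_dict(self) -> dict:
        return {"params_raw": self.params_raw, "params_M": self.params_M,
                "macs_raw": self.macs_raw, "macs_GMac": self.macs_GMac,
                "input_shape": list(self.input_shape)}


def count_params(model: Module) -> int:
    """Total size of all trainable tensors."""
    return int(sum(p.size for p in model.parameters()))


def _numel(shape: Shape) -> int:
    return int(np.prod(shape))


def _walk(module: Module, shape: Shape, conv_fc_only: bool) -> Tuple[int, Shape]:
    """Return (macs, out_shape) for one module applied at ``shape``."""
    if isinstance(module, Conv2d):
        out = module.out_shape(shape)
        k = module.kernel_size
        per_pos = k * k * (module.in_channels // module.groups)
        macs = _numel(out) * per_pos
        if module.bias is not None:
            macs += _numel(out)
        return macs, out
    if isinstance(module, Linear):
        macs = module.in_features * module.out_features
        if module.bias is not None:
            macs += module.out_features
        return macs, (module.out_features,)
    if isinstance(module, BatchNorm2d):
        return (0 if conv_fc_only else 2 * _numel(shape)), shape
    if isinstance(module, (ReLU, PReLU)):
        return (0 if conv_fc_only else _numel(shape)), shape
    if isinstance(module, Swish):
        return (0 if conv_fc_only else 2 * _numel(shape)), shape
    if isinstance(module, MaxPool2d):
        out = module.out_shape(shape)
        k = module.kernel_size
        return (0 if conv_fc_only else k * k * _numel(out)), out
    if isinstance(module, GlobalAvgPool):
        return (0 if conv_fc_only else _numel(shape)), (shape[0],)
    if isinstance(module, EcaLayer):
        c = shape[0]
        conv = c * module.kernel_size
        if conv_fc_only:
            return conv, shape
        # pool + 1-D conv + sigmoid + channel rescale
        return _numel(shape) + conv + c + _numel(shape), shape
    if isinstance(module, DepthwiseSeparableConv):
        return _walk(module._chain, shape, conv_fc_only)
    if isinstance(module, _ResidualBase):
        macs, out = _walk(module.branch, shape, conv_fc_only)
        if module.downsample is not None:
            m2, _ = _walk(module.downsample, shape, conv_fc_only)
            macs += m2
        # the shortcut addition itself is not counted
        if module.post_add_norm is not None:
            m2, out = _walk(module.post_add_norm, out, conv_fc_only)
            macs += m2
        if module.post_add_activation is not None:
            m2, out = _walk(module.post_add_activation, out, conv_fc_only)
            macs += m2
        return macs, out
    if isinstance(module, Sequential):
        total = 0
        for layer in module:
            macs, shape = _walk(layer, shape, conv_fc_only)
            total += macs
        return total, shape
    if isinstance(module, SeedNet):
        total, shape = _walk(module.stem, shape, conv_fc_only)
        for stage in module.stages:
            macs, shape = _walk(stage, shape, conv_fc_only)
            total += macs
        macs, shape = _walk(module.global_pool, shape, conv_fc_only)
        total += macs
        macs, shape = _walk(module.fc, shape, conv_fc_only)
        return total + macs, shape
    raise TypeError(f"no complexity rule for {type(module).__name__}")


def count_macs(model: Module, input_shape: Tuple[int, int, int] = (3, 224, 224),
               conv_fc_only: bool = False) -> int:
    """Multiply-accumulate operations for one forward pass."""
    macs, _ = _walk(model, tuple(input_shape), conv_fc_only)
    return int(macs)


def analyze(model: Module, input_shape: Tuple[int, int, int] = (3, 224, 224),
            conv_fc_only: bool = False) -> ComplexityReport:
    return ComplexityReport(params_raw=count_params(model),
                            macs_raw=count_macs(model, input_shape,
                                                conv_fc_only),
                            input_shape=tuple(input_shape))
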