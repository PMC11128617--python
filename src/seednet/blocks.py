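"""Residual building blocks.

Four block families share the bottleneck shape (1x1 reduce, 3x3 spatial,
1x1 expand, expansion factor 4):

* baseline — classic post-activation bottleneck: every conv is followed by
  batch norm, and a trunk activation sits after the shortcut addition.
* ResStage start/middle/end — a stage-level reorganization. The Start block
  ends its branch with a batch norm and performs a bare addition (no trunk
  activation); Middle blocks are pre-activation (norm + activation at branch
  entry, bare addition); the End block normalizes and activates *after* its
  addition, handing a clean signal to the next stage. The block immediately
  after a Start block skips its entry norm because the Start branch already
  ends in one — this bookkeeping is exactly what keeps a whole stage's
  parameter count identical to the baseline stage. On the shortcut trunk, a
  stage organized this way carries a single activation (the End block's)
  regardless of its depth.
* improved — post-activation bottleneck whose branch inserts an efficient
  channel-attention gate after the first conv's activation and replaces the
  3x3 spatial conv by a depthwise-separable pair, cutting 9*m^2 conv weights
  down to 9*m + m^2 per block.

Strides (2 at stage entry) always live in the 3x3/depthwise conv; projection
shortcuts are a 1x1 strided conv plus batch norm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .activations import RELU_SPEC, ActivationSpec, make_activation
from .eca import EcaConfig, EcaLayer, eca_kernel_size
from .nn.core import Module, Sequential
from .nn.layers import BatchNorm2d, Conv2d

__all__ = [
    "BlockSpec", "DepthwiseSeparableConv", "make_ds_conv",
    "BaselineBottleneck", "StartBlock", "MiddleBlock", "EndBlock",
    "ImprovedBottleneck", "make_baseline_block", "make_resstage_block",
    "make_improved_block", "make_block",
]

EXPANSION = 4
_ROLES = ("baseline", "start", "middle", "end", "improved")


@dataclass
class BlockSpec:
    """Declarative description of one residual block."""

    role: str
    in_channels: int
    mid_channels: int
    out_channels: int
    stride: int = 1
    trunk_activation: ActivationSpec = field(default_factory=lambda: RELU_SPEC)
    branch_activation: ActivationSpec = field(default_factory=lambda: RELU_SPEC)
    attention: Optional[EcaConfig] = None
    conv2_kind: str = "standard3x3"
    entry_norm: bool = True  # middle/end only; False right after a Start block

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValueError(f"invalid block role: {self.role!r}")
        if self.out_channels != EXPANSION * self.mid_channels:
            raise ValueError("bottleneck expansion requires out = 4 * mid")
        if self.stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        if self.conv2_kind not in ("standard3x3", "depthwise_separable"):
            raise ValueError(f"invalid conv2_kind: {self.conv2_kind!r}")
        if self.role == "improved" and self.attention is None:
            raise ValueError("improved block requires an attention config")

    @property
    def needs_projection(self) -> bool:
        return self.stride != 1 or self.in_channels != self.out_channels


class DepthwiseSeparableConv(Module):
    """3x3 depthwise conv + 1x1 pointwise conv.

    Each sub-conv is followed by batch norm; a single activation sits between
    the two. Conv parameters: 9*in_ch + in_ch*out_ch (versus 9*in_ch*out_ch
    for a standard 3x3).
    """

    def __init__(self, in_ch: int, out_ch: int, stride: int = 1,
                 activation: ActivationSpec = RELU_SPEC,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        if in_ch < 1 or out_ch < 1:
            raise ValueError("channel counts must be positive")
        self.depthwise = Conv2d(in_ch, in_ch, 3, stride=stride, padding=1,
                                groups=in_ch, rng=rng)
        self.bn_dw = BatchNorm2d(in_ch)
        self.act = make_activation(activation)
        self.pointwise = Conv2d(in_ch, out_ch, 1, rng=rng)
        self.bn_pw = BatchNorm2d(out_ch)
        self._chain = Sequential(self.depthwise, self.bn_dw, self.act,
                                 self.pointwise, self.bn_pw)

    def forward(self, x):
        return self._chain(x)

    def backward(self, grad):
        return self._chain.backward(grad)

    def conv_param_count(self) -> int:
        return self.depthwise.param_count() + self.pointwise.param_count()


def make_ds_conv(in_ch: int, out_ch: int, stride: int = 1,
                 activation: ActivationSpec = RELU_SPEC,
                 rng: Optional[np.random.Generator] = None
                 ) -> DepthwiseSeparableConv:
    return DepthwiseSeparableConv(in_ch, out_ch, stride, activation, rng=rng)


def _projection(spec: BlockSpec, rng) -> Optional[Sequential]:
    if not spec.needs_projection:
        return None
    return Sequential(
        Conv2d(spec.in_channels, spec.out_channels, 1, stride=spec.stride,
               rng=rng),
        BatchNorm2d(spec.out_channels),
    )


class _ResidualBase(Module):
    """Shared add-then-maybe-activate plumbing."""

    role: str = "baseline"

    def __init__(self) -> None:
        super().__init__()
        self.branch: Sequential = Sequential()
        self.downsample: Optional[Sequential] = None
        self.post_add_activation: Optional[Module] = None
        self.post_add_norm: Optional[BatchNorm2d] = None

    def forward(self, x):
        out = self.branch(x) + (self.downsample(x) if self.downsample else x)
        if self.post_add_norm is not None:
            out = self.post_add_norm(out)
        if self.post_add_activation is not None:
            out = self.post_add_activation(out)
        return out

    def backward(self, grad):
        if self.post_add_activation is not None:
            grad = self.post_add_activation.backward(grad)
        if self.post_add_norm is not None:
            grad = self.post_add_norm.backward(grad)
        db = self.branch.backward(grad)
        di = self.downsample.backward(grad) if self.downsample else grad
        return db + di


class BaselineBottleneck(_ResidualBase):
    role = "baseline"

    def __init__(self, spec: BlockSpec, rng=None):
        super().__init__()
        if spec.role != "baseline":
            raise ValueError("spec.role must be 'baseline'")
        m, o = spec.mid_channels, spec.out_channels
        self.branch = Sequential(
            Conv2d(spec.in_channels, m, 1, rng=rng), BatchNorm2d(m),
            make_activation(spec.branch_activation),
            Conv2d(m, m, 3, stride=spec.stride, padding=1, rng=rng),
            BatchNorm2d(m),
            make_activation(spec.branch_activation),
            Conv2d(m, o, 1, rng=rng), BatchNorm2d(o),
        )
        self.downsample = _projection(spec, rng)
        self.post_add_activation = make_activation(spec.trunk_activation)


class StartBlock(_ResidualBase):
    """Stage opener: branch ends in a norm, bare addition afterwards."""

    role = "start"

    def __init__(self, spec: BlockSpec, rng=None):
        super().__init__()
        if spec.role != "start":
            raise ValueError("spec.role must be 'start'")
        m, o = spec.mid_channels, spec.out_channels
        self.branch = Sequential(
            Conv2d(spec.in_channels, m, 1, rng=rng), BatchNorm2d(m),
            make_activation(spec.branch_activation),
            Conv2d(m, m, 3, stride=spec.stride, padding=1, rng=rng),
            BatchNorm2d(m),
            make_activation(spec.branch_activation),
            Conv2d(m, o, 1, rng=rng), BatchNorm2d(o),
        )
        self.downsample = _projection(spec, rng)


class MiddleBlock(_ResidualBase):
    """Pre-activation interior block; identity shapes only, bare addition."""

    role = "middle"

    def __init__(self, spec: BlockSpec, rng=None):
        super().__init__()
        if spec.role != "middle":
            raise ValueError("spec.role must be 'middle'")
        if spec.needs_projection:
            raise ValueError("middle blocks keep identity shape")
        m, o = spec.mid_channels, spec.out_channels
        entry = []
        if spec.entry_norm:
            entry.append(BatchNorm2d(spec.in_channels))
        entry.append(make_activation(spec.branch_activation))
        self.branch = Sequential(
            *entry,
            Conv2d(spec.in_channels, m, 1, rng=rng), BatchNorm2d(m),
            make_activation(spec.branch_activation),
            Conv2d(m, m, 3, stride=1, padding=1, rng=rng), BatchNorm2d(m),
            make_activation(spec.branch_activation),
            Conv2d(m, o, 1, rng=rng),
        )


class EndBlock(_ResidualBase):
    """Stage closer: addition, then norm and the stage's trunk activation."""

    role = "end"

    def __init__(self, spec: BlockSpec, rng=None):
        super().__init__()
        if spec.role != "end":
            raise ValueError("spec.role must be 'end'")
        if spec.needs_projection:
            raise ValueError("end blocks keep identity shape")
        m, o = spec.mid_channels, spec.out_channels
        entry = []
        if spec.entry_norm:
            entry.append(BatchNorm2d(spec.in_channels))
        entry.append(make_activation(spec.branch_activation))
        self.branch = Sequential(
            *entry,
            Conv2d(spec.in_channels, m, 1, rng=rng), BatchNorm2d(m),
            make_activation(spec.branch_activation),
            Conv2d(m, m, 3, stride=1, padding=1, rng=rng), BatchNorm2d(m),
            make_activation(spec.branch_activation),
            Conv2d(m, o, 1, rng=rng),
        )
        self.post_add_norm = BatchNorm2d(o)
        self.post_add_activation = make_activation(spec.trunk_activation)


class ImprovedBottleneck(_ResidualBase):
    """Bottleneck with channel attention and (optionally) separable conv."""

    role = "improved"

    def __init__(self, spec: BlockSpec, rng=None):
        super().__init__()
        if spec.role != "improved":
            raise ValueError("spec.role must be 'improved'")
        if spec.attention is None:
            raise ValueError("improved block requires an attention config")
        m, o = spec.mid_channels, spec.out_channels
        self.eca = EcaLayer(m, spec.attention)
        if spec.conv2_kind == "depthwise_separable":
            conv2 = [DepthwiseSeparableConv(m, m, stride=spec.stride,
                                            activation=spec.branch_activation,
                                            rng=rng)]
        else:
            conv2 = [Conv2d(m, m, 3, stride=spec.stride, padding=1, rng=rng),
                     BatchNorm2d(m),
                     make_activation(spec.branch_activation)]
        self.branch = Sequential(
            Conv2d(spec.in_channels, m, 1, rng=rng), BatchNorm2d(m),
            make_activation(spec.branch_activation),
            self.eca,
            *conv2,
            Conv2d(m, o, 1, rng=rng), BatchNorm2d(o),
        )
        self.downsample = _projection(spec, rng)
        self.post_add_activation = make_activation(spec.trunk_activation)


def make_baseline_block(spec: BlockSpec, rng=None) -> BaselineBottleneck:
    return BaselineBottleneck(spec, rng=rng)


def make_resstage_block(spec: BlockSpec, rng=None) -> _ResidualBase:
    if spec.role == "start":
        return StartBlock(spec, rng=rng)
    if spec.role == "middle":
        return MiddleBlock(spec, rng=rng)
    if spec.role == "end":
        return EndBlock(spec, rng=rng)
    raise ValueError(f"not a stage role: {spec.role!r}")


def make_improved_block(spec: BlockSpec, rng=None) -> ImprovedBottleneck:
    return ImprovedBottleneck(spec, rng=rng)


def make_block(spec: BlockSpec, rng=None) -> _ResidualBase:
    if spec.role == "baseline":
        return make_baseline_block(spec, rng=rng)
    if spec.role == "improved":
        return make_improved_block(spec, rng=rng)
    return make_resstage_block(spec, rng=rng)


def trunk_activation_count(blocks) -> int:
    """Number of activation units on the input->output trunk of a stage.

    The trunk is the shortcut/main propagation path: only activations applied
    after a block's addition lie on it (branch-entry activations act on the
    residual branch alone).
    """
    return sum(1 for b in blocks if b.post_add_activation is not None)
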