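"""Assemble the full classification networks for every ablation variant.

The family is anchored on the classic 50-layer bottleneck network: a
7x7/2 stem conv + 3x3/2 max pool, four stages of (3, 4, 6, 3) bottleneck
blocks with mid channels (64, 128, 256, 512), global average pooling and a
fully connected head. Three independent toggles select the variants:

* use_resstage    — rebuild the early stages (mid 64 and 128) as
                    Start/Middle/End stages.
* use_improved_block — rebuild the later stages (mid 256 and 512) from
                    improved blocks (channel attention + depthwise-separable
                    3x3).
* use_mixed_activation — Swish at the stem activation and at every
                    post-addition site (End blocks and improved blocks),
                    PReLU at every other site; otherwise ReLU everywhere.

(False, False, False) is the plain baseline; (True, True, True) is the full
improved model.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np

from .activations import (PRELU_SPEC, RELU_SPEC, SWISH_SPEC, ActivationSpec,
                          make_activation)
from .blocks import BlockSpec, make_block, trunk_activation_count
from .eca import EcaConfig
from .nn.core import Module, Sequential
from .nn.layers import (BatchNorm2d, Conv2d, GlobalAvgPool, Linear, MaxPool2d)

__all__ = ["VariantConfig", "NetworkPlan", "SeedNet", "build_model",
           "forward", "softmax", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class VariantConfig:
    use_resstage: bool = False
    use_improved_block: bool = False
    use_mixed_activation: bool = False
    num_classes: int = 6
    input_size: int = 224
    # ablation escape hatch: keep standard 3x3 convs inside improved blocks
    improved_conv2: str = "depthwise_separable"

    def __post_init__(self) -> None:
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.input_size < 32:
            raise ValueError("input_size must be >= 32")
        if self.improved_conv2 not in ("depthwise_separable", "standard3x3"):
            raise ValueError(f"invalid improved_conv2: {self.improved_conv2!r}")

    @property
    def tag(self) -> str:
        return "".join("T" if f else "F" for f in
                       (self.use_resstage, self.use_improved_block,
                        self.use_mixed_activation))

    @classmethod
    def from_tag(cls, tag: str, **kwargs) -> "VariantConfig":
        tag = tag.upper()
        if len(tag) != 3 or set(tag) - {"T", "F"}:
            raise ValueError("tag must be three characters from {T, F}")
        return cls(use_resstage=tag[0] == "T",
                   use_improved_block=tag[1] == "T",
                   use_mixed_activation=tag[2] == "T", **kwargs)


@dataclass(frozen=True)
class NetworkPlan:
    """Stage layout; the default is the 50-layer arrangement."""

    stem_channels: int = 64
    block_counts: Tuple[int, ...] = (3, 4, 6, 3)
    mid_channels: Tuple[int, ...] = (64, 128, 256, 512)
    early_stages: int = 2  # stages rebuilt by use_resstage; the rest are "late"

    def __post_init__(self) -> None:
        if len(self.block_counts) != len(self.mid_channels):
            raise ValueError("block_counts and mid_channels must align")
        if any(n < 1 for n in self.block_counts):
            raise ValueError("each stage needs at least one block")


DEFAULT_PLAN = NetworkPlan()


class SeedNet(Module):
    """Stem -> stages -> global average pool -> fully connected head."""

    def __init__(self, cfg: VariantConfig, plan: NetworkPlan = DEFAULT_PLAN,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        self.plan = plan
        mixed = cfg.use_mixed_activation
        trunk_act = SWISH_SPEC if mixed else RELU_SPEC
        branch_act = PRELU_SPEC if mixed else RELU_SPEC

        sc = plan.stem_channels
        self.stem = Sequential(
            Conv2d(3, sc, 7, stride=2, padding=3, rng=rng),
            BatchNorm2d(sc),
            make_activation(trunk_act if mixed else RELU_SPEC),
            MaxPool2d(3, stride=2, padding=1),
        )

        self.stages: List[Sequential] = []
        in_ch = sc
        for si, (n_blocks, mid) in enumerate(zip(plan.block_counts,
                                                 plan.mid_channels)):
            stride = 1 if si == 0 else 2
            late = si >= plan.early_stages
            if cfg.use_improved_block and late:
                kind = "improved"
            elif cfg.use_resstage and not late and n_blocks >= 2:
                kind = "resstage"
            else:
                kind = "baseline"
            stage, in_ch = self._build_stage(kind, n_blocks, in_ch, mid,
                                             stride, trunk_act, branch_act,
                                             rng, cfg.improved_conv2)
            self.stages.append(stage)

        self.global_pool = GlobalAvgPool()
        self.fc = Linear(in_ch, cfg.num_classes, bias=True, rng=rng)

    @staticmethod
    def _build_stage(kind: str, n_blocks: int, in_ch: int, mid: int,
                     stride: int, trunk_act: ActivationSpec,
                     branch_act: ActivationSpec, rng,
                     improved_conv2: str = "depthwise_separable"
                     ) -> Tuple[Sequential, int]:
        out_ch = 4 * mid
        blocks = []
        for bi in range(n_blocks):
            common = dict(in_channels=in_ch if bi == 0 else out_ch,
                          mid_channels=mid, out_channels=out_ch,
                          stride=stride if bi == 0 else 1,
                          trunk_activation=trunk_act,
                          branch_activation=branch_act)
            if kind == "improved":
                spec = BlockSpec(role="improved", attention=EcaConfig(),
                                 conv2_kind=improved_conv2, **common)
            elif kind == "resstage":
                if bi == 0:
                    role = "start"
                elif bi == n_blocks - 1:
                    role = "end"
                else:
                    role = "middle"
                # the branch of a Start block already ends in a norm, so the
                # following block skips its entry norm
                spec = BlockSpec(role=role, entry_norm=(bi != 1), **common)
            else:
                spec = BlockSpec(role="baseline", **common)
            blocks.append(make_block(spec, rng=rng))
        return Sequential(*blocks), out_ch

    # -- forward / backward ---------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.fc(self.forward_features(x))

    def forward_features(self, x: np.ndarray) -> np.ndarray:
        """Pooled (N, C) features; also records per-stage maps for Grad-CAM."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError("expected input of shape (N, 3, H, W)")
        if x.shape[2] < 32 or x.shape[3] < 32:
            raise ValueError("spatial size must be >= 32")
        x = self.stem(x)
        self._stage_maps = []
        for stage in self.stages:
            x = stage(x)
            self._stage_maps.append(x)
        return self.global_pool(x)

    def backward(self, grad_logits: np.ndarray) -> np.ndarray:
        grad = self.fc.backward(grad_logits)
        grad = self.global_pool.backward(grad)
        for stage in reversed(self.stages):
            grad = stage.backward(grad)
        return self.stem.backward(grad)

    def backward_to_stage(self, grad_logits: np.ndarray,
                          stage_index: int) -> np.ndarray:
        """Gradient of the logits objective w.r.t. a stage's output map."""
        grad = self.fc.backward(grad_logits)
        grad = self.global_pool.backward(grad)
        for stage in reversed(self.stages[stage_index + 1:]):
            grad = stage.backward(grad)
        return grad

    def stage_trunk_activation_counts(self) -> List[int]:
        return [trunk_activation_count(stage) for stage in self.stages]


def build_model(cfg: VariantConfig, plan: NetworkPlan = DEFAULT_PLAN,
                rng: Optional[np.random.Generator] = None) -> SeedNet:
    """Build one ablation variant (see VariantConfig for the toggles)."""
    return SeedNet(cfg, plan=plan, rng=rng)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


def forward(model: SeedNet, batch: np.ndarray) -> np.ndarray:
    """Run one forward pass; returns (N, num_classes) logits."""
    return model(batch)


# -- checkpointing --------------------------------------------------------

def save_checkpoint(model: SeedNet, path) -> Path:
    """Weights as .npz plus a JSON sidecar recording the variant config."""
    path = Path(path).with_suffix(".npz")
    np.savez(str(path), **model.state_dict())
    sidecar = {"variant": asdict(model.cfg), "plan": asdict(model.plan)}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_checkpoint(path) -> SeedNet:
    path = Path(path).with_suffix(".npz")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    plan_kw = sidecar["plan"]
    plan_kw["block_counts"] = tuple(plan_kw["block_counts"])
    plan_kw["mid_channels"] = tuple(plan_kw["mid_channels"])
    model = build_model(VariantConfig(**sidecar["variant"]),
                        plan=NetworkPlan(**plan_kw))
    with np.load(str(path)) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
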