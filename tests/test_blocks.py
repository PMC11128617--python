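"""Residual block structure: parameter ledgers, shapes, trunk activations."""

import numpy as np
import pytest

from seednet.activations import RELU_SPEC
from seednet.blocks import (BlockSpec, DepthwiseSeparableConv, EndBlock,
                            ImprovedBottleneck, MiddleBlock, StartBlock,
                            make_baseline_block, make_block, make_ds_conv,
                            make_improved_block, make_resstage_block,
                            trunk_activation_count)
from seednet.complexity import count_params
from seednet.eca import EcaConfig, eca_kernel_size
from seednet.network_builder import SeedNet


def bottleneck_param_ledger(in_ch, mid, out_ch, projection):
    """Independent closed-form parameter count for one bottleneck block."""
    convs = in_ch * mid + 9 * mid * mid + mid * out_ch
    norms = 2 * mid + 2 * mid + 2 * out_ch
    if projection:
        convs += in_ch * out_ch
        norms += 2 * out_ch
    return convs + norms


def make_stage(kind, n, in_ch, mid, stride=1, rng=None):
    """Mirror of the builder's stage assembly for one stage in isolation."""
    out_ch = 4 * mid
    blocks = []
    for bi in range(n):
        common = dict(in_channels=in_ch if bi == 0 else out_ch,
                      mid_channels=mid, out_channels=out_ch,
                      stride=stride if bi == 0 else 1)
        if kind == "resstage":
            role = ("start" if bi == 0 else
                    "end" if bi == n - 1 else "middle")
            spec = BlockSpec(role=role, entry_norm=(bi != 1), **common)
        elif kind == "improved":
            spec = BlockSpec(role="improved", attention=EcaConfig(),
                             conv2_kind="depthwise_separable", **common)
        else:
            spec = BlockSpec(role="baseline", **common)
        blocks.append(make_block(spec, rng=rng))
    return blocks


class TestBlockSpec:
    def test_expansion_enforced(self):
        with pytest.raises(ValueError):
            BlockSpec("baseline", 64, 64, 128)

    def test_invalid_role_and_stride(self):
        with pytest.raises(ValueError):
            BlockSpec("fancy", 64, 64, 256)
        with pytest.raises(ValueError):
            BlockSpec("baseline", 64, 64, 256, stride=3)

    def test_improved_requires_attention(self):
        with pytest.raises(ValueError):
            BlockSpec("improved", 256, 64, 256)
        with pytest.raises(ValueError):
            make_improved_block(BlockSpec("baseline", 64, 64, 256))


class TestBaselineBlock:
    def test_param_ledger_identity_shortcut(self, rng):
        block = make_baseline_block(
            BlockSpec("baseline", 256, 64, 256), rng=rng)
        assert count_params(block) == bottleneck_param_ledger(
            256, 64, 256, projection=False) == 70400

    def test_param_ledger_projection_shortcut(self, rng):
        block = make_baseline_block(
            BlockSpec("baseline", 64, 64, 256), rng=rng)
        assert count_params(block) == bottleneck_param_ledger(
            64, 64, 256, projection=True) == 75008

    def test_zero_branch_passes_shortcut_through_activation(self, rng):
        block = make_baseline_block(
            BlockSpec("baseline", 16, 4, 16), rng=rng).eval()
        for p in block.parameters():
            p.data[...] = 0.0
        # restore identity-like shortcut: no projection exists (16 -> 16)
        x = rng.normal(0, 1, (2, 16, 8, 8)).astype(np.float32)
        np.testing.assert_allclose(block.forward(x), np.maximum(x, 0),
                                   atol=1e-6)

    @pytest.mark.parametrize("stride", [1, 2])
    def test_shape_contract(self, rng, stride):
        block = make_baseline_block(
            BlockSpec("baseline", 64, 64, 256, stride=stride), rng=rng)
        x = rng.normal(0, 1, (1, 64, 56, 56)).astype(np.float32)
        out = block.forward(x)
        assert out.shape == (1, 256, 56 // stride, 56 // stride)


class TestResStage:
    @pytest.mark.parametrize("n", [2, 3, 5])
    def test_stage_parameter_count_equals_baseline(self, rng, n):
        base = make_stage("baseline", n, 32, 8, rng=rng)
        res = make_stage("resstage", n, 32, 8, rng=rng)
        assert (sum(count_params(b) for b in res)
                == sum(count_params(b) for b in base))

    def test_stage_parameter_count_matches_50_layer_stage1(self, rng):
        base = make_stage("baseline", 3, 64, 64, rng=rng)
        res = make_stage("resstage", 3, 64, 64, rng=rng)
        total = sum(count_params(b) for b in base)
        assert total == sum(count_params(b) for b in res) == 215808

    @pytest.mark.parametrize("n", [2, 3, 6])
    def test_single_trunk_activation_regardless_of_depth(self, rng, n):
        res = make_stage("resstage", n, 32, 8, rng=rng)
        assert trunk_activation_count(res) == 1
        base = make_stage("baseline", n, 32, 8, rng=rng)
        assert trunk_activation_count(base) == n

    def test_roles_and_post_add_layout(self, rng):
        start, middle, end = make_stage("resstage", 3, 32, 8, rng=rng)
        assert isinstance(start, StartBlock)
        assert isinstance(middle, MiddleBlock)
        assert isinstance(end, EndBlock)
        assert start.post_add_activation is None
        assert start.post_add_norm is None
        assert middle.post_add_activation is None
        assert end.post_add_norm is not None
        assert end.post_add_activation is not None

    def test_zero_weight_middle_block_is_identity(self, rng):
        spec = BlockSpec("middle", 32, 8, 32)
        block = make_resstage_block(spec, rng=rng).eval()
        for p in block.parameters():
            p.data[...] = 0.0
        x = rng.normal(0, 1, (2, 32, 6, 6)).astype(np.float32)
        np.testing.assert_allclose(block.forward(x), x, atol=1e-6)

    def test_middle_and_end_reject_shape_changes(self):
        with pytest.raises(ValueError):
            make_resstage_block(BlockSpec("middle", 16, 8, 32))
        with pytest.raises(ValueError):
            make_resstage_block(BlockSpec("end", 32, 8, 32, stride=2))
        with pytest.raises(ValueError):
            make_resstage_block(BlockSpec("baseline", 32, 8, 32))


class TestDepthwiseSeparable:
    @pytest.mark.parametrize("in_ch,out_ch,expected", [
        (256, 256, 9 * 256 + 256 * 256),   # 67,840
        (512, 512, 9 * 512 + 512 * 512),   # 266,752
        (3, 1, 27 + 3),
    ])
    def test_conv_param_formula(self, rng, in_ch, out_ch, expected):
        layer = make_ds_conv(in_ch, out_ch, rng=rng)
        assert layer.conv_param_count() == expected

    def test_constant_input_hand_oracle(self):
        """All-ones weights on a constant 3-channel image: each depthwise
        map is 9v in the interior, the pointwise sum is 3 x that."""
        layer = make_ds_conv(3, 1).eval()
        layer.depthwise.weight.data[...] = 1.0
        layer.pointwise.weight.data[...] = 1.0
        v = 0.7
        x = np.full((1, 3, 5, 5), v, dtype=np.float32)
        out = layer.forward(x)
        # identity-state batch norms contribute a 1/sqrt(1+eps) factor twice
        assert out[0, 0, 2, 2] == pytest.approx(3 * 9 * v, rel=1e-4)

    def test_validation(self):
        with pytest.raises(ValueError):
            make_ds_conv(0, 4)


class TestImprovedBlock:
    def test_ds_substitution_saving(self, rng):
        """Parameter saving vs the baseline block: 9m^2 - (9m + m^2)
        conv weights minus the extra norm inside the separable pair,
        plus the k attention weights."""
        m = 64
        spec_b = BlockSpec("baseline", 4 * m, m, 4 * m)
        spec_i = BlockSpec("improved", 4 * m, m, 4 * m,
                           attention=EcaConfig(),
                           conv2_kind="depthwise_separable")
        base = make_baseline_block(spec_b, rng=rng)
        imp = make_improved_block(spec_i, rng=rng)
        saving = (9 * m * m) - (9 * m + m * m) - 2 * m - eca_kernel_size(m)
        assert count_params(base) - count_params(imp) == saving

    def test_eca_kernel_width_from_mid_channels(self, rng):
        block = make_improved_block(
            BlockSpec("improved", 2048, 512, 2048, attention=EcaConfig(),
                      conv2_kind="depthwise_separable"), rng=rng)
        assert block.eca.kernel_size == 5

    def test_zero_branch_passes_shortcut_through_trunk_activation(self, rng):
        block = make_improved_block(
            BlockSpec("improved", 32, 8, 32, attention=EcaConfig(),
                      conv2_kind="depthwise_separable"), rng=rng).eval()
        for p in block.parameters():
            p.data[...] = 0.0
        x = rng.normal(0, 1, (1, 32, 8, 8)).astype(np.float32)
        np.testing.assert_allclose(block.forward(x), np.maximum(x, 0),
                                   atol=1e-6)

    def test_standard_conv2_ablation_matches_baseline_params(self, rng):
        spec = BlockSpec("improved", 256, 64, 256, attention=EcaConfig(),
                         conv2_kind="standard3x3")
        block = make_improved_block(spec, rng=rng)
        extra = eca_kernel_size(64)
        assert count_params(block) == 70400 + extra

    @pytest.mark.parametrize("kind", ["baseline", "resstage", "improved"])
    @pytest.mark.parametrize("stride", [1, 2])
    def test_stage_shape_contract(self, rng, kind, stride):
        blocks = make_stage(kind, 3, 16, 8, stride=stride, rng=rng)
        x = rng.normal(0, 1, (1, 16, 12, 12)).astype(np.float32)
        for b in blocks:
            b.eval()
            x = b.forward(x)
        assert x.shape == (1, 32, 12 // stride, 12 // stride)
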