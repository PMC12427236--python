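"""DyConv branch/fusion semantics, S2Attention contracts, bottleneck parity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from moo_reid import nn
from moo_reid.backbone import Bottleneck, count_parameters
from moo_reid.config import DyConvConfig, S2AttentionConfig
from moo_reid.dynamic import DyConv, DynamicBottleneck, S2Attention
from moo_reid.nn.tensor import Tensor


def direct_conv2d(image, kernel, dilation):
    """Sliding-window sum with explicit zero padding (shape-preserving oracle)."""
    k = kernel.shape[0]
    pad = dilation * (k - 1) // 2
    H, W = image.shape
    xp = np.pad(image, pad)
    out = np.zeros_like(image)
    for y in range(H):
        for x in range(W):
            acc = 0.0
            for i in range(k):
                for j in range(k):
                    acc += kernel[i, j] * xp[y + i * dilation, x + j * dilation]
            out[y, x] = acc
    return out


BRANCH_SPECS = [(0, 3, 1), (1, 3, 2), (2, 5, 2)]  # (branch index, kernel, dilation)


@pytest.mark.parametrize("branch,k,dil", BRANCH_SPECS)
def test_each_branch_matches_direct_convolution(rng, branch, k, dil):
    dy = DyConv(1)
    x = rng.normal(size=(7, 7))
    out = dy.branches[branch](Tensor(x[None, None])).data[0, 0]
    expect = direct_conv2d(x, dy.branches[branch].weight.data[0, 0].astype(float), dil)
    assert np.allclose(out, expect, atol=1e-5)


def test_identity_kernel_with_unit_weight_reproduces_input(rng):
    dy = DyConv(2)
    w = np.zeros_like(dy.branches[0].weight.data)
    w[:, 0, 1, 1] = 1.0  # center tap
    dy.branches[0].weight.data = w
    dy.compute_branch_weights = lambda x: Tensor(
        np.tile([1.0, 0.0, 0.0], (x.shape[0], 1))
    )
    x = rng.normal(size=(2, 2, 5, 4))
    assert np.allclose(dy(Tensor(x)).data, x, atol=1e-7)


def test_branch_weights_softmax_semantics():
    dy = DyConv(4)
    dy.gate.weight.data[:] = 0.0
    x = Tensor(np.random.default_rng(0).normal(size=(3, 4, 6, 6)))
    # equal logits -> uniform
    dy.gate.bias.data[:] = 0.0
    assert np.allclose(dy.compute_branch_weights(x).data, 1 / 3, atol=1e-7)
    # closed form: logits (ln 2, 0, 0) -> (0.5, 0.25, 0.25)
    dy.gate.bias.data = np.array([np.log(2.0), 0.0, 0.0], dtype=np.float32)
    assert np.allclose(
        dy.compute_branch_weights(x).data, [[0.5, 0.25, 0.25]] * 3, atol=1e-6
    )


def test_fixed_uniform_fusion_and_weight_normalization(rng):
    dy = DyConv(3, DyConvConfig(fusion="fixed_uniform"))
    x = Tensor(rng.normal(size=(2, 3, 4, 4)))
    w = dy.compute_branch_weights(x).data
    assert np.allclose(w.sum(axis=1), 1.0, atol=1e-6)
    dy2 = DyConv(3)
    w2 = dy2.compute_branch_weights(x).data
    assert np.allclose(w2.sum(axis=1), 1.0, atol=1e-6)
    assert (w2 >= 0).all() and (w2 <= 1).all()


def test_dyconv_rejects_channel_mismatch(rng):
    with pytest.raises(ValueError, match="channel mismatch"):
        DyConv(4)(Tensor(rng.normal(size=(1, 3, 5, 5))))


@settings(deadline=None, max_examples=20, derandomize=True)
@given(
    c=st.integers(1, 6),
    h=st.integers(1, 9),
    w=st.integers(1, 9),
    b=st.integers(1, 2),
)
def test_dyconv_preserves_shape(c, h, w, b):
    nn.seed_all(0)
    dy = DyConv(c)
    x = Tensor(np.random.default_rng(1).normal(size=(b, c, h, w)))
    assert dy(x).shape == x.shape


def test_fusion_stays_in_convex_hull_of_branches(rng):
    dy = DyConv(3)
    x = Tensor(rng.normal(size=(2, 3, 6, 6)))
    branch_outs = np.stack([br(x).data for br in dy.branches])
    out = dy(x).data
    lo, hi = branch_outs.min(axis=0), branch_outs.max(axis=0)
    assert (out >= lo - 1e-6).all() and (out <= hi + 1e-6).all()


# ---------------------------------------------------------------------------
# S2Attention
# ---------------------------------------------------------------------------

def test_s2attention_token_count_and_row_sums(rng):
    s2 = S2Attention(4, S2AttentionConfig(stride=2))
    x = Tensor(rng.normal(size=(2, 4, 24, 12)))
    attn = s2.attention_matrix(x)
    assert attn.shape == (2, 72, 72)  # N = (24/2) * (12/2)
    assert np.allclose(attn.sum(axis=2), 1.0, atol=1e-6)
    assert s2(x).shape == x.shape


@settings(deadline=None, max_examples=15, derandomize=True)
@given(
    c=st.integers(1, 5),
    h=st.integers(1, 4),
    w=st.integers(1, 4),
    stride=st.integers(1, 2),
)
def test_s2attention_preserves_shape_for_divisible_inputs(c, h, w, stride):
    nn.seed_all(0)
    H, W = h * stride, w * stride
    s2 = S2Attention(c, S2AttentionConfig(stride=stride))
    x = Tensor(np.random.default_rng(2).normal(size=(1, c, H, W)))
    assert s2(x).shape == (1, c, H, W)


def test_s2attention_degenerate_single_token(rng):
    s2 = S2Attention(3, S2AttentionConfig(stride=2))
    x = Tensor(rng.normal(size=(1, 3, 2, 2)))
    attn = s2.attention_matrix(x)
    assert attn.shape == (1, 1, 1)
    assert np.allclose(attn, 1.0)
    # attended value equals the single token's value
    q, k, v = s2._tokens(x)
    attended = (Tensor(attn) @ v).data
    assert np.allclose(attended, v.data)


def test_s2attention_rejects_indivisible_spatial_dims(rng):
    s2 = S2Attention(2, S2AttentionConfig(stride=2))
    with pytest.raises(ValueError, match="not divisible"):
        s2(Tensor(rng.normal(size=(1, 2, 3, 4))))


# ---------------------------------------------------------------------------
# DynamicBottleneck
# ---------------------------------------------------------------------------

def test_zero_expand_conv_reduces_to_gated_residual(rng):
    blk = DynamicBottleneck(8, 2, use_s2attention=False)
    blk.conv3.weight.data[:] = 0.0
    x = rng.normal(size=(2, 8, 4, 4))
    out = blk(Tensor(x)).data
    assert np.allclose(out, np.maximum(x, 0.0), atol=1e-6)


def test_dynamic_block_is_drop_in_for_standard_block(rng):
    std = Bottleneck(16, 4, stride=2)
    dyn = DynamicBottleneck(16, 4, stride=2, s2_cfg=S2AttentionConfig(stride=1))
    x = Tensor(rng.normal(size=(2, 16, 8, 8)))
    assert std(x).shape == dyn(x).shape == (2, 16, 4, 4)


def test_s2attention_adds_parameters():
    with_attn = DynamicBottleneck(16, 4, use_s2attention=True)
    without = DynamicBottleneck(16, 4, use_s2attention=False)
    assert count_parameters(without) < count_parameters(with_attn)


def test_dyconv_parameter_economy():
    for C in (16, 64, 256):
        assert count_parameters(DyConv(C)) < 9 * C * C
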