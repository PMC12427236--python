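"""Dynamic convolution, sparse spatial attention, and the residual block
combining them.

``DyConv`` runs three parallel depthwise branches — a plain k x k, a 3x3
dilated (rate d1) for local detail, and a 5x5 dilated (rate d2) for
large-scale context — and fuses them with per-sample convex weights from a
small gating head (global average pool -> linear -> softmax).  Because every
branch is depthwise, the whole module is far cheaper than a dense 3x3
convolution at the same width.

``S2Attention`` projects the map to 3C channels with a 1x1 convolution,
splits Q/K/V, average-pools each by ``stride`` so attention runs over
N = (H/stride)(W/stride) tokens, then upsamples back and applies an output
projection.

``DynamicBottleneck`` is a drop-in replacement for the standard ResNet
bottleneck: 1x1 reduce -> DyConv -> S2Attention -> 1x1 expand + residual.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .config import DyConvConfig, S2AttentionConfig
from .nn import functional as F
from .nn.tensor import Tensor

__all__ = ["DyConv", "S2Attention", "DynamicBottleneck"]


class DyConv(nn.Module):
    def __init__(self, channels: int, cfg: DyConvConfig | None = None):
        super().__init__()
        cfg = cfg or DyConvConfig()
        self.channels = channels
        self.cfg = cfg
        k = cfg.depthwise_kernel
        self.branches = nn.ModuleList(
            [
                nn.Conv2d(channels, channels, k, padding=k // 2, groups=channels),
                nn.Conv2d(
                    channels, channels, 3, padding=cfg.d1, dilation=cfg.d1, groups=channels
                ),
                nn.Conv2d(
                    channels, channels, 5, padding=2 * cfg.d2, dilation=cfg.d2, groups=channels
                ),
            ]
        )
        self.gate = nn.Linear(channels, 3)

    def compute_branch_weights(self, x) -> Tensor:
        """Per-sample convex weights over the three branches, shape (B, 3)."""
        x = nn.as_tensor(x)
        if self.cfg.fusion == "fixed_uniform":
            return Tensor(np.full((x.shape[0], 3), 1.0 / 3.0, dtype=x.dtype))
        pooled = x.mean(axis=(2, 3))  # (B, C)
        return F.softmax(self.gate(pooled), axis=1)

    def forward(self, x):
        x = nn.as_tensor(x)
        if x.shape[1] != self.channels:
            raise ValueError(
                f"channel mismatch: got {x.shape[1]}, expected {self.channels}"
            )
        w = self.compute_branch_weights(x)
        out = None
        for b, branch in enumerate(self.branches):
            term = branch(x) * w[:, b].reshape(-1, 1, 1, 1)
            out = term if out is None else out + term
        return out


class S2Attention(nn.Module):
    def __init__(self, channels: int, cfg: S2AttentionConfig | None = None):
        super().__init__()
        cfg = cfg or S2AttentionConfig()
        self.channels = channels
        self.stride = cfg.stride
        self.qkv = nn.Conv2d(channels, cfg.expansion * channels, 1)
        self.proj = nn.Conv2d(channels, channels, 1)

    def _tokens(self, x):
        """Q, K, V token matrices of shape (B, N, C) after pooled projection."""
        B, C, H, W = x.shape
        s = self.stride
        if H % s or W % s:
            raise ValueError(
                f"spatial size {H}x{W} not divisible by stride {s}"
            )
        qkv = self.qkv(x)
        out = []
        for i in range(3):
            part = qkv[:, i * C : (i + 1) * C]
            pooled = part if s == 1 else F.avg_pool2d(part, s)
            out.append(
                pooled.reshape(B, C, (H // s) * (W // s)).transpose(0, 2, 1)
            )
        return out

    def attention_matrix(self, x) -> np.ndarray:
        """Row-normalized (B, N, N) attention weights (diagnostic)."""
        x = nn.as_tensor(x)
        q, k, _ = self._tokens(x)
        scores = (q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(self.channels))
        return F.softmax(scores, axis=2).data

    def forward(self, x):
        x = nn.as_tensor(x)
        B, C, H, W = x.shape
        s = self.stride
        q, k, v = self._tokens(x)
        scores = (q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(C))
        attn = F.softmax(scores, axis=2)
        out = attn @ v  # (B, N, C)
        out = out.transpose(0, 2, 1).reshape(B, C, H // s, W // s)
        if s > 1:
            out = F.upsample_nearest(out, s)
        return self.proj(out)


class DynamicBottleneck(nn.Module):
    """Residual bottleneck with DyConv in place of the dense 3x3.

    Output channels equal ``4 * planes`` (the standard expansion); a projection
    shortcut is added when the input shape differs.  Downsampling blocks carry
    their stride on the 1x1 reduction since DyConv preserves spatial size.
    """

    expansion = 4

    def __init__(
        self,
        in_channels: int,
        planes: int,
        stride: int = 1,
        use_s2attention: bool = True,
        dyconv_cfg: DyConvConfig | None = None,
        s2_cfg: S2AttentionConfig | None = None,
        out_channels: int | None = None,
    ):
        super().__init__()
        out_channels = out_channels or planes * self.expansion
        self.conv1 = nn.Conv2d(in_channels, planes, 1, stride=stride)
        self.bn1 = nn.BatchNorm2d(planes)
        self.dyconv = DyConv(planes, dyconv_cfg)
        self.bn2 = nn.BatchNorm2d(planes)
        self.s2attention = (
            S2Attention(planes, s2_cfg) if use_s2attention else nn.Identity()
        )
        self.conv3 = nn.Conv2d(planes, out_channels, 1)
        self.bn3 = nn.BatchNorm2d(out_channels)
        self.relu = nn.ReLU()
        if stride != 1 or in_channels != out_channels:
            self.shortcut = nn.Sequential(
                nn.Conv2d(in_channels, out_channels, 1, stride=stride),
                nn.BatchNorm2d(out_channels),
            )
        else:
            self.shortcut = nn.Identity()

    def forward(self, x):
        x = nn.as_tensor(x)
        out = self.relu(self.bn1(self.conv1(x)))
        out = self.relu(self.bn2(self.dyconv(out)))
        out = self.s2attention(out)
        out = self.bn3(self.conv3(out))
        return self.relu(out + self.shortcut(x))
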