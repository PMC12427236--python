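"""Normalization-based attention (NAM).

Channel path: batch-normalize the input, weight each channel by its
normalization scale factor relative to the sum of all scale factors,

    W_a(i) = alpha_i / sum_j alpha_j,

and gate with a sigmoid, Mc = sigmoid(W_a * BN(x)).  The only trainable
parameters are the 2C batch-norm affine terms.  The spatial path mirrors
this per pixel position: statistics are taken over (batch x channels) at
each location, with a trainable per-pixel scale/shift pair; its gate Ms is
constant across channels in its weighting.  Both gates are computed from the
same input in parallel and composed multiplicatively.

The weights are signed as written — normalization divides by the *sum* of
scale factors, not of their magnitudes; ``abs_weights`` switches to the
|alpha| variant.  A zero scale-factor sum is degenerate and raises.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .config import NamConfig
from .nn.layers import _BatchNorm
from .nn.tensor import Tensor

__all__ = [
    "channel_weights",
    "NamChannelAttention",
    "NamSpatialAttention",
    "NAM",
]


def channel_weights(alpha, abs_weights: bool = False) -> np.ndarray:
    """Normalized scale-factor weights W_a(i) = alpha_i / sum_j alpha_j."""
    alpha = np.asarray(alpha, dtype=float)
    vals = np.abs(alpha) if abs_weights else alpha
    denom = vals.sum()
    if denom == 0:
        raise ValueError("degenerate scale factors: sum is zero")
    return vals / denom


class NamChannelAttention(nn.Module):
    def __init__(self, channels: int, abs_weights: bool = False):
        super().__init__()
        self.channels = channels
        self.abs_weights = abs_weights
        self.bn = nn.BatchNorm2d(channels)

    def gate(self, x) -> Tensor:
        """Elementwise channel gate Mc = sigmoid(W_a * BN(x))."""
        x = nn.as_tensor(x)
        normed = self.bn(x)
        w = channel_weights(self.bn.weight.data, self.abs_weights)
        return (normed * Tensor(w.reshape(1, -1, 1, 1))).sigmoid()

    def forward(self, x):
        x = nn.as_tensor(x)
        return x * self.gate(x)


class _PixelNorm(_BatchNorm):
    """Per-pixel batch norm on (B, S, C) token layout: statistics over
    batch and channels for each of the S positions."""

    def _stats_axes(self, x):
        return (0, 2)

    def _shape(self, x):
        return (1, self.num_features, 1)


class NamSpatialAttention(nn.Module):
    def __init__(self, height: int, width: int, abs_weights: bool = False):
        super().__init__()
        self.height, self.width = height, width
        self.abs_weights = abs_weights
        self.bn = _PixelNorm(height * width)

    def gate(self, x) -> Tensor:
        """Elementwise spatial gate Ms = sigmoid(W_px * BN_px(x))."""
        x = nn.as_tensor(x)
        B, C, H, W = x.shape
        if (H, W) != (self.height, self.width):
            raise ValueError(
                f"spatial size {H}x{W} does not match module ({self.height}x{self.width})"
            )
        tokens = x.reshape(B, C, H * W).transpose(0, 2, 1)  # (B, S, C)
        normed = self.bn(tokens)
        w = channel_weights(self.bn.weight.data, self.abs_weights)
        gated = (normed * Tensor(w.reshape(1, -1, 1))).sigmoid()
        return gated.transpose(0, 2, 1).reshape(B, C, H, W)

    def forward(self, x):
        x = nn.as_tensor(x)
        return x * self.gate(x)


class NAM(nn.Module):
    """Parallel channel + spatial gates, composed multiplicatively:
    out = x * Mc * Ms (spatial path optional)."""

    def __init__(
        self,
        channels: int,
        spatial_size: tuple[int, int] | None = None,
        cfg: NamConfig | None = None,
    ):
        super().__init__()
        cfg = cfg or NamConfig()
        self.channel = NamChannelAttention(channels, cfg.abs_weights)
        if cfg.spatial_enabled:
            if spatial_size is None:
                raise ValueError("spatial_enabled requires spatial_size")
            self.spatial = NamSpatialAttention(*spatial_size, cfg.abs_weights)
        else:
            self.spatial = None

    def forward(self, x):
        x = nn.as_tensor(x)
        mc = self.channel.gate(x)
        if self.spatial is None:
            return x * mc
        ms = self.spatial.gate(x)
        return x * mc * ms
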