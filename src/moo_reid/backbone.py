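"""Modified ResNet50 backbone for coat-pattern retrieval.

The assembly follows the standard ResNet50 feature extractor (7x7 stem,
max-pool, four stages of bottleneck blocks with [3, 4, 6, 3] repeats and
stage widths 256/512/1024/2048, global average pooling, no classifier) with
three modifications controlled by :class:`~moo_reid.config.ModelConfig`:

* stages 1 and 4 may swap every bottleneck for a
  :class:`~moo_reid.dynamic.DynamicBottleneck` (DyConv + S2Attention),
* a NAM attention head may gate the stage-4 output before pooling,
* stages 2-3 can be narrowed by ``width_factor_23`` (internal squeezed
  channels only, so inter-stage interfaces are unchanged).

With an all-standard stage plan and every flag off the model is a textbook
ResNet50 feature extractor; ``count_parameters`` then returns 23,508,032.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .config import ModelConfig
from .dynamic import DynamicBottleneck
from .nam import NAM
from .nn.tensor import Tensor

__all__ = [
    "Bottleneck",
    "CowReIDBackbone",
    "build_backbone",
    "count_parameters",
    "parameter_report",
    "extract_features",
    "ReportRow",
]

_BLOCKS_PER_STAGE = (3, 4, 6, 3)


def stage_spatial_sizes(input_size) -> list[tuple[int, int]]:
    """(H, W) after the stem and after each of the four stages."""

    def down(n, k, s, p):
        return (n + 2 * p - k) // s + 1

    h, w = input_size
    h, w = down(h, 7, 2, 3), down(w, 7, 2, 3)  # stem conv
    h, w = down(h, 3, 2, 1), down(w, 3, 2, 1)  # stem max-pool
    sizes = [(h, w)]  # stage 1 preserves the stem size
    for _ in range(3):
        h, w = down(h, 3, 2, 1), down(w, 3, 2, 1)
        sizes.append((h, w))
    return sizes


class Bottleneck(nn.Module):
    """Standard ResNet bottleneck: 1x1 reduce -> 3x3 (stride here) -> 1x1 expand."""

    expansion = 4

    def __init__(self, in_channels, planes, stride=1, out_channels=None):
        super().__init__()
        out_channels = out_channels or planes * self.expansion
        self.conv1 = nn.Conv2d(in_channels, planes, 1)
        self.bn1 = nn.BatchNorm2d(planes)
        self.conv2 = nn.Conv2d(planes, planes, 3, stride=stride, padding=1)
        self.bn2 = nn.BatchNorm2d(planes)
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
        out = self.relu(self.bn1(self.conv1(x)))
        out = self.relu(self.bn2(self.conv2(out)))
        out = self.bn3(self.conv3(out))
        return self.relu(out + self.shortcut(x))


class CowReIDBackbone(nn.Module):
    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        stem_out = config.channels_per_stage[0] // 4
        self.conv1 = nn.Conv2d(3, stem_out, 7, stride=2, padding=3)
        self.bn1 = nn.BatchNorm2d(stem_out)
        self.relu = nn.ReLU()
        self.maxpool = nn.MaxPool2d(3, 2, 1)

        in_ch = stem_out
        stages = []
        for si in range(4):
            out_ch = config.channels_per_stage[si]
            planes = out_ch // 4
            if si in (1, 2):
                planes = max(1, int(round(planes * config.width_factor_23)))
            stride = 1 if si == 0 else 2
            dynamic = config.stage_plan[si] == "dynamic"
            blocks = []
            for bi in range(_BLOCKS_PER_STAGE[si]):
                s = stride if bi == 0 else 1
                if dynamic:
                    blocks.append(
                        DynamicBottleneck(
                            in_ch,
                            planes,
                            stride=s,
                            use_s2attention=config.use_s2attention,
                            dyconv_cfg=config.dyconv,
                            s2_cfg=config.s2attention,
                            out_channels=out_ch,
                        )
                    )
                else:
                    blocks.append(
                        Bottleneck(in_ch, planes, stride=s, out_channels=out_ch)
                    )
                in_ch = out_ch
            stages.append(nn.Sequential(*blocks))
        self.stage1, self.stage2, self.stage3, self.stage4 = stages

        final_ch = config.channels_per_stage[3]
        if config.use_nam and config.nam.enabled:
            self.nam = NAM(
                final_ch,
                spatial_size=stage_spatial_sizes(config.input_size)[3],
                cfg=config.nam,
            )
        else:
            self.nam = None
        if config.embedding_dim is not None:
            self.embed = nn.Linear(final_ch, config.embedding_dim)
        else:
            self.embed = None

    @property
    def embedding_dim(self) -> int:
        if self.embed is not None:
            return self.config.embedding_dim
        return self.config.channels_per_stage[3]

    def forward_features(self, x) -> dict[str, Tensor]:
        """Stage-by-stage activations; key 'final' is the NAM-gated stage-4 map."""
        x = nn.as_tensor(x)
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError("expected input of shape (B, 3, H, W)")
        h, w = self.config.input_size
        if x.shape[2] != h or x.shape[3] != w:
            raise ValueError(
                f"input size {x.shape[2]}x{x.shape[3]} does not match configured {h}x{w}"
            )
        out = {}
        x = self.maxpool(self.relu(self.bn1(self.conv1(x))))
        out["stem"] = x
        for name in ("stage1", "stage2", "stage3", "stage4"):
            x = getattr(self, name)(x)
            out[name] = x
        if self.nam is not None:
            x = self.nam(x)
        out["final"] = x
        return out

    def forward(self, x) -> Tensor:
        """Pooled embedding, shape (B, embedding_dim)."""
        final = self.forward_features(x)["final"]
        pooled = final.mean(axis=(2, 3))
        if self.embed is not None:
            pooled = self.embed(pooled)
        return pooled


def build_backbone(config: ModelConfig | None = None) -> CowReIDBackbone:
    return CowReIDBackbone(config or ModelConfig())


def count_parameters(model: nn.Module) -> int:
    """Number of trainable scalar parameters (conv kernels, BN affine, linear)."""
    return int(sum(p.size for p in model.parameters()))


@dataclass
class ReportRow:
    path: str
    count: int
    delta: int | None = None


def parameter_report(model: nn.Module, baseline=None) -> list[ReportRow]:
    """Per-module parameter table whose counts sum to ``count_parameters``.

    Each row covers one module's *directly owned* parameters.  ``baseline``
    may be another model or a previous report; rows whose paths match get a
    delta column (and a delta-only row is emitted for paths unique to either
    side, so the deltas also reconcile the totals).
    """
    rows = []
    for path, mod in model.named_modules():
        own = sum(p.size for p in mod._params.values() if p is not None)
        if own:
            rows.append(ReportRow(path=path or "<root>", count=int(own)))
    if baseline is not None:
        if isinstance(baseline, nn.Module):
            baseline = parameter_report(baseline)
        base = {r.path: r.count for r in baseline}
        for r in rows:
            r.delta = r.count - base.pop(r.path, 0)
        for path, count in base.items():
            rows.append(ReportRow(path=path, count=0, delta=-count))
    return rows


def extract_features(model: CowReIDBackbone, x) -> tuple[np.ndarray, np.ndarray]:
    """Final feature map and pooled embeddings for a normalized input batch.

    Deterministic in eval mode; returns plain arrays (no graph is built).
    """
    with nn.no_grad():
        feats = model.forward_features(x)
        final = feats["final"]
        pooled = final.mean(axis=(2, 3))
        if model.embed is not None:
            pooled = model.embed(pooled)
    return final.data, pooled.data
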