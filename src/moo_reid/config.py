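"""Configuration dataclasses and YAML round-trip.

The YAML layout mirrors the module structure::

    model:
      input_size: [384, 192]
      stage_plan: [dynamic, standard, standard, dynamic]
      dyconv: {depthwise_kernel: 3, d1: 2, d2: 2, fusion: dynamic_softmax}
      s2attention: {stride: 2}
      nam: {enabled: true, abs_weights: false, spatial_enabled: false}
      qaconv: {enabled: true, patch_size: 1, feature_stage: 1}
    train:
      epochs: 80
      ...
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

__all__ = [
    "DyConvConfig",
    "S2AttentionConfig",
    "NamConfig",
    "QAConvConfig",
    "ModelConfig",
    "TrainConfig",
    "load_yaml",
    "save_yaml",
]


@dataclass
class DyConvConfig:
    """Three-branch dynamic convolution: depthwise k x k plus two dilated
    depthwise branches (3x3 rate d1 for local detail, 5x5 rate d2 for
    context).  Padding always preserves the spatial size."""

    depthwise_kernel: int = 3
    d1: int = 2
    d2: int = 2
    fusion: str = "dynamic_softmax"  # or "fixed_uniform"

    def __post_init__(self):
        if self.depthwise_kernel % 2 == 0:
            raise ValueError("depthwise_kernel must be odd")
        if self.fusion not in ("dynamic_softmax", "fixed_uniform"):
            raise ValueError(f"unknown fusion mode {self.fusion!r}")


@dataclass
class S2AttentionConfig:
    """Sparse spatial attention over average-pooled tokens.

    ``stride`` is the down-sampling factor (token count N = (H/stride)(W/stride));
    the channel expansion of the Q/K/V projection is fixed at 3.
    """

    stride: int = 2
    expansion: int = 3

    def __post_init__(self):
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.expansion != 3:
            raise ValueError("Q/K/V expansion is fixed at 3")


@dataclass
class NamConfig:
    enabled: bool = True
    abs_weights: bool = False
    spatial_enabled: bool = False


@dataclass
class QAConvConfig:
    enabled: bool = True
    patch_size: int = 1
    feature_stage: int = 1  # 1-4; stage whose maps feed the matcher

    def __post_init__(self):
        if self.patch_size % 2 == 0:
            raise ValueError("patch_size must be odd")
        if not 1 <= self.feature_stage <= 4:
            raise ValueError("feature_stage must be in 1..4")


@dataclass
class ModelConfig:
    input_size: tuple[int, int] = (384, 192)  # (height, width)
    stage_plan: tuple[str, str, str, str] = (
        "dynamic",
        "standard",
        "standard",
        "dynamic",
    )
    channels_per_stage: tuple[int, int, int, int] = (256, 512, 1024, 2048)
    width_factor_23: float = 1.0
    embedding_dim: int | None = None  # None: raw post-pool width
    use_s2attention: bool = True
    use_nam: bool = True
    use_qaconv: bool = True
    dyconv: DyConvConfig = field(default_factory=DyConvConfig)
    s2attention: S2AttentionConfig = field(default_factory=S2AttentionConfig)
    nam: NamConfig = field(default_factory=NamConfig)
    qaconv: QAConvConfig = field(default_factory=QAConvConfig)

    def __post_init__(self):
        self.input_size = tuple(self.input_size)
        self.stage_plan = tuple(self.stage_plan)
        self.channels_per_stage = tuple(self.channels_per_stage)
        if isinstance(self.dyconv, dict):
            self.dyconv = DyConvConfig(**self.dyconv)
        if isinstance(self.s2attention, dict):
            self.s2attention = S2AttentionConfig(**self.s2attention)
        if isinstance(self.nam, dict):
            self.nam = NamConfig(**self.nam)
        if isinstance(self.qaconv, dict):
            self.qaconv = QAConvConfig(**self.qaconv)
        if len(self.stage_plan) != 4:
            raise ValueError("stage_plan must have exactly 4 entries")
        for entry in self.stage_plan:
            if entry not in ("standard", "dynamic"):
                raise ValueError(f"unknown stage plan entry {entry!r}")
        if not 0.0 < self.width_factor_23 <= 1.0:
            raise ValueError("width_factor_23 must be in (0, 1]")
        h, w = self.input_size
        if h % 16 or w % 16:
            raise ValueError(
                "input height and width must be divisible by 16 (stride budget)"
            )


@dataclass
class TrainConfig:
    epochs: int = 80
    batch_size: int = 16
    learning_rate: float = 1e-4
    momentum: float = 0.9  # Adam first-moment decay beta1
    optimizer: str = "adam"  # or "sgd" (plain momentum)
    padding: int = 10
    margin: float = 0.3
    num_instances: int = 4  # K in the P x K identity sampler
    seed: int = 0
    # Freeze batch-norm statistics at their initial values during training.
    # Intended for small-scale from-scratch runs, where running estimates
    # converge orders of magnitude faster than the weights and decouple
    # train-mode from eval-mode behaviour.
    freeze_bn: bool = False
    augmentations: tuple[str, ...] = (
        "random_crop",
        "random_erasing",
        "horizontal_flip",
    )

    def __post_init__(self):
        self.augmentations = tuple(self.augmentations)
        if self.num_instances < 2:
            raise ValueError("num_instances (K) must be >= 2")
        if self.batch_size % self.num_instances:
            raise ValueError("batch_size must be P * num_instances")
        for aug in self.augmentations:
            if aug not in ("random_crop", "random_erasing", "horizontal_flip"):
                raise ValueError(f"unknown augmentation {aug!r}")


def _build(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if dataclasses.is_dataclass(f.type) or f.name in (
            "dyconv",
            "s2attention",
            "nam",
            "qaconv",
        ):
            sub = {
                "dyconv": DyConvConfig,
                "s2attention": S2AttentionConfig,
                "nam": NamConfig,
                "qaconv": QAConvConfig,
            }[f.name]
            v = _build(sub, v) if isinstance(v, dict) else v
        kwargs[f.name] = v
    return cls(**kwargs)


def load_yaml(path) -> tuple[ModelConfig, TrainConfig]:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    model = _build(ModelConfig, raw.get("model", {}))
    train = _build(TrainConfig, raw.get("train", {}))
    return model, train


def _as_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _as_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def save_yaml(path, model: ModelConfig, train: TrainConfig | None = None) -> None:
    doc = {"model": _as_plain(model)}
    if train is not None:
        doc["train"] = _as_plain(train)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
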