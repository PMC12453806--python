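"""Model and pipeline configuration.

The default :class:`ModelConfig` is the full-size screening network:
embedding width C=32, four stages with transformer depths (2, 2, 6, 2) and
CNN depths (1, 2, 2, 1), 7x7 attention windows and downsampling strides
(4, 2, 2, 2).  Per-stage feature dims are C * (1, 2, 4, 8) in both branches.

Head counts: the printed pairing (3, 6, 12, 24) does not divide the stage
dims produced by C=32, so by default heads are resolved to keep a head dim
of 16 per stage (2, 4, 8, 16).  Setting ``heads`` explicitly restores any
other pairing when the chosen C allows it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class ModelConfig:
    embed_dim: int = 32
    transformer_depths: tuple = (2, 2, 6, 2)
    cnn_depths: tuple = (1, 2, 2, 1)
    heads: tuple | None = None          # None -> head_dim 16 per stage
    window_size: int = 7
    mlp_ratio: float = 4.0
    num_classes: int = 4
    img_size: int = 224
    drop_path: float = 0.1
    se_reduction: int = 16
    adaptive_mlp_ratio: float = 2.0
    ln_eps: float = 1e-5

    def resolve_heads(self) -> tuple:
        if self.heads is not None:
            heads = tuple(self.heads)
        else:
            heads = tuple(max(1, (self.embed_dim << s) // 16) for s in range(4))
        for s, h in enumerate(heads):
            dim = self.embed_dim << s
            if dim % h:
                raise ValueError(
                    f"stage {s}: dim {dim} not divisible by {h} heads")
        return heads

    def validate(self):
        if self.embed_dim % 4:
            raise ValueError("embed_dim must be divisible by 4 (channel split)")
        if len(self.transformer_depths) != 4 or len(self.cnn_depths) != 4:
            raise ValueError("exactly four stages are required")
        for s, d in enumerate(self.transformer_depths):
            if d % 2 or d < 2:
                raise ValueError(f"transformer depth at stage {s} must be an "
                                 "even count of attention modules (>= 2)")
        for s, d in enumerate(self.cnn_depths):
            if d not in (1, 2):
                raise ValueError("cnn depths of 1 or 2 are supported")
        self.resolve_heads()
        return self


# compact profile for CPU desk runs (smoke training / quick experiments)
def desk_config(num_classes: int = 4) -> ModelConfig:
    return ModelConfig(embed_dim=16, transformer_depths=(2, 2, 2, 2),
                       cnn_depths=(1, 1, 1, 1), img_size=112,
                       drop_path=0.0, num_classes=num_classes)


@dataclass
class TrainConfig:
    epochs: int = 300
    batch_size: int = 24
    lr: float = 1e-3
    weight_decay: float = 0.05
    min_lr: float = 1e-5
    seed: int = 0


@dataclass
class EnhanceConfig:
    grid: tuple = (8, 8)
    norm_clip_luma: float = 4.0
    norm_clip_chroma: float = 4.0


@dataclass
class Config:
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    enhancement: EnhanceConfig = field(default_factory=EnhanceConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for section, dc in (("model", cfg.model), ("train", cfg.train),
                            ("enhancement", cfg.enhancement)):
            for k, v in (raw.get(section) or {}).items():
                if not hasattr(dc, k):
                    raise KeyError(f"unknown key {section}.{k}")
                if isinstance(getattr(dc, k), tuple) and v is not None:
                    v = tuple(v)
                setattr(dc, k, v)
        cfg.model.validate()
        return cfg

    def to_yaml(self, path: str | Path):
        Path(path).write_text(yaml.safe_dump(
            {"model": asdict(self.model), "train": asdict(self.train),
             "enhancement": asdict(self.enhancement)}))
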