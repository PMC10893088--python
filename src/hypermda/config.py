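"""Model and training configuration.

Defaults follow the reference training setup: batch size 128, embedding
dimension 128, 64 hypernodes, dropout 0.5, two GCN layers per similarity
view, two hypergraph layers, Sorensen-Dice loss, 5-fold cross-validation
with 1:1 negative sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from pathlib import Path

import yaml

__all__ = ["ModelConfig"]

ABLATIONS = ("none", "no_hypergraph", "bce_loss")


@dataclass
class ModelConfig:
    batch_size: int = 128
    embedding_dim: int = 128
    n_hypernodes: int = 64
    dropout: float = 0.5
    n_layers: int = 2
    hyper_layers: int = 2
    activation: str = "relu"
    view_fusion: str = "mean"
    include_encoder_layer: bool = True
    clip_negative: bool = False
    fnn_hidden: int | None = None
    loss: str = "dice"
    loss_form: str = "as_printed"
    epsilon: float = 1.0
    learning_rate: float = 1e-3
    epochs: int = 100
    neg_ratio: float = 1.0
    n_folds: int = 5
    gamma_prime: float = 1.0
    threshold: float = 0.5
    seed: int = 0
    ablation: str = "none"

    def __post_init__(self):
        if self.ablation not in ABLATIONS:
            raise ValueError(f"ablation must be one of {ABLATIONS}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.loss not in ("dice", "bce"):
            raise ValueError("loss must be 'dice' or 'bce'")
        if self.fnn_hidden is None:
            self.fnn_hidden = self.embedding_dim

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def as_dict(self) -> dict:
        return asdict(self)

    def replace(self, **kwargs) -> "ModelConfig":
        data = self.as_dict()
        data.update(kwargs)
        return ModelConfig(**data)
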