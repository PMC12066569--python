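"""Run configuration.

Defaults follow the reference training recipe: embedding size 128, three
GAT layers, dropout 0.2, Adam with learning rate 1e-3 and weight decay
1e-3, 300 epochs, 10-fold cross-validation over all drug-disease pairs.
All randomness in a run flows from the single ``seed`` through named
substreams (fold shuffling, parameter init, negative sampling, dropout).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .objectives import LossWeights

__all__ = ["TrainConfig", "load_config", "save_config"]


@dataclass
class TrainConfig:
    embed_dim: int = 128
    dropout: float = 0.2
    gat_layers: int = 3
    heads: int = 4
    knn_k: int = 15
    negative_slope: float = 0.2
    lr: float = 1e-3
    weight_decay: float = 1e-3
    epochs: int = 300
    loss_weights: LossWeights = field(default_factory=LossWeights)
    head_kind: str = "kan"          # kan | mlp | dot
    head_hidden: int = 64
    pair_features: str = "product"  # product | concat (head input features)
    contrastive: bool = True
    neg_ratio: float = 1.0          # negatives per positive, each epoch
    ce_reduction: str = "mean"
    n_folds: int = 10
    split_mode: str = "pairwise"    # pairwise | disease-cold
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.loss_weights, dict):
            self.loss_weights = LossWeights(**self.loss_weights)
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.head_kind not in ("kan", "mlp", "dot"):
            raise ValueError(f"unknown head kind {self.head_kind!r}")
        if self.split_mode not in ("pairwise", "disease-cold"):
            raise ValueError(f"unknown split mode {self.split_mode!r}")
        if self.pair_features not in ("product", "concat"):
            raise ValueError(f"unknown pair features {self.pair_features!r}")
        for name in ("embed_dim", "gat_layers", "heads", "knn_k",
                     "head_hidden", "n_folds"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.epochs < 0 or self.lr <= 0 or self.neg_ratio <= 0:
            raise ValueError("invalid training hyperparameters")

    def to_dict(self) -> dict:
        return asdict(self)

    def replace(self, **kwargs) -> "TrainConfig":
        d = self.to_dict()
        d.update(kwargs)
        return TrainConfig(**d)


def load_config(path: str | None = None, **overrides) -> TrainConfig:
    """Build a TrainConfig from an optional YAML file; overrides win."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(TrainConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    return TrainConfig(**data)


def save_config(cfg: TrainConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
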