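"""Configuration dataclasses and YAML round-trip helpers."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

__all__ = ["ModelConfig", "LossConfig", "TrainConfig", "load_yaml", "dump_yaml"]


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    d          input feature dimension per instance.
    d_prime    width after the deep projection layer (all attention runs here).
    heads      attention heads; must divide d_prime.
    r1, r2     top-K ratios for the reliable / ordinary internal queries
               (K = max(1, floor(r * n))); r1 >= r2.
    beta       reliability margin in [-1, 1] gating the reliable-query branch.
    class_bias optional per-class offsets subtracted from the confidence
               factors before gating (asymmetric prior for imbalanced
               instance distributions); None = symmetric gate.
    alpha_attn convex weight on the internal-query attention matrix versus
               the variational-query one; "gated" mode switches between
               alpha_hi / alpha_lo on whether a reliable query was found.
    """

    d: int = 1024
    d_prime: int = 512
    n_classes: int = 2
    heads: int = 8
    r1: float = 0.05
    r2: float = 0.01
    beta: float = 0.0
    class_bias: list[float] | None = None
    alpha_attn: float = 0.5
    alpha_mode: str = "fixed"  # "fixed" | "gated"
    alpha_hi: float = 0.7
    alpha_lo: float = 0.3
    ffn_expansion: int = 4
    vq_init_std: float = 0.02

    def __post_init__(self):
        if self.d_prime % self.heads != 0:
            raise ValueError("heads must divide d_prime")
        if not 0.0 <= self.alpha_attn <= 1.0:
            raise ValueError("alpha_attn must lie in [0, 1]")
        if not (0.0 < self.r2 <= self.r1 <= 1.0):
            raise ValueError("need 0 < r2 <= r1 <= 1")
        if not -1.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [-1, 1]")
        if self.class_bias is not None and len(self.class_bias) != self.n_classes:
            raise ValueError("class_bias must have one entry per class")


@dataclass
class LossConfig:
    """Composite-objective hyperparameters.

    alpha_loss weight of the contrastive term; tau temperature of the
    similarity softmax; momentum of the class-center memory update;
    instance_pooling how the instance probability matrix is pooled for
    its cross-entropy term.
    """

    alpha_loss: float = 0.5
    tau: float = 0.07
    momentum: float = 0.999
    instance_pooling: str = "per_class_max"  # or "global_max"

    def __post_init__(self):
        if self.alpha_loss < 0:
            raise ValueError("alpha_loss must be >= 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if not 0.0 <= self.momentum <= 1.0:
            raise ValueError("momentum must lie in [0, 1]")
        if self.instance_pooling not in ("per_class_max", "global_max"):
            raise ValueError("unknown instance_pooling")


@dataclass
class TrainConfig:
    epochs: int = 30
    lr: float = 2e-4
    weight_decay: float = 1e-5
    optimizer: str = "adam"
    seed: int = 0
    selection_metric: str = "auc_acc"  # "auc" | "auc_acc"
    cosine_decay: bool = True

    def __post_init__(self):
        if self.epochs < 1 or self.lr <= 0:
            raise ValueError("need epochs >= 1 and lr > 0")


def _from_dict(cls, d: dict):
    names = {f.name for f in fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**d)


def load_yaml(path) -> tuple[ModelConfig, LossConfig, TrainConfig]:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return (
        _from_dict(ModelConfig, raw.get("model", {})),
        _from_dict(LossConfig, raw.get("loss", {})),
        _from_dict(TrainConfig, raw.get("train", {})),
    )


def dump_yaml(path, model: ModelConfig, loss: LossConfig, train: TrainConfig) -> None:
    def clean(dc):
        return {
            k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in asdict(dc).items()
        }

    Path(path).write_text(
        yaml.safe_dump({"model": clean(model), "loss": clean(loss), "train": clean(train)})
    )
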