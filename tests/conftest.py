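"""Shared fixtures: toy configs and session-scoped trained models.

The trained-model fixtures run the full 30-epoch CPU training once per
session and are shared by the benchmark, ablation and attention-
localization tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from mdmil.config import LossConfig, ModelConfig, TrainConfig
from mdmil.mdm import MDMILModel
from mdmil.synthetic import camelyon_like, tcga_like
from mdmil.train_eval import evaluate, train

SEEDS = (1, 2, 3)


def toy_model_config(**overrides) -> ModelConfig:
    base = dict(d=8, d_prime=8, n_classes=2, heads=2, r1=0.3, r2=0.1, beta=0.0)
    base.update(overrides)
    return ModelConfig(**base)


@pytest.fixture()
def toy_model():
    return MDMILModel(toy_model_config(), seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def _train_camelyon(seed: int, alpha_attn: float):
    ds, truth = camelyon_like(seed=seed)
    cfg = ModelConfig(
        d=64, d_prime=64, n_classes=2, heads=8, r1=0.05, r2=0.01, beta=0.0,
        alpha_attn=alpha_attn,
    )
    model = MDMILModel(cfg, seed=seed)
    result = train(model, ds, TrainConfig(epochs=30, seed=seed), LossConfig())
    report = evaluate(result.model, ds.subset("test"), 2)
    return ds, truth, result, report


@pytest.fixture(scope="session")
def camelyon_runs():
    """Full dual-query model (alpha=0.5) trained on 3 seeds of the
    detection-style preset."""
    return [_train_camelyon(s, alpha_attn=0.5) for s in SEEDS]


@pytest.fixture(scope="session")
def camelyon_runs_no_vq():
    """Ablated variant: alpha=1 uses the internal-query attention only."""
    return [_train_camelyon(s, alpha_attn=1.0) for s in SEEDS]


@pytest.fixture(scope="session")
def tcga_runs():
    """Subtyping-style preset (3 classes, high prevalence), 3 seeds."""
    out = []
    for s in SEEDS:
        ds, truth = tcga_like(seed=s)
        cfg = ModelConfig(
            d=64, d_prime=64, n_classes=3, heads=8, r1=0.1, r2=0.01, beta=0.0
        )
        model = MDMILModel(cfg, seed=s)
        result = train(model, ds, TrainConfig(epochs=30, seed=s), LossConfig())
        report = evaluate(result.model, ds.subset("test"), 3)
        out.append((ds, truth, result, report))
    return out
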