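"""Composite training objective: two cross-entropies plus a memory-based
contrastive term.

Because only one bag fits a training step (bags have variable length),
in-batch contrastive learning is impossible; instead a *memory bank*
keeps one momentum-updated, L2-normalized center per class. Each step,
the bag's labeled subtype representation f (the row of the MDM output
matching the bag's true label, L2-normalized) is pulled toward its own
class center and pushed from the others through a temperature softmax
over inner products:

    L_CL = -log exp(<f, c_y>/tau) / sum_j exp(<f, c_j>/tau).

Centers are initialized from the normalized per-class means over the
training set and updated as c_k <- m c_k + (1-m) f, re-normalized after
each update so the inner-product scale cannot drift.

The instance stream contributes a cross-entropy on the max-pooled
instance probability matrix P1 (per-class max over instances,
renormalized), the slide stream one on P2, and the total objective is

    L = L_CE(maxpool(P1), y) + L_CE(P2, y) + alpha * L_CL.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, as_tensor, constant
from .config import LossConfig

__all__ = [
    "MemoryBank",
    "DegenerateCenterError",
    "init_memory",
    "update_memory",
    "contrastive_loss",
    "instance_ce",
    "bag_ce",
    "total_loss",
    "l2_normalize",
]

_EPS = 1e-12


class DegenerateCenterError(ValueError):
    """A class center collapsed to (numerically) zero norm."""


def l2_normalize(v):
    if isinstance(v, Tensor):
        return v / ((v * v).sum() ** 0.5 + _EPS)
    v = np.asarray(v, dtype=np.float64)
    nrm = np.linalg.norm(v)
    if nrm < 1e-9:
        raise DegenerateCenterError("zero-norm vector cannot be normalized")
    return v / nrm


@dataclass
class MemoryBank:
    """N unit-norm class centers with momentum-update state."""

    centers: np.ndarray  # N x d'
    momentum: float = 0.999
    tau: float = 0.07

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=np.float64)
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if not 0.0 <= self.momentum <= 1.0:
            raise ValueError("momentum must lie in [0, 1]")

    @property
    def n_classes(self) -> int:
        return self.centers.shape[0]


def init_memory(model, train_bags, loss_config: LossConfig | None = None) -> MemoryBank:
    """Class centers = L2-normalized per-class means of the labeled subtype
    representations over the training bags, under the current model state."""
    cfg = loss_config or LossConfig()
    n_classes = model.config.n_classes
    sums: dict[int, np.ndarray] = {}
    counts = np.zeros(n_classes, dtype=int)
    for bag in train_bags:
        out = model.predict(bag)
        f = out.f_subtypes.data[bag.label]
        sums[bag.label] = sums.get(bag.label, 0.0) + f
        counts[bag.label] += 1
    missing = np.flatnonzero(counts == 0)
    if missing.size:
        raise ValueError(f"classes with zero training bags: {missing.tolist()}")
    centers = np.stack([l2_normalize(sums[k] / counts[k]) for k in range(n_classes)])
    return MemoryBank(centers=centers, momentum=cfg.momentum, tau=cfg.tau)


def update_memory(bank: MemoryBank, k: int, f: np.ndarray) -> MemoryBank:
    """c_k <- momentum * c_k + (1-momentum) * f, re-normalized; in place."""
    f = np.asarray(f, dtype=np.float64)
    if not np.isfinite(f).all():
        raise ValueError("non-finite representation in memory update")
    mixed = bank.momentum * bank.centers[k] + (1.0 - bank.momentum) * f
    bank.centers[k] = l2_normalize(mixed)
    return bank


def contrastive_loss(f, bank: MemoryBank, label: int):
    """Cross-entropy over similarity logits <f, c_j>/tau with target `label`.

    f is L2-normalized before the inner products; the centers enter as
    constants (they are state, not trainable parameters).
    """
    if bank.tau <= 0:
        raise ValueError("tau must be > 0")
    ft = l2_normalize(as_tensor(f) if isinstance(f, Tensor) else Tensor(np.asarray(f, float)))
    logits = (constant(bank.centers) @ ft.reshape(-1, 1)).reshape(bank.n_classes) * (1.0 / bank.tau)
    logp = _log_softmax_vec(logits)
    loss = -logp.take_rows(np.array([label])).sum()
    return loss if isinstance(f, Tensor) else float(loss.data)


def _log_softmax_vec(logits: Tensor) -> Tensor:
    z = logits - float(logits.data.max())  # constant shift, gradient-neutral
    return z - z.exp().sum().log()


def instance_ce(P1, y: int, pooling: str = "per_class_max"):
    """Cross-entropy of the pooled instance probability matrix.

    per_class_max: per-class max over instances, renormalized to a
    distribution, then -log of the true class's entry. global_max: the
    single instance with the highest overall score supplies its row.
    """
    p = as_tensor(P1)
    if pooling == "per_class_max":
        pooled = p.max(axis=0)
        pooled = pooled / pooled.sum()
    elif pooling == "global_max":
        i_star = int(np.argmax(p.data.max(axis=1)))
        pooled = p.take_rows(np.array([i_star])).reshape(p.shape[1])
    else:
        raise ValueError(f"unknown pooling {pooling!r}")
    loss = -(pooled.take_rows(np.array([y])).sum().log())
    return loss if isinstance(P1, Tensor) else float(loss.data)


def bag_ce(P2, y: int):
    """-log P2[y] for a slide-level probability vector."""
    p = as_tensor(P2)
    loss = -(p.take_rows(np.array([y])).sum().log())
    return loss if isinstance(P2, Tensor) else float(loss.data)


def total_loss(P1, P2, f, bank: MemoryBank, y: int, config: LossConfig):
    """instance CE + bag CE + alpha * contrastive."""
    li = instance_ce(P1, y, config.instance_pooling)
    lb = bag_ce(P2, y)
    lc = contrastive_loss(f, bank, y)
    tensor_mode = isinstance(P1, Tensor)
    if tensor_mode:
        return li + lb + lc * config.alpha_loss
    return float(li) + float(lb) + config.alpha_loss * float(lc)
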