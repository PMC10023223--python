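"""Training loop, model selection, metrics, attention export.

One bag per optimization step (bags have variable length, so there is
no trivial batching). The memory bank is initialized from the untrained
model before the first epoch and momentum-updated after every optimizer
step with the current bag's labeled subtype representation. The
checkpoint with the best validation AUC (ties: higher accuracy, then
earlier epoch) is restored at the end. Adam with cosine learning-rate
decay and decoupled weight decay; fully reproducible from the seed on a
single thread.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, roc_auc_score

from .config import LossConfig, ModelConfig, TrainConfig
from .feature_bags import BagDataset, InstanceBag
from .losses import MemoryBank, init_memory, total_loss, update_memory
from .mdm import MDMILModel
from .losses import l2_normalize

__all__ = ["EvalReport", "TrainResult", "Adam", "train", "evaluate", "export_attention"]


class Adam:
    """Adam with decoupled weight decay on a named-parameter dict."""

    def __init__(self, params, lr=2e-4, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def step(self, lr_scale: float = 1.0):
        self.t += 1
        lr = self.lr * lr_scale
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data = p.data - lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p.data)

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None


@dataclass
class EvalReport:
    accuracy: float
    auc: float
    per_class: dict[int, dict[str, float]]
    confusion: np.ndarray


@dataclass
class TrainResult:
    model: MDMILModel
    bank: MemoryBank
    history: list[dict] = field(default_factory=list)
    best_epoch: int = -1


def train(
    model: MDMILModel,
    dataset: BagDataset,
    train_config: TrainConfig,
    loss_config: LossConfig,
    verbose: bool = False,
) -> TrainResult:
    train_bags = dataset.subset("train")
    val_bags = dataset.subset("val")
    if not train_bags or not val_bags:
        raise ValueError("dataset needs non-empty train and val splits")
    rng = np.random.default_rng(train_config.seed)
    params = model.parameters()
    opt = Adam(params, lr=train_config.lr, weight_decay=train_config.weight_decay)
    bank = init_memory(model, train_bags, loss_config)

    total_steps = train_config.epochs * len(train_bags)
    step = 0
    best = (-np.inf, -np.inf, np.inf)  # (auc, acc, -epoch) maximized
    best_state = model.state_dict()
    best_epoch = -1
    history = []
    for epoch in range(train_config.epochs):
        order = rng.permutation(len(train_bags))
        epoch_loss = 0.0
        for i in order:
            bag = train_bags[i]
            out = model.forward_t(bag.features)
            f = l2_normalize(out.f_subtypes.take_rows(np.array([bag.label])).reshape(-1))
            loss = total_loss(out.P1, out.P2, f, bank, bag.label, loss_config)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, bag {bag.bag_id}"
                )
            epoch_loss += float(loss.data)
            opt.zero_grad()
            loss.backward()
            scale = (
                0.5 * (1 + math.cos(math.pi * step / max(1, total_steps)))
                if train_config.cosine_decay
                else 1.0
            )
            opt.step(lr_scale=scale)
            update_memory(bank, bag.label, f.data)
            step += 1
        report = evaluate(model, val_bags, model.config.n_classes)
        history.append(
            {
                "epoch": epoch,
                "train_loss": epoch_loss / len(train_bags),
                "val_auc": report.auc,
                "val_accuracy": report.accuracy,
            }
        )
        if verbose:
            print(
                f"epoch {epoch:3d}  loss {history[-1]['train_loss']:.4f}"
                f"  val_auc {report.auc:.4f}  val_acc {report.accuracy:.4f}"
            )
        if train_config.selection_metric == "auc":
            key = (report.auc, report.accuracy, -epoch)
        elif train_config.selection_metric == "auc_acc":
            # AUC alone can peak at an epoch whose argmax threshold is still
            # uncalibrated; the sum rewards ranking and calibration jointly
            key = (report.auc + report.accuracy, 0.0, -epoch)
        else:
            raise ValueError(f"unknown selection metric {train_config.selection_metric!r}")
        if key > best:
            best = key
            best_state = model.state_dict()
            best_epoch = epoch
    model.set_parameters(best_state)
    return TrainResult(model=model, bank=bank, history=history, best_epoch=best_epoch)


def evaluate(model: MDMILModel, bags: list[InstanceBag], n_classes: int) -> EvalReport:
    """Accuracy and AUROC (binary: positive-class probability; multiclass:
    macro one-vs-rest) over labeled bags."""
    if not bags:
        raise ValueError("empty evaluation set")
    y_true = np.array([b.label for b in bags])
    if np.unique(y_true).size < 2:
        raise ValueError("AUC undefined: evaluation set contains a single class")
    probs = np.vstack([model.predict(b).P2.data for b in bags])
    y_pred = probs.argmax(axis=1)
    accuracy = float((y_pred == y_true).mean())
    if n_classes == 2:
        auc = float(roc_auc_score(y_true, probs[:, 1]))
    else:
        auc = float(
            roc_auc_score(y_true, probs, multi_class="ovr", average="macro",
                          labels=np.arange(n_classes))
        )
    conf = confusion_matrix(y_true, y_pred, labels=np.arange(n_classes))
    per_class = {}
    for k in range(n_classes):
        tp = conf[k, k]
        support = conf[k].sum()
        pred_k = conf[:, k].sum()
        per_class[k] = {
            "recall": float(tp / support) if support else float("nan"),
            "precision": float(tp / pred_k) if pred_k else float("nan"),
            "support": int(support),
        }
    return EvalReport(accuracy=accuracy, auc=auc, per_class=per_class, confusion=conf)


def export_attention(model: MDMILModel, bag: InstanceBag, path=None) -> pd.DataFrame:
    """Head-averaged mixed attention per (instance, subtype) as a TSV table.

    Columns: bag_id, instance_index, row, col, subtype, attention_weight.
    Per subtype the weights sum to 1 (rows of a convex mix of softmaxes).
    """
    out = model.predict(bag)
    attn = out.attn  # N x n
    n_cls, n = attn.shape
    coords = bag.coords if bag.coords is not None else np.stack(
        [np.arange(n), np.zeros(n, dtype=int)], axis=1
    )
    records = [
        {
            "bag_id": bag.bag_id,
            "instance_index": j,
            "row": int(coords[j, 0]),
            "col": int(coords[j, 1]),
            "subtype": k,
            "attention_weight": attn[k, j],
        }
        for k in range(n_cls)
        for j in range(n)
    ]
    df = pd.DataFrame.from_records(records)
    if path is not None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, sep="\t", index=False)
    return df
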