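"""Internal query generation: probability analysis and reliable-query mining.

Two parallel streams process a bag. The *deep projection layer* (DPL) —
linear, layer norm, ReLU, then a second linear map — recalibrates the
transferred d-dim instance features into a compact d'-dim space. In
parallel, a classification layer on the **raw** features followed by a
per-instance softmax yields the instance probability matrix P (n x N).

For each class i, a *confidence factor*

    cf_i = mean(top-K1 of P[:, i]) - std(top-K1 of P[:, i])

(population std, divisor K1) measures how confidently and consistently
the bag's best instances support that class. If the unique arg-max class
satisfies the margin test  cf_max - beta > cf_j  for every other class j,
its internal query is the mean of the projected features of its top-K1
instances (the *reliable* query); every other class averages only its
top-K2 instances. If no class passes, all classes fall back to top-K2.
K = max(1, floor(r * n)) with ratios r1 >= r2, so the reliable branch
pools more instances and the fallback stays conservative.

Top-K selection ranks by descending probability with ties broken by
ascending instance index, which makes the whole module permutation
invariant up to floating-point summation order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor
from .config import ModelConfig

__all__ = [
    "DPLParams",
    "IQGMOutput",
    "init_dpl",
    "init_cls1",
    "project_features",
    "instance_probabilities",
    "top_k_count",
    "top_k_indices",
    "confidence_factor",
    "generate_internal_queries",
    "layer_norm",
]

_LN_EPS = 1e-5


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc / (var + _LN_EPS) ** 0.5 * gain + bias


@dataclass
class DPLParams:
    """linear(d -> d') + LN + ReLU, then linear(d' -> d')."""

    w1: Tensor
    b1: Tensor
    ln_g: Tensor
    ln_b: Tensor
    w2: Tensor
    b2: Tensor

    def tensors(self) -> dict[str, Tensor]:
        return {
            "dpl.w1": self.w1,
            "dpl.b1": self.b1,
            "dpl.ln_g": self.ln_g,
            "dpl.ln_b": self.ln_b,
            "dpl.w2": self.w2,
            "dpl.b2": self.b2,
        }


@dataclass
class IQGMOutput:
    """Internal queries, confidence factors, gate decision and P1."""

    queries: np.ndarray | Tensor  # N x d'
    conf: np.ndarray  # N
    reliable_class: int | None
    P1: np.ndarray | Tensor  # n x N


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    return rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / (fan_in + fan_out))


def init_dpl(d: int, d_prime: int, rng: np.random.Generator) -> DPLParams:
    return DPLParams(
        w1=Tensor(_xavier(rng, d, d_prime)),
        b1=Tensor(np.zeros(d_prime)),
        ln_g=Tensor(np.ones(d_prime)),
        ln_b=Tensor(np.zeros(d_prime)),
        w2=Tensor(_xavier(rng, d_prime, d_prime)),
        b2=Tensor(np.zeros(d_prime)),
    )


def init_cls1(d: int, n_classes: int) -> dict[str, Tensor]:
    """Zero-initialized instance classification head (uniform P at step 0)."""
    return {"cls1.w": Tensor(np.zeros((d, n_classes))), "cls1.b": Tensor(np.zeros(n_classes))}


def project_features(features, params: DPLParams):
    """DPL forward: row-wise, deterministic. Accepts arrays or Tensors."""
    x = as_tensor(features)
    if x.shape[-1] != params.w1.shape[0]:
        raise ValueError(
            f"feature dim {x.shape[-1]} does not match DPL input dim {params.w1.shape[0]}"
        )
    h = (x @ params.w1 + params.b1)
    h = layer_norm(h, params.ln_g, params.ln_b).relu()
    out = h @ params.w2 + params.b2
    return out if isinstance(features, Tensor) else out.data


def instance_probabilities(features, w, b):
    """P = softmax(cls1(F)) per instance over the N classes (raw features in)."""
    x = as_tensor(features)
    p = (x @ as_tensor(w) + as_tensor(b)).softmax(axis=-1)
    return p if isinstance(features, Tensor) else p.data


def top_k_count(n: int, r: float) -> int:
    """K = max(1, floor(r*n)); clamped so tiny bags still contribute one instance."""
    if n < 1 or not 0.0 < r <= 1.0:
        raise ValueError(f"need n >= 1 and r in (0, 1], got n={n}, r={r}")
    return max(1, int(np.floor(r * n)))


def top_k_indices(column: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest entries, descending value, ties by ascending index."""
    order = np.argsort(-np.asarray(column), kind="stable")
    return np.sort(order[:k])


def confidence_factor(class_probs: np.ndarray, k1: int) -> float:
    """cf = mean(top-K1) - population-std(top-K1) of one class's probabilities."""
    p = np.asarray(class_probs, dtype=np.float64)
    if k1 > p.shape[0]:
        raise ValueError("K1 exceeds bag length")
    top = p[top_k_indices(p, k1)]
    return float(top.mean() - top.std())  # np.std is the population form


def generate_internal_queries(f_proj, P, config: ModelConfig) -> IQGMOutput:
    """Confidence-gated aggregation of projected features into per-class queries.

    Accepts arrays (analysis) or Tensors (training; gradients flow through
    the row averaging into the DPL, while the selection itself — ranks,
    confidence factors and the gate — is treated as data-dependent but
    non-differentiable structure).
    """
    fp = as_tensor(f_proj)
    p_np = P.data if isinstance(P, Tensor) else np.asarray(P, dtype=np.float64)
    n, n_cls = p_np.shape
    if n < 1:
        raise ValueError("empty bag")
    if n_cls != config.n_classes:
        raise ValueError(f"P has {n_cls} columns, config expects {config.n_classes}")

    k1 = top_k_count(n, config.r1)
    k2 = top_k_count(n, config.r2)
    conf = np.array([confidence_factor(p_np[:, i], k1) for i in range(n_cls)])

    gated = conf if config.class_bias is None else conf - np.asarray(config.class_bias)
    mx = gated.max()
    argmaxes = np.flatnonzero(gated == mx)
    reliable: int | None = None
    if argmaxes.size == 1:
        i = int(argmaxes[0])
        others = np.delete(gated, i)
        if others.size == 0 or np.all(mx - config.beta > others):
            reliable = i

    rows = []
    for i in range(n_cls):
        k = k1 if i == reliable else k2
        rows.append(fp.take_rows(top_k_indices(p_np[:, i], k)).mean(axis=0, keepdims=True))
    queries = rows[0]
    for r in rows[1:]:
        queries = _vstack2(queries, r)

    if not isinstance(f_proj, Tensor):
        queries = queries.data
    return IQGMOutput(queries=queries, conf=conf, reliable_class=reliable, P1=P)


def _vstack2(a: Tensor, b: Tensor) -> Tensor:
    """Stack two row blocks (autodiff-aware vertical concatenation)."""
    na, nb = a.shape[0], b.shape[0]

    def vjp_a(g):
        return g[:na]

    def vjp_b(g):
        return g[na:]

    return Tensor(np.concatenate([a.data, b.data], axis=0), (a, b), (vjp_a, vjp_b))
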