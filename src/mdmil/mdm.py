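"""Multiplex detection module and the full slide classifier.

The multiplex-detection cross-attention (MDCA) detects critical
instances with two queries at once: the bag-derived internal query IQ
(internal assistance, converges fast) and a trainable variational query
VQ shared across the training set (external assistance, robust to bags
whose own statistics are unreliable). With pre-layernorms and per-head
splitting,

    Q1 = LN(IQ) W1,   Q2 = LN(VQ) W2,   K = LN(F') W3,   V = LN(F') W4,

two row-stochastic attention matrices mt1, mt2 are formed from scaled
dot products, convexly mixed as m' = alpha*mt1 + (1-alpha)*mt2, applied
to V, head-concatenated, linearly projected, and residual-added to IQ.
This reduces the instance dimension from n (patches) to N (subtypes).
A post-LN feed-forward block, a multi-head self-attention over the N
subtype tokens (disentangling their representations), a second FFN, and
a mean over the subtype rows produce the final slide representation,
which a linear head turns into the slide-level prediction P2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor
from .config import ModelConfig
from .feature_bags import InstanceBag
from .iqgm import (
    DPLParams,
    IQGMOutput,
    _xavier,
    generate_internal_queries,
    init_cls1,
    init_dpl,
    instance_probabilities,
    layer_norm,
    project_features,
)

__all__ = [
    "MDCAParams",
    "MHSAParams",
    "FFNParams",
    "MDMILModel",
    "ForwardOutput",
    "attention_matrix",
    "mdca",
    "mhsa",
    "ffn",
    "bag_representation",
    "forward",
]


def _split_heads(x: Tensor, m: int) -> Tensor:
    """(rows, d') -> (m, rows, d'/m)."""
    rows, dp = x.shape
    return x.reshape(rows, m, dp // m).transpose((1, 0, 2))


def _merge_heads(x: Tensor) -> Tensor:
    """(m, rows, dk) -> (rows, m*dk)."""
    m, rows, dk = x.shape
    return x.transpose((1, 0, 2)).reshape(rows, m * dk)


def _gelu(x: Tensor) -> Tensor:
    return x * 0.5 * ((x * (1.0 / np.sqrt(2.0))).erf() + 1.0)


@dataclass
class MDCAParams:
    ln_iq_g: Tensor
    ln_iq_b: Tensor
    ln_vq_g: Tensor
    ln_vq_b: Tensor
    ln_f_g: Tensor
    ln_f_b: Tensor
    w1: Tensor  # IQ query projection
    w2: Tensor  # VQ query projection
    w3: Tensor  # key projection
    w4: Tensor  # value projection
    wo: Tensor  # output projection
    bo: Tensor
    heads: int

    def tensors(self, prefix="mdca"):
        out = {}
        for name in ("ln_iq_g", "ln_iq_b", "ln_vq_g", "ln_vq_b", "ln_f_g", "ln_f_b",
                     "w1", "w2", "w3", "w4", "wo", "bo"):
            out[f"{prefix}.{name}"] = getattr(self, name)
        return out


@dataclass
class MHSAParams:
    ln_g: Tensor
    ln_b: Tensor
    wq: Tensor
    wk: Tensor
    wv: Tensor
    wo: Tensor
    bo: Tensor
    heads: int

    def tensors(self, prefix="mhsa"):
        return {
            f"{prefix}.{name}": getattr(self, name)
            for name in ("ln_g", "ln_b", "wq", "wk", "wv", "wo", "bo")
        }


@dataclass
class FFNParams:
    """Two-layer block with GELU, residual, then post-layernorm."""

    w1: Tensor
    b1: Tensor
    w2: Tensor
    b2: Tensor
    ln_g: Tensor
    ln_b: Tensor

    def tensors(self, prefix="ffn"):
        return {
            f"{prefix}.{name}": getattr(self, name)
            for name in ("w1", "b1", "w2", "b2", "ln_g", "ln_b")
        }


def attention_matrix(q, k):
    """Row-stochastic attention from scaled dot products.

    q: (..., N, dk), k: (..., n, dk); logits q k^T / sqrt(dk), softmax per row.
    """
    qt, kt = as_tensor(q), as_tensor(k)
    if kt.shape[-2] == 0:
        raise ValueError("attention requires at least one key")
    dk = qt.shape[-1]
    logits = (qt @ kt.transpose(_swap_last(kt.ndim))) * (1.0 / np.sqrt(dk))
    out = logits.softmax(axis=-1)
    return out if isinstance(q, Tensor) else out.data


def _swap_last(ndim: int) -> tuple[int, ...]:
    axes = list(range(ndim))
    axes[-1], axes[-2] = axes[-2], axes[-1]
    return tuple(axes)


def mdca(iq, vq, f_proj, params: MDCAParams, alpha: float, return_attn: bool = False):
    """Dual-query cross-attention with residual connection to IQ.

    Returns the N x d' aggregate (and optionally the head-averaged mixed
    attention matrix m', N x n, for heatmap export).
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    iq_t, vq_t, f_t = as_tensor(iq), as_tensor(vq), as_tensor(f_proj)
    m = params.heads
    q1 = _split_heads(layer_norm(iq_t, params.ln_iq_g, params.ln_iq_b) @ params.w1, m)
    q2 = _split_heads(layer_norm(vq_t, params.ln_vq_g, params.ln_vq_b) @ params.w2, m)
    fn = layer_norm(f_t, params.ln_f_g, params.ln_f_b)
    k = _split_heads(fn @ params.w3, m)
    v = _split_heads(fn @ params.w4, m)
    mt1 = attention_matrix(q1, k)
    mt2 = attention_matrix(q2, k)
    mixed = mt1 * alpha + mt2 * (1.0 - alpha)
    agg = _merge_heads(mixed @ v) @ params.wo + params.bo
    out = agg + iq_t  # residual after the output projection
    attn = mixed.mean(axis=0)  # head-averaged m'
    if not isinstance(f_proj, Tensor):
        out, attn = out.data, attn.data
    return (out, attn) if return_attn else out


def mhsa(x, params: MHSAParams):
    """Standard multi-head self-attention over the N subtype tokens, residual."""
    xt = as_tensor(x)
    m = params.heads
    xn = layer_norm(xt, params.ln_g, params.ln_b)
    q = _split_heads(xn @ params.wq, m)
    k = _split_heads(xn @ params.wk, m)
    v = _split_heads(xn @ params.wv, m)
    out = _merge_heads(attention_matrix(q, k) @ v) @ params.wo + params.bo + xt
    return out if isinstance(x, Tensor) else out.data


def ffn(x, params: FFNParams):
    """Row-wise feed-forward with residual, then post-layernorm."""
    xt = as_tensor(x)
    h = _gelu(xt @ params.w1 + params.b1) @ params.w2 + params.b2
    out = layer_norm(xt + h, params.ln_g, params.ln_b)
    return out if isinstance(x, Tensor) else out.data


def bag_representation(features):
    """Mean over the N subtype rows."""
    xt = as_tensor(features)
    out = xt.mean(axis=0)
    return out if isinstance(features, Tensor) else out.data


@dataclass
class ForwardOutput:
    """Everything one forward pass produces (Tensors in training mode)."""

    P1: Tensor
    P2: Tensor
    f_subtypes: Tensor  # N x d', post second FFN, pre-averaging
    rep: Tensor  # d'
    attn: np.ndarray  # N x n head-averaged mixed attention
    iqgm: IQGMOutput


class MDMILModel:
    """The full classifier: DPL + IQGM + MDCA + FFN + MHSA + FFN + linear head."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        dp, m = config.d_prime, config.heads
        self.dpl: DPLParams = init_dpl(config.d, dp, rng)
        self.cls1 = init_cls1(config.d, config.n_classes)
        self.vq = Tensor(rng.standard_normal((config.n_classes, dp)) * config.vq_init_std)
        self.mdca_params = MDCAParams(
            ln_iq_g=Tensor(np.ones(dp)), ln_iq_b=Tensor(np.zeros(dp)),
            ln_vq_g=Tensor(np.ones(dp)), ln_vq_b=Tensor(np.zeros(dp)),
            ln_f_g=Tensor(np.ones(dp)), ln_f_b=Tensor(np.zeros(dp)),
            w1=Tensor(_xavier(rng, dp, dp)), w2=Tensor(_xavier(rng, dp, dp)),
            w3=Tensor(_xavier(rng, dp, dp)), w4=Tensor(_xavier(rng, dp, dp)),
            wo=Tensor(_xavier(rng, dp, dp)), bo=Tensor(np.zeros(dp)),
            heads=m,
        )
        e = config.ffn_expansion
        self.ffn1 = FFNParams(
            w1=Tensor(_xavier(rng, dp, e * dp)), b1=Tensor(np.zeros(e * dp)),
            w2=Tensor(_xavier(rng, e * dp, dp)), b2=Tensor(np.zeros(dp)),
            ln_g=Tensor(np.ones(dp)), ln_b=Tensor(np.zeros(dp)),
        )
        self.mhsa_params = MHSAParams(
            ln_g=Tensor(np.ones(dp)), ln_b=Tensor(np.zeros(dp)),
            wq=Tensor(_xavier(rng, dp, dp)), wk=Tensor(_xavier(rng, dp, dp)),
            wv=Tensor(_xavier(rng, dp, dp)), wo=Tensor(_xavier(rng, dp, dp)),
            bo=Tensor(np.zeros(dp)), heads=m,
        )
        self.ffn2 = FFNParams(
            w1=Tensor(_xavier(rng, dp, e * dp)), b1=Tensor(np.zeros(e * dp)),
            w2=Tensor(_xavier(rng, e * dp, dp)), b2=Tensor(np.zeros(dp)),
            ln_g=Tensor(np.ones(dp)), ln_b=Tensor(np.zeros(dp)),
        )
        # zero-initialized slide-level head: P2 is uniform at step 0
        self.head_w = Tensor(np.zeros((dp, config.n_classes)))
        self.head_b = Tensor(np.zeros(config.n_classes))

    # ------------------------------------------------------------------ #

    def parameters(self) -> dict[str, Tensor]:
        params = {}
        params.update(self.dpl.tensors())
        params.update(self.cls1)
        params["vq"] = self.vq
        params.update(self.mdca_params.tensors())
        params.update(self.ffn1.tensors("ffn1"))
        params.update(self.mhsa_params.tensors())
        params.update(self.ffn2.tensors("ffn2"))
        params["head.w"] = self.head_w
        params["head.b"] = self.head_b
        return params

    def set_parameters(self, values: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        for k, v in values.items():
            params[k].data = np.asarray(v, dtype=np.float64).reshape(params[k].data.shape)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def _alpha(self, reliable_class: int | None) -> float:
        cfg = self.config
        if cfg.alpha_mode == "gated":
            return cfg.alpha_hi if reliable_class is not None else cfg.alpha_lo
        return cfg.alpha_attn

    def forward_t(self, features: np.ndarray) -> ForwardOutput:
        """Training-mode forward pass; all outputs differentiable Tensors."""
        cfg = self.config
        x = Tensor(np.asarray(features, dtype=np.float64))
        f_proj = project_features(x, self.dpl)
        p1 = instance_probabilities(x, self.cls1["cls1.w"], self.cls1["cls1.b"])
        iq_out = generate_internal_queries(f_proj, p1, cfg)
        alpha = self._alpha(iq_out.reliable_class)
        f_ag, attn = mdca(iq_out.queries, self.vq, f_proj, self.mdca_params,
                          alpha, return_attn=True)
        h = ffn(f_ag, self.ffn1)
        h = mhsa(h, self.mhsa_params)
        f_subtypes = ffn(h, self.ffn2)
        rep = bag_representation(f_subtypes)
        logits = rep.reshape(1, cfg.d_prime) @ self.head_w + self.head_b
        p2 = logits.softmax(axis=-1).reshape(cfg.n_classes)
        return ForwardOutput(
            P1=p1, P2=p2, f_subtypes=f_subtypes, rep=rep,
            attn=attn.data, iqgm=iq_out,
        )

    def predict(self, bag_or_features) -> ForwardOutput:
        """Inference: same composition, numpy views kept inside Tensors."""
        feats = (
            bag_or_features.features
            if isinstance(bag_or_features, InstanceBag)
            else bag_or_features
        )
        return self.forward_t(feats)


def forward(bag, model: MDMILModel):
    """Full forward pass on one bag -> (P1, P2, f_subtypes, rep, attn)."""
    out = model.predict(bag)
    return out.P1.data, out.P2.data, out.f_subtypes.data, out.rep.data, out.attn
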