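"""Dual-query cross-attention, self-attention, FFN and the composed model."""

import numpy as np
import pytest

from mdmil.config import ModelConfig
from mdmil.iqgm import generate_internal_queries, instance_probabilities, project_features
from mdmil.mdm import (
    MDMILModel,
    attention_matrix,
    bag_representation,
    ffn,
    forward,
    mdca,
    mhsa,
)

from conftest import toy_model_config


def _ln(x, g, b, eps=1e-5):
    mu = x.mean(axis=-1, keepdims=True)
    var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
    return (x - mu) / np.sqrt(var + eps) * g + b


# ---------------------------------------------------------------------- #
# attention_matrix


def test_single_key_row_is_one(rng):
    mt = attention_matrix(rng.standard_normal((3, 4)), rng.standard_normal((1, 4)))
    np.testing.assert_allclose(mt, 1.0)


def test_equal_dot_products_split_evenly():
    q = np.array([[1.0, 0.0]])
    k = np.array([[1.0, 1.0], [1.0, -1.0]])  # equal dot products with q
    np.testing.assert_allclose(attention_matrix(q, k), [[0.5, 0.5]])


def test_scaled_logit_closed_form():
    # scaled logits (1, 0) -> softmax = [0.73106, 0.26894]
    dk = 4
    q = np.array([[np.sqrt(dk), 0.0, 0.0, 0.0]])
    k = np.array([[1.0, 0, 0, 0], [0.0, 0, 0, 0]])
    np.testing.assert_allclose(attention_matrix(q, k), [[0.7310586, 0.2689414]], atol=1e-6)


def test_rows_stochastic_random(rng):
    mt = attention_matrix(rng.standard_normal((2, 5, 8)), rng.standard_normal((2, 11, 8)))
    assert (mt >= 0).all()
    np.testing.assert_allclose(mt.sum(axis=-1), 1.0, atol=1e-6)


def test_zero_keys_rejected(rng):
    with pytest.raises(ValueError):
        attention_matrix(rng.standard_normal((2, 4)), np.zeros((0, 4)))


# ---------------------------------------------------------------------- #
# mdca


def _toy_parts(rng, n=6, n_cls=2):
    model = MDMILModel(toy_model_config(), seed=0)
    iq = rng.standard_normal((n_cls, 8))
    f = rng.standard_normal((n, 8))
    return model, iq, f


def test_alpha_one_matches_iq_only_path(rng):
    model, iq, f = _toy_parts(rng)
    p = model.mdca_params
    out1, attn1 = mdca(iq, model.vq.data, f, p, alpha=1.0, return_attn=True)
    # independent single-query cross-attention oracle using IQ only
    m, dp = p.heads, 8
    qh = _ln(iq, p.ln_iq_g.data, p.ln_iq_b.data) @ p.w1.data
    fn = _ln(f, p.ln_f_g.data, p.ln_f_b.data)
    kh, vh = fn @ p.w3.data, fn @ p.w4.data
    heads = []
    for h in range(m):
        sl = slice(h * dp // m, (h + 1) * dp // m)
        logits = qh[:, sl] @ kh[:, sl].T / np.sqrt(dp // m)
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        a = e / e.sum(axis=1, keepdims=True)
        heads.append(a @ vh[:, sl])
    expected = np.concatenate(heads, axis=1) @ p.wo.data + p.bo.data + iq
    np.testing.assert_allclose(out1, expected, atol=1e-10)


def test_alpha_zero_still_adds_iq_residual(rng):
    model, iq, f = _toy_parts(rng)
    out_a = mdca(iq, model.vq.data, f, model.mdca_params, alpha=0.0)
    out_b = mdca(iq + 1.0, model.vq.data, f, model.mdca_params, alpha=0.0)
    # at alpha=0 the attention depends only on VQ, so shifting IQ moves the
    # output exactly through the residual term
    np.testing.assert_allclose(out_b - out_a, 1.0, atol=1e-10)


def test_single_instance_bag_broadcasts_value_row(rng):
    model, iq, _ = _toy_parts(rng, n=1)
    f = rng.standard_normal((1, 8))
    p = model.mdca_params
    out, attn = mdca(iq, model.vq.data, f, p, alpha=0.3, return_attn=True)
    np.testing.assert_allclose(attn, 1.0)  # all weights 1 with a single key
    v = _ln(f, p.ln_f_g.data, p.ln_f_b.data) @ p.w4.data
    expected = np.tile(v, (2, 1)) @ p.wo.data + p.bo.data + iq
    np.testing.assert_allclose(out, expected, atol=1e-10)


def test_mixed_attention_rows_convex(rng):
    model, iq, f = _toy_parts(rng, n=9)
    for alpha in (0.0, 0.25, 0.5, 1.0):
        _, attn = mdca(iq, model.vq.data, f, model.mdca_params, alpha, return_attn=True)
        assert (attn >= 0).all()
        np.testing.assert_allclose(attn.sum(axis=1), 1.0, atol=1e-6)


def test_mdca_permutation_invariant(rng):
    model, iq, f = _toy_parts(rng, n=8)
    perm = rng.permutation(8)
    out = mdca(iq, model.vq.data, f, model.mdca_params, 0.5)
    out_p = mdca(iq, model.vq.data, f[perm], model.mdca_params, 0.5)
    np.testing.assert_allclose(out, out_p, atol=1e-6)


def test_mdca_alpha_out_of_range(rng):
    model, iq, f = _toy_parts(rng)
    with pytest.raises(ValueError):
        mdca(iq, model.vq.data, f, model.mdca_params, alpha=1.5)


# ---------------------------------------------------------------------- #
# mhsa / ffn / bag representation


def test_mhsa_single_token(rng):
    model = MDMILModel(toy_model_config(), seed=1)
    p = model.mhsa_params
    x = rng.standard_normal((1, 8))
    out = mhsa(x, p)
    v = _ln(x, p.ln_g.data, p.ln_b.data) @ p.wv.data
    np.testing.assert_allclose(out, v @ p.wo.data + p.bo.data + x, atol=1e-10)


def test_mhsa_identical_rows_stay_identical(rng):
    model = MDMILModel(toy_model_config(), seed=1)
    row = rng.standard_normal(8)
    out = mhsa(np.vstack([row, row]), model.mhsa_params)
    np.testing.assert_allclose(out[0], out[1], atol=1e-12)


def test_mhsa_matches_loop_oracle(rng):
    model = MDMILModel(toy_model_config(), seed=2)
    p = model.mhsa_params
    x = rng.standard_normal((3, 8))
    xn = _ln(x, p.ln_g.data, p.ln_b.data)
    q, k, v = xn @ p.wq.data, xn @ p.wk.data, xn @ p.wv.data
    m, dk = p.heads, 8 // p.heads
    rows = np.zeros((3, 8))
    for h in range(m):
        sl = slice(h * dk, (h + 1) * dk)
        for i in range(3):
            logits = np.array([q[i, sl] @ k[j, sl] for j in range(3)]) / np.sqrt(dk)
            w = np.exp(logits - logits.max())
            w /= w.sum()
            rows[i, sl] = sum(w[j] * v[j, sl] for j in range(3))
    expected = rows @ p.wo.data + p.bo.data + x
    np.testing.assert_allclose(mhsa(x, p), expected, atol=1e-10)


def test_ffn_row_wise(rng):
    model = MDMILModel(toy_model_config(), seed=0)
    x = rng.standard_normal((4, 8))
    perm = rng.permutation(4)
    np.testing.assert_allclose(ffn(x, model.ffn1)[perm], ffn(x[perm], model.ffn1), atol=1e-12)


def test_ffn_zero_expansion_is_layernormed_passthrough(rng):
    model = MDMILModel(toy_model_config(), seed=0)
    model.ffn1.w1.data[:] = 0.0
    model.ffn1.b1.data[:] = 0.0
    model.ffn1.w2.data[:] = 0.0
    model.ffn1.b2.data[:] = 0.0
    x = rng.standard_normal((3, 8))
    np.testing.assert_allclose(
        ffn(x, model.ffn1), _ln(x, model.ffn1.ln_g.data, model.ffn1.ln_b.data), atol=1e-10
    )


def test_ffn_stagewise_oracle_single_row(rng):
    from scipy.special import erf

    model = MDMILModel(toy_model_config(), seed=4)
    fp = model.ffn1
    x = rng.standard_normal((1, 8))
    h = x @ fp.w1.data + fp.b1.data
    h = 0.5 * h * (1 + erf(h / np.sqrt(2)))  # GELU
    h = h @ fp.w2.data + fp.b2.data
    np.testing.assert_allclose(ffn(x, fp), _ln(x + h, fp.ln_g.data, fp.ln_b.data), atol=1e-10)


def test_bag_representation_mean(rng):
    u, v = rng.standard_normal(8), rng.standard_normal(8)
    np.testing.assert_allclose(bag_representation(np.vstack([u, v])), (u + v) / 2)
    np.testing.assert_allclose(bag_representation(np.tile(u, (5, 1))), u, atol=1e-12)
    x = rng.standard_normal((7, 8))
    np.testing.assert_allclose(bag_representation(x), x.sum(axis=0) / 7, atol=1e-12)


# ---------------------------------------------------------------------- #
# full forward pass


def test_forward_shapes_and_stochasticity(rng):
    cfgm = toy_model_config()
    model = MDMILModel(cfgm, seed=0)
    x = rng.standard_normal((10, 8))
    P1, P2, f_sub, rep, attn = forward(x, model)
    assert P1.shape == (10, 2) and P2.shape == (2,)
    assert f_sub.shape == (2, 8) and rep.shape == (8,) and attn.shape == (2, 10)
    np.testing.assert_allclose(P1.sum(axis=1), 1.0, atol=1e-6)
    np.testing.assert_allclose(P2.sum(), 1.0, atol=1e-6)
    np.testing.assert_allclose(attn.sum(axis=1), 1.0, atol=1e-6)


def test_forward_uniform_p2_with_zero_head(rng):
    model = MDMILModel(toy_model_config(), seed=0)  # heads zero-initialized
    _, P2, *_ = forward(rng.standard_normal((6, 8)), model)
    np.testing.assert_allclose(P2, 0.5, atol=1e-12)


def test_forward_permutation_invariant(rng):
    model = MDMILModel(toy_model_config(), seed=5)
    # break the uniform-P1 degeneracy so top-K selection is generic
    model.cls1["cls1.w"].data = rng.standard_normal((8, 2)) * 0.5
    model.head_w.data = rng.standard_normal((8, 2)) * 0.5
    x = rng.standard_normal((12, 8))
    perm = rng.permutation(12)
    P1, P2, f_sub, rep, attn = forward(x, model)
    P1p, P2p, f_subp, repp, attnp = forward(x[perm], model)
    np.testing.assert_allclose(P1[perm], P1p, atol=1e-9)
    np.testing.assert_allclose(P2, P2p, atol=1e-5)
    np.testing.assert_allclose(rep, repp, atol=1e-5)
    np.testing.assert_allclose(attn[:, perm], attnp, atol=1e-5)


def test_forward_matches_hand_unrolled_composition(rng):
    """The model's forward equals the explicit module chain on a 4-instance bag."""
    cfgm = toy_model_config(r1=0.5, r2=0.25)
    model = MDMILModel(cfgm, seed=6)
    model.cls1["cls1.w"].data = rng.standard_normal((8, 2)) * 0.5
    model.head_w.data = rng.standard_normal((8, 2)) * 0.5
    x = rng.standard_normal((4, 8))

    f_proj = project_features(x, model.dpl)
    P1 = instance_probabilities(x, model.cls1["cls1.w"].data, model.cls1["cls1.b"].data)
    iq_out = generate_internal_queries(f_proj, P1, cfgm)
    f_ag = mdca(iq_out.queries, model.vq.data, f_proj, model.mdca_params, cfgm.alpha_attn)
    h = ffn(f_ag, model.ffn1)
    h = mhsa(h, model.mhsa_params)
    f_sub = ffn(h, model.ffn2)
    rep = bag_representation(f_sub)
    logits = rep @ model.head_w.data + model.head_b.data
    expected_P2 = np.exp(logits - logits.max())
    expected_P2 /= expected_P2.sum()

    P1m, P2m, f_subm, repm, _ = forward(x, model)
    np.testing.assert_allclose(P1m, P1, atol=1e-10)
    np.testing.assert_allclose(f_subm, f_sub, atol=1e-10)
    np.testing.assert_allclose(repm, rep, atol=1e-10)
    np.testing.assert_allclose(P2m, expected_P2, atol=1e-10)


def test_gated_alpha_mode(rng):
    cfgm = toy_model_config(alpha_mode="gated", alpha_hi=0.7, alpha_lo=0.3)
    model = MDMILModel(cfgm, seed=0)
    assert model._alpha(reliable_class=0) == 0.7
    assert model._alpha(reliable_class=None) == 0.3
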