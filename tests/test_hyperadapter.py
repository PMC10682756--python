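"""Hypernetwork-generated adapters: algebra, identities, oracle equivalence."""

import numpy as np
import pytest
from scipy.special import erf

from hypermood.autodiff import Tensor
from hypermood.hyperadapter_core import (AdapterParams, EncoderConfig,
                                         adapter_apply, backbone_forward,
                                         conditioning_input,
                                         generate_adapter_params,
                                         hyperformer_forward, init_backbone,
                                         init_hypernet, load_checkpoint,
                                         n_parameters, save_checkpoint,
                                         sinusoidal_positions,
                                         subject_embedding)

EPS = 1e-5


def np_gelu(x):
    return 0.5 * x * (1.0 + erf(x / np.sqrt(2.0)))


def np_layer_norm(x, gamma, beta, eps=EPS):
    mu = x.mean(axis=-1, keepdims=True)
    var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
    return (x - mu) / np.sqrt(var + eps) * gamma + beta


def oracle_adapter(x, p, activation="gelu"):
    """Independent straight-line recomputation of the bottleneck adapter."""
    z = x @ p["W_D"].T + p["b_D"]
    if activation == "gelu":
        z = np_gelu(z)
    u = z @ p["W_U"].T + p["b_U"]
    return np_layer_norm(u, p["gamma"], p["beta"]) + x


def random_params(rng, h, d, batch=None):
    shape = lambda *s: (batch, *s) if batch else s
    raw = {
        "W_D": rng.normal(size=shape(d, h)), "b_D": rng.normal(size=shape(d)),
        "W_U": rng.normal(size=shape(h, d)), "b_U": rng.normal(size=shape(h)),
        "beta": rng.normal(size=shape(h)), "gamma": rng.normal(size=shape(h)),
    }
    return raw, AdapterParams(**{k: Tensor(v) for k, v in raw.items()})


def test_adapter_identity_when_up_projection_and_beta_zero(rng):
    h, d = 6, 3
    raw, params = random_params(rng, h, d)
    for key in ("W_U", "b_U", "beta"):
        getattr(params, key).data[...] = 0.0
    x = rng.normal(size=(4, h))
    np.testing.assert_array_equal(adapter_apply(x, params, eps=EPS).data, x)


def test_adapter_hand_computed_two_element_case():
    """x=(1,3) with passthrough projections and no nonlinearity: the LN core
    standardizes to (-1, +1), so the output is (0, 4)."""
    eye = np.eye(2)
    params = AdapterParams(
        W_D=Tensor(eye), b_D=Tensor(np.zeros(2)),
        W_U=Tensor(eye), b_U=Tensor(np.zeros(2)),
        beta=Tensor(np.zeros(2)), gamma=Tensor(np.ones(2)))
    out = adapter_apply(np.array([1.0, 3.0]), params, eps=1e-12,
                        activation="identity")
    np.testing.assert_allclose(out.data, [0.0, 4.0], atol=1e-5)


def test_adapter_matches_oracle_on_many_random_instances(rng):
    for _ in range(100):
        h = int(rng.integers(3, 10))
        d = int(rng.integers(1, h))
        T = int(rng.integers(1, 6))
        raw, params = random_params(rng, h, d)
        x = rng.normal(size=(T, h))
        np.testing.assert_allclose(adapter_apply(x, params, eps=EPS).data,
                                   oracle_adapter(x, raw), atol=1e-6)


def test_adapter_batched_params_match_per_row_application(rng):
    h, d, B, T = 8, 3, 5, 4
    raw, params = random_params(rng, h, d, batch=B)
    x = rng.normal(size=(B, T, h))
    out = adapter_apply(x, params, eps=EPS).data
    for b in range(B):
        row = {k: v[b] for k, v in raw.items()}
        np.testing.assert_allclose(out[b], oracle_adapter(x[b], row), atol=1e-6)


def test_adapter_rejects_non_finite_input(rng):
    _, params = random_params(rng, 4, 2)
    with pytest.raises(ValueError):
        adapter_apply(np.array([np.nan, 0, 0, 0.0]), params)


# ---------------------------------------------------------------------------
# conditioning and generation


def _toy_hypernet(rng, m_dim=9, L=4, e=8, s=5, d=3, h=8):
    cfg = EncoderConfig(input_dim=4, n_layers=L, hidden=h, n_heads=2,
                        adapter_dim=d, subject_dim=s, embed_dim=e, seed=1)
    hp = init_hypernet(cfg, m_dim, seed=int(rng.integers(2**31)))
    return cfg, hp


def test_conditioning_length_and_block_structure(rng):
    cfg, hp = _toy_hypernet(rng)
    m = rng.normal(size=9)
    c00 = conditioning_input(m, 0, 0, hp).data
    c01 = conditioning_input(m, 0, 1, hp).data
    assert c00.shape == (9 + 2 * cfg.embed_dim,)
    np.testing.assert_array_equal(c00[:9 + cfg.embed_dim],
                                  c01[:9 + cfg.embed_dim])
    assert not np.array_equal(c00[9 + cfg.embed_dim:], c01[9 + cfg.embed_dim:])
    c10 = conditioning_input(m, 1, 0, hp).data
    np.testing.assert_array_equal(c00[:9], c10[:9])
    with pytest.raises(IndexError):
        conditioning_input(m, cfg.n_layers, 0, hp)
    with pytest.raises(IndexError):
        conditioning_input(m, 0, 2, hp)


def test_subject_embedding_matches_oracle(rng):
    cfg, hp = _toy_hypernet(rng)
    for _ in range(100):
        cond = rng.normal(size=9 + 2 * cfg.embed_dim)
        got = subject_embedding(Tensor(cond), hp).data
        hidden = np.maximum(cond @ hp["hi_W1"].data + hp["hi_b1"].data, 0.0)
        want = hidden @ hp["hi_W2"].data + hp["hi_b2"].data
        np.testing.assert_allclose(got, want, atol=1e-6)


def test_relu_masks_negative_preactivations(rng):
    cfg, hp = _toy_hypernet(rng)
    cond = rng.normal(size=9 + 2 * cfg.embed_dim)
    pre = cond @ hp["hi_W1"].data + hp["hi_b1"].data
    dead = int(np.argmin(pre))
    assert pre[dead] < 0
    base = subject_embedding(Tensor(cond), hp).data
    hp2 = {k: Tensor(v.data.copy(), requires_grad=False) for k, v in hp.items()}
    hp2["hi_W2"].data[dead, :] += 100.0  # only reachable through the dead unit
    np.testing.assert_allclose(subject_embedding(Tensor(cond), hp2).data, base)


def test_generator_zero_input_zero_biases_gives_identity_adapter(rng):
    cfg, hp = _toy_hypernet(rng)
    params = generate_adapter_params(Tensor(np.zeros(cfg.subject_dim)), hp, cfg)
    x = rng.normal(size=(3, cfg.hidden))
    np.testing.assert_array_equal(adapter_apply(x, params, eps=EPS).data, x)


def test_generator_linearity_with_zero_biases(rng):
    cfg, hp = _toy_hypernet(rng)
    for key in ("gen_d_W", "gen_u_W", "gen_ln_W"):
        hp[key].data = rng.normal(size=hp[key].data.shape)
    I = rng.normal(size=cfg.subject_dim)
    p1 = generate_adapter_params(Tensor(I), hp, cfg)
    p2 = generate_adapter_params(Tensor(2 * I), hp, cfg)
    np.testing.assert_allclose(p2.W_D.data, 2 * p1.W_D.data, atol=1e-10)
    np.testing.assert_allclose(p2.beta.data, 2 * p1.beta.data, atol=1e-10)


def test_generator_index_level_oracle(rng):
    cfg, hp = _toy_hypernet(rng)
    hp["gen_d_W"].data = rng.normal(size=hp["gen_d_W"].data.shape)
    hp["gen_d_b"].data = rng.normal(size=hp["gen_d_b"].data.shape)
    I = rng.normal(size=cfg.subject_dim)
    params = generate_adapter_params(Tensor(I), hp, cfg)
    d, h = cfg.adapter_dim, cfg.hidden
    for _ in range(30):
        k = int(rng.integers(d))
        l = int(rng.integers(h))
        col = k * (h + 1) + l
        want = float(I @ hp["gen_d_W"].data[:, col] + hp["gen_d_b"].data[col])
        assert params.W_D.data[k, l] == pytest.approx(want, abs=1e-10)
    for k in range(d):
        col = k * (h + 1) + h
        want = float(I @ hp["gen_d_W"].data[:, col] + hp["gen_d_b"].data[col])
        assert params.b_D.data[k] == pytest.approx(want, abs=1e-10)


# ---------------------------------------------------------------------------
# full forward pass


def _toy_model(rng, L=2, h=8, m_dim=7, use_positions=True):
    cfg = EncoderConfig(input_dim=5, n_layers=L, hidden=h, n_heads=2,
                        ff_mult=2, adapter_dim=3, subject_dim=4, embed_dim=3,
                        use_positions=use_positions, seed=2)
    backbone = init_backbone(cfg, seed=int(rng.integers(2**31)))
    hp = init_hypernet(cfg, m_dim, seed=int(rng.integers(2**31)))
    return cfg, backbone, hp


def test_identity_regime_reduces_to_frozen_backbone(rng):
    cfg, backbone, hp = _toy_model(rng)
    for _ in range(20):
        frames = rng.normal(size=(6, cfg.input_dim))
        m = rng.normal(size=7)
        base = backbone_forward(frames, backbone, cfg).data
        pers = hyperformer_forward(frames, m, backbone, hp, cfg).data
        assert pers == pytest.approx(base, abs=1e-12)


def test_frame_permutation_invariance_without_positions(rng):
    cfg, backbone, hp = _toy_model(rng, use_positions=False)
    for key in hp:
        hp[key].data = rng.normal(0, 0.2, size=hp[key].data.shape)
    frames = rng.normal(size=(7, cfg.input_dim))
    m = rng.normal(size=7)
    base = hyperformer_forward(frames, m, backbone, hp, cfg).data
    perm = hyperformer_forward(frames[rng.permutation(7)], m, backbone, hp,
                               cfg).data
    assert perm == pytest.approx(base, abs=1e-9)


def test_metadata_changes_predictions(rng):
    cfg, backbone, hp = _toy_model(rng)
    for key in hp:
        hp[key].data = rng.normal(0, 0.3, size=hp[key].data.shape)
    frames = rng.normal(size=(6, cfg.input_dim))
    m1, m2 = rng.normal(size=7), rng.normal(size=7)
    y1 = hyperformer_forward(frames, m1, backbone, hp, cfg).data
    y2 = hyperformer_forward(frames, m2, backbone, hp, cfg).data
    y1b = hyperformer_forward(frames, m1.copy(), backbone, hp, cfg).data
    assert y1 != pytest.approx(y2, abs=1e-9)
    assert y1 == pytest.approx(y1b, abs=1e-15)


def oracle_forward(frames, m, backbone, hp, cfg):
    """Independent numpy reimplementation of the personalized encoder."""
    g = {k: v.data for k, v in backbone.items()}
    hn = {k: v.data for k, v in hp.items()}

    def adapter_for(i, j):
        cond = np.concatenate([m, hn["layer_emb"][i], hn["pos_emb"][j]])
        I = np.maximum(cond @ hn["hi_W1"] + hn["hi_b1"], 0) @ hn["hi_W2"] + hn["hi_b2"]
        gd = (I @ hn["gen_d_W"] + hn["gen_d_b"]).reshape(cfg.adapter_dim,
                                                         cfg.hidden + 1)
        gu = (I @ hn["gen_u_W"] + hn["gen_u_b"]).reshape(cfg.hidden,
                                                         cfg.adapter_dim + 1)
        gl = I @ hn["gen_ln_W"] + hn["gen_ln_b"]
        return {"W_D": gd[:, :-1], "b_D": gd[:, -1],
                "W_U": gu[:, :-1], "b_U": gu[:, -1],
                "beta": gl[:cfg.hidden], "gamma": gl[cfg.hidden:]}

    def ln(x, gam, bet):
        return np_layer_norm(x, gam, bet, eps=cfg.ln_eps)

    T = frames.shape[0]
    h = frames @ g["in_W"] + g["in_b"]
    if cfg.use_positions:
        h = h + sinusoidal_positions(T, cfg.hidden)
    nh, dh = cfg.n_heads, cfg.hidden // cfg.n_heads
    for i in range(cfg.n_layers):
        x = ln(h, g[f"l{i}_ln1_g"], g[f"l{i}_ln1_b"])
        q = (x @ g[f"l{i}_Wq"] + g[f"l{i}_bq"]).reshape(T, nh, dh).transpose(1, 0, 2)
        k = (x @ g[f"l{i}_Wk"] + g[f"l{i}_bk"]).reshape(T, nh, dh).transpose(1, 0, 2)
        v = (x @ g[f"l{i}_Wv"] + g[f"l{i}_bv"]).reshape(T, nh, dh).transpose(1, 0, 2)
        scores = q @ k.transpose(0, 2, 1) / np.sqrt(dh)
        attn = np.exp(scores - scores.max(axis=-1, keepdims=True))
        attn = attn / attn.sum(axis=-1, keepdims=True)
        a = (attn @ v).transpose(1, 0, 2).reshape(T, cfg.hidden)
        a = a @ g[f"l{i}_Wo"] + g[f"l{i}_bo"]
        p = adapter_for(i, 0)
        a = ln(np_gelu(a @ p["W_D"].T + p["b_D"]) @ p["W_U"].T + p["b_U"],
               p["gamma"], p["beta"]) + a
        h = h + a
        x = ln(h, g[f"l{i}_ln2_g"], g[f"l{i}_ln2_b"])
        f = np_gelu(x @ g[f"l{i}_ff_W1"] + g[f"l{i}_ff_b1"]) @ g[f"l{i}_ff_W2"] \
            + g[f"l{i}_ff_b2"]
        p = adapter_for(i, 1)
        f = ln(np_gelu(f @ p["W_D"].T + p["b_D"]) @ p["W_U"].T + p["b_U"],
               p["gamma"], p["beta"]) + f
        h = h + f
    h = ln(h, g["final_ln_g"], g["final_ln_b"])
    return float((h.mean(axis=0) @ g["head_w"] + g["head_b"])[0])


def test_full_forward_matches_independent_oracle(rng):
    cfg, backbone, hp = _toy_model(rng, L=2, h=8)
    for key in hp:
        hp[key].data = rng.normal(0, 0.3, size=hp[key].data.shape)
    for _ in range(25):
        frames = rng.normal(size=(int(rng.integers(2, 8)), cfg.input_dim))
        m = rng.normal(size=7)
        got = float(hyperformer_forward(frames, m, backbone, hp, cfg).data)
        want = oracle_forward(frames, m, backbone, hp, cfg)
        assert got == pytest.approx(want, abs=1e-5)


def test_batched_forward_matches_single_rows(rng):
    cfg, backbone, hp = _toy_model(rng)
    for key in hp:
        hp[key].data = rng.normal(0, 0.3, size=hp[key].data.shape)
    frames = rng.normal(size=(4, 5, cfg.input_dim))
    m = rng.normal(size=(4, 7))
    batched = hyperformer_forward(frames, m, backbone, hp, cfg).data
    for b in range(4):
        single = hyperformer_forward(frames[b], m[b], backbone, hp, cfg).data
        assert batched[b] == pytest.approx(float(single), abs=1e-10)


def test_hypernetwork_size_independent_of_depth(rng):
    shallow = EncoderConfig(input_dim=4, n_layers=2, hidden=16, n_heads=2,
                            adapter_dim=4, subject_dim=4, embed_dim=3)
    deep = EncoderConfig(input_dim=4, n_layers=12, hidden=16, n_heads=2,
                         adapter_dim=4, subject_dim=4, embed_dim=3)
    hp_s = init_hypernet(shallow, m_dim=9)
    hp_d = init_hypernet(deep, m_dim=9)
    extra = n_parameters(hp_d) - n_parameters(hp_s)
    assert extra == (12 - 2) * shallow.embed_dim  # only the embedding table grows


def test_config_validation():
    with pytest.raises(ValueError):
        EncoderConfig(hidden=8, adapter_dim=8).validate()
    with pytest.raises(ValueError):
        EncoderConfig(hidden=10, n_heads=4, adapter_dim=2).validate()


def test_checkpoint_round_trip(tmp_path, rng):
    cfg, backbone, hp = _toy_model(rng)
    path = tmp_path / "model.npz"
    save_checkpoint(path, cfg, {"backbone": backbone, "hypernet": hp},
                    extra={"epoch": 3})
    cfg2, groups, extra = load_checkpoint(path)
    assert extra["epoch"] == 3
    assert cfg2.hidden == cfg.hidden
    frames = rng.normal(size=(5, cfg.input_dim))
    m = rng.normal(size=7)
    a = hyperformer_forward(frames, m, backbone, hp, cfg).data
    b = hyperformer_forward(frames, m, groups["backbone"], groups["hypernet"],
                            cfg2).data
    assert float(a) == pytest.approx(float(b), abs=1e-15)
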