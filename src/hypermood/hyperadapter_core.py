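"""Metadata-conditioned hypernetwork adapters inside a transformer encoder.

The personalization mechanism: every encoder layer carries two bottleneck
adapters (one after the attention block, one after the feedforward block,
both before the additive skip connection),

    A(x) = LN(U(GeLU(D(x)))) + x,
    LN(x) = (x - mu) / sigma * gamma + beta,

and *none* of the adapter parameters are trained directly. Instead, a single
shared set of hypernetworks generates them per subject: the subject's
metadata vector m_S is concatenated with learned layer and position
embeddings (l_i, p_j), projected by a two-stage network h_I to a subject
embedding I_S, and three affine generators h_D, h_U, h_LN map I_S to the
down-projection, up-projection and layer-norm parameters of site (i, j).
With the generator output layers zero-initialized every adapter is the
identity, so training starts exactly from the frozen backbone's behavior.

The backbone here is a small generic pre-LN transformer encoder over frame
sequences with sinusoidal positions, mean pooling and an affine regression
head; real-audio front ends are out of scope.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .autodiff import Tensor, concat, gelu, relu, softmax

POSITIONS_PER_LAYER = 2  # j=0: after attention, j=1: after feedforward


@dataclass
class EncoderConfig:
    input_dim: int = 8  # F: feature channels per frame
    n_layers: int = 4  # L
    hidden: int = 64  # h
    n_heads: int = 4
    ff_mult: int = 2  # feedforward inner width = ff_mult * hidden
    adapter_dim: int = 8  # d: adapter bottleneck
    subject_dim: int = 8  # s: subject embedding I_S
    embed_dim: int = 8  # e: layer/position embedding width
    hi_hidden: int = 16  # width of h_I's rectified stage
    ln_eps: float = 1e-5
    use_positions: bool = True
    pooling: str = "mean"
    generator_bias: bool = True  # whether h_D/h_U/h_LN are affine
    seed: int = 0

    def validate(self) -> None:
        if self.adapter_dim >= self.hidden:
            raise ValueError("adapter bottleneck d must be < hidden width h")
        if self.subject_dim < 1:
            raise ValueError("subject embedding dimension s must be >= 1")
        if self.hidden % self.n_heads:
            raise ValueError("hidden width must divide evenly into heads")


@dataclass
class AdapterParams:
    """Generated per-(subject, layer, position) adapter weights. Leading batch
    axes are allowed on every field."""

    W_D: Tensor  # (..., d, h)
    b_D: Tensor  # (..., d)
    W_U: Tensor  # (..., h, d)
    b_U: Tensor  # (..., h)
    beta: Tensor  # (..., h)
    gamma: Tensor  # (..., h)


def _xavier(rng, fan_in, fan_out, shape=None):
    shape = shape or (fan_in, fan_out)
    std = np.sqrt(2.0 / (fan_in + fan_out))
    return Tensor(rng.normal(0.0, std, size=shape), requires_grad=True)


def _zeros(*shape):
    return Tensor(np.zeros(shape), requires_grad=True)


def sinusoidal_positions(T: int, h: int) -> np.ndarray:
    pos = np.arange(T)[:, None]
    i = np.arange(h)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / h)
    pe = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return pe


# ---------------------------------------------------------------------------
# parameter initialization


def init_backbone(cfg: EncoderConfig, seed: int | None = None) -> dict:
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    h, ff = cfg.hidden, cfg.ff_mult * cfg.hidden
    p = {
        "in_W": _xavier(rng, cfg.input_dim, h),
        "in_b": _zeros(h),
        "final_ln_g": Tensor(np.ones(h), requires_grad=True),
        "final_ln_b": _zeros(h),
        "head_w": _xavier(rng, h, 1),
        "head_b": _zeros(1),
    }
    for l in range(cfg.n_layers):
        p[f"l{l}_ln1_g"] = Tensor(np.ones(h), requires_grad=True)
        p[f"l{l}_ln1_b"] = _zeros(h)
        p[f"l{l}_ln2_g"] = Tensor(np.ones(h), requires_grad=True)
        p[f"l{l}_ln2_b"] = _zeros(h)
        for name in ("q", "k", "v", "o"):
            p[f"l{l}_W{name}"] = _xavier(rng, h, h)
            p[f"l{l}_b{name}"] = _zeros(h)
        p[f"l{l}_ff_W1"] = _xavier(rng, h, ff)
        p[f"l{l}_ff_b1"] = _zeros(ff)
        p[f"l{l}_ff_W2"] = _xavier(rng, ff, h)
        p[f"l{l}_ff_b2"] = _zeros(h)
    return p


def init_hypernet(cfg: EncoderConfig, m_dim: int, seed: int | None = None) -> dict:
    """One shared generator set serves all L x 2 adapter sites; only the
    embedding tables grow with depth. Generator output layers start at zero
    (identity adapters)."""
    cfg.validate()
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 1)
    e, s, d, h = cfg.embed_dim, cfg.subject_dim, cfg.adapter_dim, cfg.hidden
    cond = m_dim + 2 * e
    p = {
        "layer_emb": Tensor(rng.normal(0, 0.1, size=(cfg.n_layers, e)),
                            requires_grad=True),
        "pos_emb": Tensor(rng.normal(0, 0.1, size=(POSITIONS_PER_LAYER, e)),
                          requires_grad=True),
        "hi_W1": _xavier(rng, cond, cfg.hi_hidden),
        "hi_b1": _zeros(cfg.hi_hidden),
        "hi_W2": _xavier(rng, cfg.hi_hidden, s),
        "hi_b2": _zeros(s),
        "gen_d_W": _zeros(s, d * (h + 1)),
        "gen_u_W": _zeros(s, h * (d + 1)),
        "gen_ln_W": _zeros(s, 2 * h),
    }
    if cfg.generator_bias:
        p["gen_d_b"] = _zeros(d * (h + 1))
        p["gen_u_b"] = _zeros(h * (d + 1))
        p["gen_ln_b"] = _zeros(2 * h)
    return p


# ---------------------------------------------------------------------------
# core operations


def layer_norm(x: Tensor, gamma, beta, eps: float = 1e-5) -> Tensor:
    """Normalize across the last axis; eps keeps constant vectors finite."""
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    xhat = xc * ((var + eps) ** -0.5)
    return xhat * gamma + beta


def adapter_apply(x, params: AdapterParams, eps: float = 1e-5,
                  activation: str = "gelu") -> Tensor:
    """Bottleneck adapter A(x) = LN(U(act(D(x)))) + x.

    `x` may be a single h-vector, a (T, h) matrix, or batched (B, T, h) with
    per-row generated parameters (B, d, h) etc. The layer norm uses the
    mean/SD across the h elements of each position and the *generated*
    beta/gamma.
    """
    x = Tensor.as_tensor(x)
    if not np.all(np.isfinite(x.data)):
        raise ValueError("non-finite adapter input")
    squeeze = x.ndim == 1
    if squeeze:
        x = x.reshape(1, -1)

    W_D, W_U = params.W_D, params.W_U
    batched = W_D.ndim == 3
    b_D = params.b_D.reshape(-1, 1, params.b_D.shape[-1]) if batched else params.b_D
    b_U = params.b_U.reshape(-1, 1, params.b_U.shape[-1]) if batched else params.b_U
    beta = params.beta.reshape(-1, 1, params.beta.shape[-1]) if batched else params.beta
    gamma = params.gamma.reshape(-1, 1, params.gamma.shape[-1]) if batched else params.gamma

    z = x @ W_D.swapaxes(-1, -2) + b_D
    if activation == "gelu":
        z = gelu(z)
    elif activation != "identity":
        raise ValueError(f"unknown activation {activation!r}")
    u = z @ W_U.swapaxes(-1, -2) + b_U
    out = layer_norm(u, gamma, beta, eps=eps) + x
    return out.reshape(-1) if squeeze else out


def conditioning_input(m_S, layer_index: int, position_index: int,
                       hp: dict) -> Tensor:
    """concat(m_S, l_i, p_j); batched if m_S is (B, M)."""
    L = hp["layer_emb"].shape[0]
    if not (0 <= layer_index < L):
        raise IndexError(f"layer index {layer_index} out of range [0, {L})")
    if position_index not in (0, 1):
        raise IndexError("position index must be 0 (post-attention) or 1 (post-ffn)")
    m_S = Tensor.as_tensor(m_S)
    l_row = hp["layer_emb"][layer_index:layer_index + 1]  # (1, e)
    p_row = hp["pos_emb"][position_index:position_index + 1]
    if m_S.ndim == 1:
        return concat([m_S, l_row.reshape(-1), p_row.reshape(-1)], axis=0)
    ones = Tensor(np.ones((m_S.shape[0], 1)))
    return concat([m_S, ones @ l_row, ones @ p_row], axis=-1)


def subject_embedding(cond_input, hp: dict) -> Tensor:
    """I_S = Affine2(ReLU(Affine1(cond)))."""
    cond = Tensor.as_tensor(cond_input)
    hidden = relu(cond @ hp["hi_W1"] + hp["hi_b1"])
    return hidden @ hp["hi_W2"] + hp["hi_b2"]


def generate_adapter_params(I_S, hp: dict, cfg: EncoderConfig) -> AdapterParams:
    """h_D, h_U, h_LN applied to I_S; linear in I_S when generator biases are
    zero. Accepts a single s-vector or a batch (B, s)."""
    I_S = Tensor.as_tensor(I_S)
    d, h = cfg.adapter_dim, cfg.hidden
    squeeze = I_S.ndim == 1
    if squeeze:
        I_S = I_S.reshape(1, -1)
    B = I_S.shape[0]
    if I_S.shape[-1] != hp["gen_d_W"].shape[0]:
        raise ValueError("subject embedding dimension does not match generators")

    gd = I_S @ hp["gen_d_W"]
    gu = I_S @ hp["gen_u_W"]
    gl = I_S @ hp["gen_ln_W"]
    if "gen_d_b" in hp:
        gd = gd + hp["gen_d_b"]
        gu = gu + hp["gen_u_b"]
        gl = gl + hp["gen_ln_b"]

    gd = gd.reshape(B, d, h + 1)
    gu = gu.reshape(B, h, d + 1)
    W_D, b_D = gd[:, :, :h], gd[:, :, h]
    W_U, b_U = gu[:, :, :d], gu[:, :, d]
    beta, gamma = gl[:, :h], gl[:, h:]
    if squeeze:
        W_D, b_D = W_D.reshape(d, h), b_D.reshape(d)
        W_U, b_U = W_U.reshape(h, d), b_U.reshape(h)
        beta, gamma = beta.reshape(h), gamma.reshape(h)
    return AdapterParams(W_D=W_D, b_D=b_D, W_U=W_U, b_U=b_U, beta=beta, gamma=gamma)


# ---------------------------------------------------------------------------
# backbone forward


def _attention(x: Tensor, p: dict, l: int, cfg: EncoderConfig) -> Tensor:
    B, T, h = x.shape
    nh, dh = cfg.n_heads, h // cfg.n_heads

    def heads(t):
        return t.reshape(B, T, nh, dh).transpose(0, 2, 1, 3)  # (B, nh, T, dh)

    q = heads(x @ p[f"l{l}_Wq"] + p[f"l{l}_bq"])
    k = heads(x @ p[f"l{l}_Wk"] + p[f"l{l}_bk"])
    v = heads(x @ p[f"l{l}_Wv"] + p[f"l{l}_bv"])
    scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dh))
    attn = softmax(scores, axis=-1) @ v  # (B, nh, T, dh)
    merged = attn.transpose(0, 2, 1, 3).reshape(B, T, h)
    return merged @ p[f"l{l}_Wo"] + p[f"l{l}_bo"]


def backbone_forward(frames, backbone: dict, cfg: EncoderConfig,
                     adapters=None) -> Tensor:
    """Pre-LN transformer encoder -> temporal mean pool -> affine head.

    `adapters`: optional callable (layer, position) -> AdapterParams; each
    adapter transforms the sublayer output *before* the residual addition.
    Returns per-row scalar predictions (B,) (scalar Tensor for a single
    (T, F) input).
    """
    x = Tensor.as_tensor(frames)
    squeeze = x.ndim == 2
    if squeeze:
        x = x.reshape(1, *x.shape)
    if x.shape[-1] != cfg.input_dim:
        raise ValueError(f"expected {cfg.input_dim} feature channels, got {x.shape[-1]}")
    B, T, _ = x.shape

    hdd = x @ backbone["in_W"] + backbone["in_b"]
    if cfg.use_positions:
        hdd = hdd + Tensor(sinusoidal_positions(T, cfg.hidden)[None])

    for l in range(cfg.n_layers):
        a = _attention(
            layer_norm(hdd, backbone[f"l{l}_ln1_g"], backbone[f"l{l}_ln1_b"],
                       cfg.ln_eps),
            backbone, l, cfg)
        if adapters is not None:
            a = adapter_apply(a, adapters(l, 0), eps=cfg.ln_eps)
        hdd = hdd + a

        f_in = layer_norm(hdd, backbone[f"l{l}_ln2_g"], backbone[f"l{l}_ln2_b"],
                          cfg.ln_eps)
        f = gelu(f_in @ backbone[f"l{l}_ff_W1"] + backbone[f"l{l}_ff_b1"])
        f = f @ backbone[f"l{l}_ff_W2"] + backbone[f"l{l}_ff_b2"]
        if adapters is not None:
            f = adapter_apply(f, adapters(l, 1), eps=cfg.ln_eps)
        hdd = hdd + f

    hdd = layer_norm(hdd, backbone["final_ln_g"], backbone["final_ln_b"], cfg.ln_eps)
    pooled = hdd.mean(axis=1)  # (B, h)
    pred = (pooled @ backbone["head_w"] + backbone["head_b"]).reshape(-1)
    return pred.reshape(()) if squeeze else pred


def hyperformer_forward(frames, m_S, backbone: dict, hp: dict,
                        cfg: EncoderConfig) -> Tensor:
    """Personalized forward pass: adapter parameters for every (layer,
    position) site are generated on the fly from m_S."""
    m = Tensor.as_tensor(m_S)
    batched = Tensor.as_tensor(frames).ndim == 3

    cache = {}

    def adapters(l, j):
        if (l, j) not in cache:
            cond = conditioning_input(m, l, j, hp)
            I_S = subject_embedding(cond, hp)
            cache[(l, j)] = generate_adapter_params(I_S, hp, cfg)
        return cache[(l, j)]

    if batched and m.ndim != 2:
        raise ValueError("batched frames require a (B, M) metadata matrix")
    return backbone_forward(frames, backbone, cfg, adapters=adapters)


# ---------------------------------------------------------------------------
# parameter bookkeeping and checkpoints


def set_trainable(params: dict, trainable: bool) -> None:
    for t in params.values():
        t.requires_grad = trainable
        t.grad = None


def n_parameters(params: dict) -> int:
    return int(sum(t.data.size for t in params.values()))


def save_checkpoint(path, cfg: EncoderConfig, parameter_groups: dict,
                    extra: dict | None = None) -> None:
    """Single-file archive: config JSON + named parameter arrays; loadable
    without the training code."""
    arrays = {}
    for group, params in parameter_groups.items():
        for name, t in params.items():
            arrays[f"{group}/{name}"] = t.data
    meta = {"config": asdict(cfg), "groups": sorted(parameter_groups),
            "extra": extra or {}}
    buf = io.BytesIO()
    np.savez_compressed(buf, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)
    with open(path, "wb") as fh:
        fh.write(buf.getvalue())


def load_checkpoint(path):
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        cfg = EncoderConfig(**meta["config"])
        groups = {g: {} for g in meta["groups"]}
        for key in z.files:
            if key == "__meta__":
                continue
            g, name = key.split("/", 1)
            groups[g][name] = Tensor(z[key], requires_grad=True)
    return cfg, groups, meta["extra"]
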