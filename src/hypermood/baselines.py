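"""Comparison systems: plain FFNNs, additive-metadata personalized FFNNs,
and full fine-tuning of the frame encoder.

The FFNN baselines operate on pre-extracted functional feature vectors
(3 equal hidden ReLU layers; width 30 for acoustic functionals, 256 for
encoder embeddings). The personalized variant embeds the subject metadata
vector through a linear projection and adds it elementwise to the output of
the second hidden layer; with the projection zeroed it reduces exactly to
the plain FFNN. The fine-tuning baseline is the adapter-free encoder with
the transformer body and head trainable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, relu
from .hyperadapter_core import EncoderConfig, backbone_forward


@dataclass
class FFNNConfig:
    input_width: int
    hidden: int = 30  # all three hidden layers share this width
    meta_width: int | None = None  # |m_S| for the personalized variant
    seed: int = 0


def init_ffnn(cfg: FFNNConfig, personalized: bool = False) -> dict:
    rng = np.random.default_rng(cfg.seed)

    def xav(fi, fo):
        return Tensor(rng.normal(0, np.sqrt(2.0 / (fi + fo)), size=(fi, fo)),
                      requires_grad=True)

    def zeros(*shape):
        return Tensor(np.zeros(shape), requires_grad=True)

    w = {
        "W1": xav(cfg.input_width, cfg.hidden), "b1": zeros(cfg.hidden),
        "W2": xav(cfg.hidden, cfg.hidden), "b2": zeros(cfg.hidden),
        "W3": xav(cfg.hidden, cfg.hidden), "b3": zeros(cfg.hidden),
        "head_w": xav(cfg.hidden, 1), "head_b": zeros(1),
    }
    if personalized:
        if cfg.meta_width is None:
            raise ValueError("personalized FFNN needs meta_width")
        # zero-initialized projection: starts identical to the plain FFNN
        w["proj_W"] = zeros(cfg.meta_width, cfg.hidden)
        w["proj_b"] = zeros(cfg.hidden)
    return w


def _ffnn_core(x, cfg: FFNNConfig, weights: dict, m_S=None) -> Tensor:
    x = Tensor.as_tensor(x)
    squeeze = x.ndim == 1
    if squeeze:
        x = x.reshape(1, -1)
    if x.shape[-1] != cfg.input_width:
        raise ValueError(f"expected input width {cfg.input_width}, got {x.shape[-1]}")
    h1 = relu(x @ weights["W1"] + weights["b1"])
    h2 = relu(h1 @ weights["W2"] + weights["b2"])
    if m_S is not None:
        m = Tensor.as_tensor(m_S)
        if m.ndim == 1:
            m = m.reshape(1, -1)
        if weights["proj_W"].shape[1] != cfg.hidden:
            raise ValueError("metadata projection width must equal the hidden width")
        h2 = h2 + (m @ weights["proj_W"] + weights["proj_b"])
    h3 = relu(h2 @ weights["W3"] + weights["b3"])
    out = (h3 @ weights["head_w"] + weights["head_b"]).reshape(-1)
    return out.reshape(()) if squeeze else out


def ffnn_forward(x, cfg: FFNNConfig, weights: dict) -> Tensor:
    """affine -> ReLU (x3) -> affine head -> scalar per row."""
    return _ffnn_core(x, cfg, weights, m_S=None)


def personalized_ffnn_forward(x, m_S, cfg: FFNNConfig, weights: dict) -> Tensor:
    """Plain FFNN with Linear(m_S) added elementwise to hidden layer 2."""
    return _ffnn_core(x, cfg, weights, m_S=m_S)


def finetune_encoder_forward(frames, backbone: dict, cfg: EncoderConfig) -> Tensor:
    """Adapter-free encoder forward; in this training mode the transformer
    body and regression head are all trainable."""
    return backbone_forward(frames, backbone, cfg, adapters=None)


def ffnn_parameter_count(cfg: FFNNConfig, personalized: bool = False) -> int:
    w = init_ffnn(cfg, personalized=personalized)
    return int(sum(t.data.size for t in w.values()))
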