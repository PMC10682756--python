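"""Optimization: speaker-independent splits, AdamW with warmup, freeze
policies per model kind, and validation-based checkpoint selection.

Encoder-path models (fine-tuned encoder, hyperformer) default to batch size
16, learning rate 3e-4, at most 10 epochs; FFNN baselines to batch size 128,
learning rate 1e-4, at most 100 epochs. AdamW runs with a linear learning-rate
warmup over the first 10% of steps, constant at the peak afterwards. The
checkpoint maximizing the *global* Spearman correlation on the fold's
speaker-independent validation set is the one evaluated on the test set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from .autodiff import Tensor, relu
from .baselines import (FFNNConfig, ffnn_forward, finetune_encoder_forward,
                        init_ffnn, personalized_ffnn_forward)
from .evaluation import spearman_rho
from .hyperadapter_core import (EncoderConfig, hyperformer_forward,
                                init_backbone, init_hypernet)

MODEL_KINDS = ("ffnn", "ffnn-pers", "finetune", "hyperformer")
_ENCODER_KINDS = ("finetune", "hyperformer")


# ---------------------------------------------------------------------------
# splits


@dataclass
class FoldSplit:
    fold: int
    train: list
    val: list
    test: list


def make_splits(subjects: list, k: int = 5, val_fraction: float = 0.2,
                seed: int = 0) -> list:
    """Speaker-independent, group-stratified k-fold CV with a validation
    partition carved out of each fold's training side. Splits are always by
    subject, never by recording."""
    if k > len(subjects):
        raise ValueError(f"cannot make {k} folds from {len(subjects)} subjects")
    ids = np.array([s.subject_id for s in subjects])
    groups = np.array([s.group for s in subjects])
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    splits = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(ids, groups)):
        try:
            tr, va = train_test_split(
                train_idx, test_size=val_fraction, random_state=seed + fold,
                stratify=groups[train_idx])
        except ValueError:  # a stratum too small to stratify on
            tr, va = train_test_split(
                train_idx, test_size=val_fraction, random_state=seed + fold)
        splits.append(FoldSplit(
            fold=fold, train=list(ids[tr]), val=list(ids[va]),
            test=list(ids[test_idx])))
    return splits


# ---------------------------------------------------------------------------
# configuration


@dataclass
class TrainConfig:
    model: str = "hyperformer"
    batch_size: int = 16
    learning_rate: float = 3e-4
    max_epochs: int = 10
    warmup_fraction: float = 0.1
    loss: str = "mse"  # 'mse' (default; target is the 0-10 rating) or 'l1'
    weight_decay: float = 0.0
    seed: int = 0

    @classmethod
    def for_model(cls, kind: str, **overrides) -> "TrainConfig":
        if kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {kind!r}")
        if kind in _ENCODER_KINDS:
            base = cls(model=kind, batch_size=16, learning_rate=3e-4, max_epochs=10)
        else:
            base = cls(model=kind, batch_size=128, learning_rate=1e-4, max_epochs=100)
        return replace(base, **overrides)


@dataclass
class Checkpoint:
    params: dict  # group -> {name: ndarray} (validation-selected weights)
    epoch: int
    val_score: float
    config: TrainConfig
    history: list = field(default_factory=list)  # per-epoch (loss, val score)


# ---------------------------------------------------------------------------
# models


@dataclass
class Model:
    kind: str
    groups: dict  # parameter groups, each {name: Tensor}
    enc_cfg: EncoderConfig | None = None
    ffnn_cfg: FFNNConfig | None = None

    def predict(self, batch: dict) -> Tensor:
        if self.kind == "ffnn":
            return ffnn_forward(batch["x"], self.ffnn_cfg, self.groups["ffnn"])
        if self.kind == "ffnn-pers":
            return personalized_ffnn_forward(
                batch["x"], batch["m"], self.ffnn_cfg, self.groups["ffnn"])
        if self.kind == "finetune":
            return finetune_encoder_forward(
                batch["frames"], self.groups["backbone"], self.enc_cfg)
        if self.kind == "hyperformer":
            return hyperformer_forward(
                batch["frames"], batch["m"], self.groups["backbone"],
                self.groups["hypernet"], self.enc_cfg)
        raise ValueError(f"unknown model kind {self.kind!r}")

    def trainable(self) -> dict:
        """name -> Tensor for exactly the parameters this kind trains."""
        if self.kind in ("ffnn", "ffnn-pers"):
            return {f"ffnn/{k}": t for k, t in self.groups["ffnn"].items()}
        if self.kind == "finetune":
            return {f"backbone/{k}": t for k, t in self.groups["backbone"].items()}
        # hyperformer: the backbone stays frozen; only the weight-generating
        # hypernetworks and the final prediction layer train
        out = {f"hypernet/{k}": t for k, t in self.groups["hypernet"].items()}
        out["backbone/head_w"] = self.groups["backbone"]["head_w"]
        out["backbone/head_b"] = self.groups["backbone"]["head_b"]
        return out

    def frozen(self) -> dict:
        trainable = set(map(id, self.trainable().values()))
        return {f"{g}/{k}": t for g, grp in self.groups.items()
                for k, t in grp.items() if id(t) not in trainable}

    def set_freeze_policy(self) -> None:
        for t in self.frozen().values():
            t.requires_grad = False
            t.grad = None
        for t in self.trainable().values():
            t.requires_grad = True

    def state(self) -> dict:
        return {g: {k: t.data.copy() for k, t in grp.items()}
                for g, grp in self.groups.items()}

    def load_state(self, state: dict) -> None:
        for g, grp in state.items():
            for k, arr in grp.items():
                self.groups[g][k].data = arr.copy()


def build_model(kind: str, input_width: int | None = None,
                meta_width: int | None = None,
                enc_cfg: EncoderConfig | None = None,
                ffnn_hidden: int = 30, seed: int = 0,
                backbone_state: dict | None = None) -> Model:
    """Construct an initialized model; `backbone_state` lets the hyperformer
    start from a fine-tuned encoder's weights."""
    if kind in ("ffnn", "ffnn-pers"):
        fc = FFNNConfig(input_width=input_width, hidden=ffnn_hidden,
                        meta_width=meta_width, seed=seed)
        groups = {"ffnn": init_ffnn(fc, personalized=(kind == "ffnn-pers"))}
        return Model(kind=kind, groups=groups, ffnn_cfg=fc)
    if kind in _ENCODER_KINDS:
        enc_cfg = enc_cfg or EncoderConfig(seed=seed)
        backbone = init_backbone(enc_cfg, seed=seed)
        if backbone_state is not None:
            for k, arr in backbone_state.items():
                backbone[k].data = arr.copy()
        groups = {"backbone": backbone}
        if kind == "hyperformer":
            if meta_width is None:
                raise ValueError("hyperformer needs meta_width")
            groups["hypernet"] = init_hypernet(enc_cfg, meta_width, seed=seed)
        return Model(kind=kind, groups=groups, enc_cfg=enc_cfg)
    raise ValueError(f"unknown model kind {kind!r}")


# ---------------------------------------------------------------------------
# optimizer


class AdamW:
    """AdamW with decoupled weight decay."""

    def __init__(self, params: dict, lr: float = 3e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = dict(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(t.data) for k, t in self.params.items()}
        self.v = {k: np.zeros_like(t.data) for k, t in self.params.items()}

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= lr * (mhat / (np.sqrt(vhat) + self.eps)
                            + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def warmup_lr(step: int, total_steps: int, cfg: TrainConfig) -> float:
    """Linear warmup to the configured peak, constant afterwards."""
    warmup_steps = max(int(round(cfg.warmup_fraction * total_steps)), 1)
    return cfg.learning_rate * min(1.0, (step + 1) / warmup_steps)


# ---------------------------------------------------------------------------
# train loop


def _loss(pred: Tensor, y: np.ndarray, kind: str) -> Tensor:
    diff = pred - Tensor(y)
    if kind == "mse":
        return (diff * diff).mean()
    if kind == "l1":
        return (relu(diff) + relu(-diff)).mean()
    raise ValueError(f"unknown loss {kind!r}")


def _batch_slice(data: dict, idx: np.ndarray) -> dict:
    out = {}
    for key in ("x", "m", "frames"):
        if key in data and data[key] is not None:
            out[key] = data[key][idx]
    return out


def predict_rows(model: Model, data: dict, batch_size: int = 512) -> np.ndarray:
    """Forward pass without building gradient graphs."""
    flags = [(t, t.requires_grad) for grp in model.groups.values()
             for t in grp.values()]
    for t, _ in flags:
        t.requires_grad = False
    try:
        n = len(data["y"]) if "y" in data else len(next(
            data[k] for k in ("x", "frames") if data.get(k) is not None))
        preds = []
        for start in range(0, n, batch_size):
            idx = np.arange(start, min(start + batch_size, n))
            preds.append(model.predict(_batch_slice(data, idx)).data)
        return np.concatenate(preds)
    finally:
        for t, flag in flags:
            t.requires_grad = flag


def _global_spearman(pred: np.ndarray, y: np.ndarray) -> float:
    if np.std(pred) == 0 or np.std(y) == 0:
        return 0.0
    return spearman_rho(pred, y)


def train(model: Model, fold_data: dict, cfg: TrainConfig) -> Checkpoint:
    """Train `model` on fold_data['train'], selecting the checkpoint with the
    best global validation Spearman. fold_data: {'train': ..., 'val': ...},
    each with keys y and (x | frames) and m where applicable."""
    train_data, val_data = fold_data["train"], fold_data["val"]
    n = len(train_data["y"])
    if n == 0:
        raise ValueError("empty training set")

    model.set_freeze_policy()
    params = model.trainable()
    # untouched regression heads start at the training-target mean, so every
    # checkpoint's output scale is at least mean-calibrated
    for name, t in params.items():
        if name.endswith("head_b") and not t.data.any():
            t.data = np.full_like(t.data, float(np.mean(train_data["y"])))
    opt = AdamW(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)

    steps_per_epoch = int(np.ceil(n / cfg.batch_size))
    total_steps = steps_per_epoch * cfg.max_epochs
    step = 0
    best = None
    history = []

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch = _batch_slice(train_data, idx)
            pred = model.predict(batch)
            loss = _loss(pred, train_data["y"][idx], cfg.loss)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, step {step}: {loss.data}")
            opt.zero_grad()
            loss.backward()
            opt.step(lr=warmup_lr(step, total_steps, cfg))
            epoch_loss += float(loss.data) * len(idx)
            step += 1
        epoch_loss /= n

        val_pred = predict_rows(model, val_data)
        val_score = _global_spearman(val_pred, val_data["y"])
        history.append({"epoch": epoch, "train_loss": epoch_loss,
                        "val_score": val_score})
        if best is None or val_score > best[0]:
            best = (val_score, epoch, model.state())

    val_score, epoch, state = best
    model.load_state(state)
    return Checkpoint(params=state, epoch=epoch, val_score=val_score,
                      config=cfg, history=history)
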