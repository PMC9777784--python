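"""Minibatch gradient descent over a curriculum of batch sets.

The reference classifier is a small convolutional text model — embedding
lookup, parallel convolutions of widths 2/3/4 with ReLU and max-over-time
pooling, and a linear layer to one logit per label — trained against the
element-wise sigmoid binary cross-entropy. Forward and backward passes are
implemented directly in NumPy; parameters are updated with Adam at the
default learning rate 0.008 for a default 150 epochs split into three
50-epoch curriculum phases.

The model contract is deliberately small (``init_params`` /
``loss_and_grads`` / ``logits``), so other architectures can be dropped in
without touching the training loop.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .batching import BatchKind, BatchSet, CurriculumSchedule, build_schedule
from .metrics import micro_metrics
from .preprocess import EncodedCorpus

Params = dict[str, np.ndarray]


@dataclass
class ModelSpec:
    """Architecture hyperparameters of the reference convolutional classifier."""

    vocab_size: int  # number of token ids, including the unknown/padding id
    n_labels: int
    embedding_dim: int = 16
    filter_widths: tuple[int, ...] = (2, 3, 4)
    n_filters: int = 8
    kind: str = "textcnn"

    def __post_init__(self) -> None:
        if self.kind != "textcnn":
            raise ValueError(f"unknown architecture kind {self.kind!r}")
        if self.n_labels < 1 or self.vocab_size < 1:
            raise ValueError("need at least one label and one token id")
        if min(self.filter_widths) < 1:
            raise ValueError("filter widths must be ≥ 1")

    @property
    def n_parameters(self) -> int:
        d, f, L = self.embedding_dim, self.n_filters, self.n_labels
        conv = sum(w * d * f + f for w in self.filter_widths)
        out = len(self.filter_widths) * f * L + L
        return self.vocab_size * d + conv + out


INIT_RANGE = 0.05


def init_params(model_spec: ModelSpec, seed: int) -> Params:
    """Seeded uniform initialization in [-0.05, 0.05] for every parameter."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(17,)))
    s = model_spec

    def u(*shape: int) -> np.ndarray:
        return rng.uniform(-INIT_RANGE, INIT_RANGE, size=shape)

    params: Params = {"emb": u(s.vocab_size, s.embedding_dim)}
    for w in s.filter_widths:
        params[f"conv{w}_W"] = u(w * s.embedding_dim, s.n_filters)
        params[f"conv{w}_b"] = u(s.n_filters)
    params["out_W"] = u(len(s.filter_widths) * s.n_filters, s.n_labels)
    params["out_b"] = u(s.n_labels)
    return params


def bce_loss(logits: np.ndarray, targets: np.ndarray) -> float:
    """Mean element-wise sigmoid binary cross-entropy, computed stably on logits.

    −[y·log σ(x) + (1−y)·log(1−σ(x))] = max(x,0) − x·y + log(1 + e^(−|x|)).
    """
    x = np.asarray(logits, dtype=float)
    y = np.asarray(targets, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: logits {x.shape} vs targets {y.shape}")
    return float(np.mean(np.maximum(x, 0) - x * y + np.log1p(np.exp(-np.abs(x)))))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


_NEG = -1e30  # sentinel for invalid (padding) pool positions


def _pad_batch(
    token_ids: Sequence[np.ndarray], min_len: int
) -> tuple[np.ndarray, np.ndarray]:
    """Right-pad sequences with the unknown id into one (B, T) matrix."""
    lengths = np.array([len(t) for t in token_ids], dtype=np.int64)
    T = max(int(lengths.max()), min_len)
    ids = np.zeros((len(token_ids), T), dtype=np.int64)
    for i, t in enumerate(token_ids):
        ids[i, : len(t)] = t
    return ids, lengths


def _forward(
    params: Params, spec: ModelSpec, ids: np.ndarray, lengths: np.ndarray
) -> tuple[np.ndarray, dict]:
    """Logits plus the cache needed for the backward pass."""
    B, T = ids.shape
    X = params["emb"][ids]  # (B, T, d)
    feats, cache = [], {"ids": ids, "X": X, "per_width": []}
    for w in spec.filter_widths:
        P = T - w + 1
        win = np.concatenate(
            [X[:, j : j + P, :] for j in range(w)], axis=2
        )  # (B, P, w*d)
        A = win @ params[f"conv{w}_W"] + params[f"conv{w}_b"]  # (B, P, F)
        R = np.maximum(A, 0.0)
        # positions whose window would overlap padding are masked out;
        # documents shorter than w keep position 0 (padded window)
        valid = np.maximum(lengths - w + 1, 1)
        pos = np.arange(P)[None, :]
        R = np.where(pos[:, :, None] < valid[:, None, None], R, _NEG)
        pmax = R.argmax(axis=1)  # (B, F)
        h = np.take_along_axis(R, pmax[:, None, :], axis=1)[:, 0, :]
        feats.append(h)
        cache["per_width"].append({"w": w, "win": win, "A": A, "pmax": pmax})
    H = np.concatenate(feats, axis=1)  # (B, n_widths*F)
    cache["H"] = H
    logits = H @ params["out_W"] + params["out_b"]
    return logits, cache


def logits(
    params: Params,
    spec: ModelSpec,
    token_ids: Sequence[np.ndarray],
    chunk: int = 256,
) -> np.ndarray:
    """Forward pass over arbitrary documents, in chunks."""
    out = []
    min_len = max(spec.filter_widths)
    for i in range(0, len(token_ids), chunk):
        ids, lengths = _pad_batch(token_ids[i : i + chunk], min_len)
        out.append(_forward(params, spec, ids, lengths)[0])
    return np.concatenate(out, axis=0)


def loss_and_grads(
    params: Params,
    spec: ModelSpec,
    ids: np.ndarray,
    lengths: np.ndarray,
    targets: np.ndarray,
) -> tuple[float, Params]:
    """Mean BCE loss over the batch and the gradient for every parameter."""
    lg, cache = _forward(params, spec, ids, lengths)
    loss = bce_loss(lg, targets)
    B, L = lg.shape
    dlogits = (_sigmoid(lg) - targets) / (B * L)

    grads: Params = {}
    grads["out_W"] = cache["H"].T @ dlogits
    grads["out_b"] = dlogits.sum(axis=0)
    dH = dlogits @ params["out_W"].T  # (B, n_widths*F)

    X = cache["X"]
    dX = np.zeros_like(X)
    F = spec.n_filters
    rows = np.arange(B)[:, None]
    cols = np.arange(F)[None, :]
    for k, pw in enumerate(cache["per_width"]):
        w, win, A, pmax = pw["w"], pw["win"], pw["A"], pw["pmax"]
        dh = dH[:, k * F : (k + 1) * F]  # (B, F)
        # gradient reaches only the argmax position of each filter, and only
        # where the pre-activation was positive (ReLU)
        dA = np.zeros_like(A)
        dA[rows, pmax, cols] = dh * (A[rows, pmax, cols] > 0)
        grads[f"conv{w}_W"] = win.reshape(-1, win.shape[2]).T @ dA.reshape(-1, F)
        grads[f"conv{w}_b"] = dA.sum(axis=(0, 1))
        dwin = dA @ params[f"conv{w}_W"].T  # (B, P, w*d)
        P, d = A.shape[1], spec.embedding_dim
        for j in range(w):
            dX[:, j : j + P, :] += dwin[:, :, j * d : (j + 1) * d]

    demb = np.zeros_like(params["emb"])
    np.add.at(demb, cache["ids"].ravel(), dX.reshape(-1, spec.embedding_dim))
    grads["emb"] = demb
    return loss, grads


class Adam:
    """Adam optimizer (β1=0.9, β2=0.999, eps=1e-8) over a parameter dict."""

    def __init__(
        self,
        params: Params,
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: Params) -> None:
        self.t += 1
        b1c = 1 - self.beta1**self.t
        b2c = 1 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            self.params[k] -= (
                self.lr * (self.m[k] / b1c) / (np.sqrt(self.v[k] / b2c) + self.eps)
            )


@dataclass
class TrainConfig:
    """Training hyperparameters; defaults mirror the reference protocol."""

    batch_size: int = 1000
    learning_rate: float = 0.008
    schedule: CurriculumSchedule = field(default_factory=build_schedule)
    seed: int = 0
    prediction_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if not (0.0 < self.prediction_threshold < 1.0):
            raise ValueError("prediction threshold must lie strictly in (0, 1)")

    @property
    def total_epochs(self) -> int:
        return self.schedule.total_epochs


@dataclass
class TrainState:
    """Everything the training loop produced."""

    params: Params
    model_spec: ModelSpec
    config: TrainConfig
    loss_history: list[float]
    phase_history: list[str]
    phase_switch_epochs: list[int]
    val_f1_history: list[float] = field(default_factory=list)
    best_epoch: int | None = None
    best_params: Params | None = None

    def selected_params(self) -> Params:
        """Best-on-validation parameters if tracked, else the final ones."""
        return self.best_params if self.best_params is not None else self.params

    def loss_history_tsv(self) -> str:
        lines = ["epoch\tphase\tmean_loss"]
        for i, (ph, lo) in enumerate(zip(self.phase_history, self.loss_history)):
            lines.append(f"{i}\t{ph}\t{lo:.8f}")
        return "\n".join(lines) + "\n"


@dataclass
class PredictionMatrix:
    """Per-example, per-label sigmoid scores and thresholded decisions."""

    scores: np.ndarray
    decisions: np.ndarray
    threshold: float


def predict(
    state_or_params: "TrainState | Params",
    encoded: EncodedCorpus,
    threshold: float = 0.5,
    model_spec: ModelSpec | None = None,
) -> PredictionMatrix:
    """Sigmoid scores with the decision rule score ≥ threshold → positive."""
    if isinstance(state_or_params, TrainState):
        params = state_or_params.selected_params()
        model_spec = state_or_params.model_spec
    else:
        params = state_or_params
        if model_spec is None:
            raise ValueError("model_spec is required when passing bare parameters")
    if model_spec.n_labels != encoded.n_labels:
        raise ValueError(
            f"model predicts {model_spec.n_labels} labels but corpus has "
            f"{encoded.n_labels}"
        )
    scores = _sigmoid(logits(params, model_spec, encoded.token_ids))
    return PredictionMatrix(scores, (scores >= threshold).astype(np.int8), threshold)


def train(
    train_encoded: EncodedCorpus,
    batchsets: dict[BatchKind, BatchSet],
    model_spec: ModelSpec,
    config: TrainConfig,
    val_encoded: EncodedCorpus | None = None,
    batchset_factory: "Callable[[int, BatchKind], BatchSet] | None" = None,
    n_epochs: int | None = None,
) -> TrainState:
    """Run the curriculum MBGD loop.

    Each epoch iterates every batch of the scheduled batch set, computes the
    mean example loss and applies one Adam update per batch. Batch sets are
    built offline and reused across the epochs of a phase unless
    ``batchset_factory`` is given (then it is called as ``factory(epoch,
    kind)`` to regenerate the batch set each epoch). If a validation corpus
    is provided, the parameters with the best validation micro-F1 are kept
    alongside the final ones. ``n_epochs`` truncates the schedule (0 returns
    the untouched initialization with an empty history).
    """
    for kind in config.schedule.kinds():
        if kind not in batchsets and batchset_factory is None:
            raise ValueError(f"schedule needs batch set {kind.value}, not provided")
    params = init_params(model_spec, config.seed)
    opt = Adam(params, config.learning_rate)
    doc_index = train_encoded.doc_index
    min_len = max(model_spec.filter_widths)

    state = TrainState(
        params=params,
        model_spec=model_spec,
        config=config,
        loss_history=[],
        phase_history=[],
        phase_switch_epochs=config.schedule.phase_starts,
    )
    best_f1 = -1.0
    total = config.schedule.total_epochs if n_epochs is None else min(
        n_epochs, config.schedule.total_epochs
    )
    for epoch in range(total):
        kind = config.schedule.kind_for_epoch(epoch)
        bs = (
            batchset_factory(epoch, kind)
            if batchset_factory is not None
            else batchsets[kind]
        )
        losses = []
        for batch in bs.batches:
            idx = [doc_index[d] for d in batch.doc_ids]
            ids, lengths = _pad_batch([train_encoded.token_ids[i] for i in idx], min_len)
            targets = train_encoded.label_matrix[idx].astype(float)
            loss, grads = loss_and_grads(params, model_spec, ids, lengths, targets)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            opt.step(grads)
            losses.append(loss)
        state.loss_history.append(float(np.mean(losses)))
        state.phase_history.append(kind.value)
        if val_encoded is not None:
            pm = predict(params, val_encoded, config.prediction_threshold, model_spec)
            _, _, f1 = micro_metrics(pm.decisions, val_encoded.label_matrix)
            state.val_f1_history.append(f1)
            if f1 > best_f1:
                best_f1 = f1
                state.best_epoch = epoch
                state.best_params = copy.deepcopy(params)
    return state
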