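"""Bidirectional LSTM relation classifier, training protocol and metrics.

Architecture: embedding layer (CBOW-initialized, fine-tuned by default) →
LSTM read in one or both directions → final hidden states concatenated →
dropout 0.5 → dense layer with tanh → 2-unit output → log-softmax, with the
prediction taken as the argmax of the two log-probabilities.  Training uses
cross-entropy loss and Adam (learning rate 0.01, weight decay 1e-4, hidden
size 150; the learning rate halves every 500 optimizer steps).

The training protocol mirrors sparse-data practice: within every epoch cycle
the training partition is reshuffled and split into five folds; each fold in
turn is held out for validation while the other four are trained on, so one
cycle comprises five train/validate experiments and folds never repeat across
cycles.  The parameter snapshot with the best validation F1 is kept.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .embeddings import EmbeddingMatrix, Vocabulary
from .instances import PAD, TokenizedInstance
from .nn import Adam, LSTMCache, clip_gradients, init_lstm_params, log_softmax, lstm_backward, lstm_forward

logger = logging.getLogger(__name__)

N_FOLDS = 5


class DegenerateDataError(ValueError):
    """Training data with a single class cannot fit a binary classifier."""


class ShapeError(ValueError):
    """Instance length does not match the model's configured sequence length."""


@dataclass
class ModelConfig:
    """Hyperparameters of the classifier and its training protocol."""

    hidden_size: int = 150
    learn_rate: float = 0.01
    dropout: float = 0.50
    weight_decay: float = 0.0001
    learn_rate_decay: int = 500        # optimizer steps between learning-rate halvings
    optimizer: str = "ADAM"
    bidirectional: bool = True
    epochs: int = 30                   # epoch cycles (each cycle = 5 fold experiments)
    batch_size: int = 32
    seed: int = 0
    patience: int = 3                  # early-stop after this many cycles without val-F1 gain
    grad_clip: float = 5.0
    finetune_embeddings: bool = True
    model_selection: str = "best_fold"  # or "final"

    def __post_init__(self) -> None:
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.learn_rate <= 0:
            raise ValueError("learn_rate must be positive")
        if self.hidden_size < 1:
            raise ValueError("hidden_size must be >= 1")
        if self.optimizer.upper() != "ADAM":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class MetricsReport:
    """Confusion counts and the derived closed-form scores."""

    tp: int
    fp: int
    tn: int
    fn: int
    precision: float
    recall: float
    accuracy: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def compute_metrics(tp: int, fp: int, tn: int, fn: int) -> MetricsReport:
    """Precision, recall, accuracy and F1 from confusion counts.

    Zero-denominator conventions: precision = 0 when TP+FP = 0, recall = 0
    when TP+FN = 0, F1 = 0 when precision+recall = 0.
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("no evaluated instances")
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    accuracy = (tp + tn) / total
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return MetricsReport(tp=tp, fp=fp, tn=tn, fn=fn, precision=precision, recall=recall, accuracy=accuracy, f1=f1)


def _encode(instances: Sequence[TokenizedInstance], vocab: Vocabulary) -> tuple[np.ndarray, np.ndarray]:
    lengths = {len(i.tokens) for i in instances}
    if len(lengths) != 1:
        raise ShapeError(f"instances have differing lengths: {sorted(lengths)}")
    X = np.stack([vocab.encode(i.tokens) for i in instances])
    y = np.array([i.label for i in instances], dtype=np.int64)
    return X, y


class RelationModel:
    """A trained (or freshly initialized) LSTM relation classifier."""

    def __init__(self, embeddings: EmbeddingMatrix, config: ModelConfig, max_len: int, rng: np.random.Generator):
        self.vocab = embeddings.vocab
        self.config = config
        self.max_len = max_len
        self.pad_index = self.vocab.token_to_index[PAD]
        h = config.hidden_size
        d = embeddings.dim
        summary_dim = 2 * h if config.bidirectional else h
        self.summary_dim = summary_dim
        p: dict[str, np.ndarray] = {"E": embeddings.weights.astype(np.float32).copy()}
        fwd = init_lstm_params(rng, d, h)
        p.update({"W_f": fwd["W"], "U_f": fwd["U"], "b_f": fwd["b"]})
        if config.bidirectional:
            bwd = init_lstm_params(rng, d, h)
            p.update({"W_b": bwd["W"], "U_b": bwd["U"], "b_b": bwd["b"]})
        lim1 = np.sqrt(6.0 / (summary_dim + h))
        p["W_d"] = rng.uniform(-lim1, lim1, size=(summary_dim, h)).astype(np.float32)
        p["b_d"] = np.zeros(h, dtype=np.float32)
        lim2 = np.sqrt(6.0 / (h + 2))
        p["W_o"] = rng.uniform(-lim2, lim2, size=(h, 2)).astype(np.float32)
        p["b_o"] = np.zeros(2, dtype=np.float32)
        self.params = p
        self.history: dict[str, list] = {"train_loss": [], "val_f1": [], "folds_per_cycle": []}

    # ---------------------------------------------------------------- forward

    def _mask(self, X: np.ndarray) -> np.ndarray:
        return (X != self.pad_index).astype(np.float32)

    def forward(
        self, X: np.ndarray, dropout_rng: np.random.Generator | None = None
    ) -> tuple[np.ndarray, dict]:
        """Log-probabilities (B×2) and the cache for backprop.

        Dropout on the concatenated recurrent summary is applied only when a
        ``dropout_rng`` is supplied (training mode).
        """
        p, cfg = self.params, self.config
        mask = self._mask(X)
        emb = p["E"][X]
        h_f, cache_f = lstm_forward(emb, mask, {"W": p["W_f"], "U": p["U_f"], "b": p["b_f"]}, reverse=False)
        caches: dict = {"X": X, "mask": mask, "emb": emb, "f": cache_f}
        if cfg.bidirectional:
            h_b, cache_b = lstm_forward(emb, mask, {"W": p["W_b"], "U": p["U_b"], "b": p["b_b"]}, reverse=True)
            caches["b"] = cache_b
            summary = np.concatenate([h_f, h_b], axis=1)
        else:
            summary = h_f
        if dropout_rng is not None and cfg.dropout > 0:
            keep = (dropout_rng.random(summary.shape) >= cfg.dropout).astype(np.float32)
            drop_mask = keep / (1.0 - cfg.dropout)
        else:
            drop_mask = np.ones_like(summary)
        dropped = summary * drop_mask
        z1 = np.tanh(dropped @ p["W_d"] + p["b_d"])
        logits = z1 @ p["W_o"] + p["b_o"]
        logp = log_softmax(logits)
        caches.update({"summary": summary, "drop_mask": drop_mask, "dropped": dropped, "z1": z1, "logp": logp})
        return logp, caches

    def backward(self, caches: dict, y: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of mean cross-entropy w.r.t. every parameter."""
        p, cfg = self.params, self.config
        B = y.shape[0]
        probs = np.exp(caches["logp"])
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        z1 = caches["z1"]
        grads: dict[str, np.ndarray] = {}
        grads["W_o"] = z1.T @ dlogits
        grads["b_o"] = dlogits.sum(axis=0)
        dz1 = (dlogits @ p["W_o"].T) * (1.0 - z1 * z1)
        grads["W_d"] = caches["dropped"].T @ dz1
        grads["b_d"] = dz1.sum(axis=0)
        dsummary = (dz1 @ p["W_d"].T) * caches["drop_mask"]
        h = cfg.hidden_size
        T = caches["X"].shape[1]
        if cfg.bidirectional:
            dh_f, dh_b = dsummary[:, :h], dsummary[:, h:]
        else:
            dh_f, dh_b = dsummary, None
        g_f, demb = lstm_backward(dh_f, {"W": p["W_f"], "U": p["U_f"], "b": p["b_f"]}, caches["f"], reverse=False, T=T)
        grads.update({"W_f": g_f["W"], "U_f": g_f["U"], "b_f": g_f["b"]})
        if dh_b is not None:
            g_b, demb_b = lstm_backward(dh_b, {"W": p["W_b"], "U": p["U_b"], "b": p["b_b"]}, caches["b"], reverse=True, T=T)
            grads.update({"W_b": g_b["W"], "U_b": g_b["U"], "b_b": g_b["b"]})
            demb = demb + demb_b
        gE = np.zeros_like(p["E"])
        if cfg.finetune_embeddings:
            np.add.at(gE, caches["X"], demb)
            gE[self.pad_index] = 0.0
        grads["E"] = gE
        return grads

    # -------------------------------------------------------------- inference

    def log_probabilities(self, instances: Sequence[TokenizedInstance]) -> np.ndarray:
        for inst in instances:
            if len(inst.tokens) != self.max_len:
                raise ShapeError(f"instance length {len(inst.tokens)} != configured {self.max_len}")
        X, _ = _encode(instances, self.vocab)
        logp, _ = self.forward(X, dropout_rng=None)
        return logp

    def predict(self, instances: Sequence[TokenizedInstance]) -> np.ndarray:
        """Argmax class per instance; an exact log-probability tie predicts 0."""
        logp = self.log_probabilities(instances)
        return (logp[:, 1] > logp[:, 0]).astype(np.int64)

    def snapshot(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def restore(self, snap: dict[str, np.ndarray]) -> None:
        self.params = {k: v.copy() for k, v in snap.items()}

    def save(self, path: str | Path) -> None:
        import json

        meta = dict(asdict(self.config), max_len=self.max_len)
        np.savez(path, __meta__=np.array([json.dumps(meta)]), **self.params)


def classify(model: RelationModel, instance: TokenizedInstance) -> int:
    """Binary prediction for a single instance (deterministic in eval mode)."""
    return int(model.predict([instance])[0])


def evaluate_model(model: RelationModel, instances: Sequence[TokenizedInstance]) -> MetricsReport:
    pred = model.predict(instances)
    y = np.array([i.label for i in instances])
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    return compute_metrics(tp, fp, tn, fn)


def kfold_indices(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Shuffled split of range(n) into k near-equal folds."""
    return [f for f in np.array_split(rng.permutation(n), k)]


def train_model(
    train: Sequence[TokenizedInstance],
    embeddings: EmbeddingMatrix,
    config: ModelConfig,
) -> RelationModel:
    """Fit the classifier with the shuffled five-fold protocol.

    Every epoch cycle reshuffles the training partition into ``N_FOLDS`` folds;
    each fold serves once as the validation set while the model trains one pass
    over the remaining four, so a cycle is five experiments and the folds never
    repeat between cycles.  Early stopping monitors the cycle-mean validation
    F1; the returned model carries the best-validation-F1 snapshot (or the
    final weights when ``model_selection="final"``).
    """
    if not train:
        raise ValueError("empty training set")
    labels = {i.label for i in train}
    if labels != {0, 1}:
        raise DegenerateDataError(f"training data must contain both classes, found {sorted(labels)}")
    max_len = len(train[0].tokens)
    rng = np.random.default_rng(config.seed)
    model = RelationModel(embeddings, config, max_len=max_len, rng=rng)
    X, y = _encode(train, model.vocab)
    no_decay = ("b_f", "b_b", "b_d", "b_o", "E")
    opt = Adam(
        model.params, lr=config.learn_rate, weight_decay=config.weight_decay,
        lr_halving_steps=config.learn_rate_decay, no_decay=no_decay,
    )
    best_f1, best_snap, stale = -1.0, None, 0
    n = len(train)
    for cycle in range(config.epochs):
        folds = kfold_indices(n, N_FOLDS, rng)
        model.history["folds_per_cycle"].append(len(folds))
        cycle_losses, cycle_f1s = [], []
        for k, val_idx in enumerate(folds):
            train_idx = np.concatenate([f for j, f in enumerate(folds) if j != k])
            for lo in range(0, len(train_idx), config.batch_size):
                sel = train_idx[lo:lo + config.batch_size]
                logp, caches = model.forward(X[sel], dropout_rng=rng)
                loss = float(-logp[np.arange(len(sel)), y[sel]].mean())
                cycle_losses.append(loss)
                grads = model.backward(caches, y[sel])
                clip_gradients(grads, config.grad_clip)
                opt.step(grads)
            val_logp, _ = model.forward(X[val_idx], dropout_rng=None)
            val_pred = (val_logp[:, 1] > val_logp[:, 0]).astype(np.int64)
            yv = y[val_idx]
            rep = compute_metrics(
                tp=int(((val_pred == 1) & (yv == 1)).sum()),
                fp=int(((val_pred == 1) & (yv == 0)).sum()),
                tn=int(((val_pred == 0) & (yv == 0)).sum()),
                fn=int(((val_pred == 0) & (yv == 1)).sum()),
            )
            cycle_f1s.append(rep.f1)
            if config.model_selection == "best_fold" and rep.f1 > best_f1:
                best_f1, best_snap = rep.f1, model.snapshot()
        mean_f1 = float(np.mean(cycle_f1s))
        model.history["train_loss"].append(float(np.mean(cycle_losses)))
        model.history["val_f1"].append(mean_f1)
        if mean_f1 > max(model.history["val_f1"][:-1], default=-1.0):
            stale = 0
        else:
            stale += 1
        logger.debug("cycle %d: loss=%.4f val_f1=%.4f", cycle, model.history["train_loss"][-1], mean_f1)
        if stale >= config.patience:
            break
    if config.model_selection == "best_fold" and best_snap is not None:
        history = model.history
        model.restore(best_snap)
        model.history = history
    return model


@dataclass
class ExperimentSummary:
    """Per-run test metrics with their mean ± standard deviation (Table-style)."""

    dataset: str
    model_tag: str
    runs: list[MetricsReport]
    mean: dict[str, float] = field(init=False)
    sd: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        names = ("precision", "recall", "accuracy", "f1")
        vals = {m: np.array([getattr(r, m) for r in self.runs]) for m in names}
        self.mean = {m: float(v.mean()) for m, v in vals.items()}
        self.sd = {m: float(v.std(ddof=0)) for m, v in vals.items()}

    def format_row(self) -> str:
        """One table row, scores as percentages with ± sd."""
        cells = [
            f"{100 * self.mean[m]:.2f} ± {100 * self.sd[m]:.1f}"
            for m in ("precision", "recall", "accuracy", "f1")
        ]
        return "\t".join([self.dataset, self.model_tag] + cells)

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["run", "precision", "recall", "accuracy", "f1"])
            for i, r in enumerate(self.runs, start=1):
                writer.writerow([i, f"{r.precision:.6f}", f"{r.recall:.6f}", f"{r.accuracy:.6f}", f"{r.f1:.6f}"])


def run_experiments(
    train: Sequence[TokenizedInstance],
    test: Sequence[TokenizedInstance],
    embeddings: EmbeddingMatrix,
    config: ModelConfig,
    n_runs: int = 30,
    dataset: str = "synthetic",
) -> ExperimentSummary:
    """Repeat the full training protocol ``n_runs`` times with fresh seeds.

    Each run re-seeds initialization and shuffling (seed + run index) and
    scores the held-out, paper-disjoint test partition.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    reports = []
    for run in range(n_runs):
        cfg = ModelConfig(**{**asdict(config), "seed": config.seed + run})
        model = train_model(train, embeddings, cfg)
        reports.append(evaluate_model(model, test))
        logger.info("run %d/%d: acc=%.4f f1=%.4f", run + 1, n_runs, reports[-1].accuracy, reports[-1].f1)
    tag = "bidirectional" if config.bidirectional else "unidirectional"
    return ExperimentSummary(dataset=dataset, model_tag=tag, runs=reports)
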