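"""Splitting, training loop, metrics and multi-replicate orchestration.

The training protocol: Adam (initial LR 0.001), two-class cross-entropy,
LR multiplied by 0.1 after 10 epochs without validation-loss improvement
(floor 1e-6), early stopping after 100 non-improving epochs, up to 1000
epochs; the returned parameters are those of the best-validation-loss
epoch.  Experiments repeat this over independent stratified
0.7:0.15:0.15 splits (30 by default), re-fitting the word embeddings on
each replicate's training portion, and report per-metric means with
normal-approximation 95% confidence intervals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from . import gnn_classifier as gc
from ._autodiff import Tensor, backward, softmax_cross_entropy, softmax_rows
from .duplex_graph import DuplexGraph, build_duplex_graph
from .sequence_encoding import (EmbeddingTable, build_corpora, embed_tokens,
                                tokenize_sequence, train_cbow)
from .synthetic_data import DuplexRecord
from .word2vec import CbowParams

__all__ = [
    "TrainConfig",
    "SplitSpec",
    "MetricsReport",
    "TrainingLog",
    "split_dataset",
    "train_model",
    "Trainer",
    "compute_metrics",
    "summarize_replicates",
    "run_replicates",
    "fit_embedding_tables",
    "build_graphs",
    "UNDEFINED",
]

logger = logging.getLogger(__name__)

#: marker for metrics whose denominator is zero
UNDEFINED = float("nan")


@dataclass(frozen=True)
class TrainConfig:
    max_epochs: int = 1000
    initial_lr: float = 0.001
    batch_size: int = 64
    early_stop_patience: int = 100
    lr_reduce_factor: float = 0.1
    lr_reduce_patience: int = 10
    lr_floor: float = 1e-6
    seed: int = 0

    def __post_init__(self):
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.early_stop_patience < 1 or self.lr_reduce_patience < 1:
            raise ValueError("patience values must be >= 1")
        if not (0.0 < self.lr_reduce_factor < 1.0):
            raise ValueError("lr_reduce_factor must be in (0, 1)")

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "max_epochs", "initial_lr", "batch_size", "early_stop_patience",
            "lr_reduce_factor", "lr_reduce_patience", "lr_floor", "seed")}


@dataclass(frozen=True)
class SplitSpec:
    train_frac: float = 0.7
    val_frac: float = 0.15
    test_frac: float = 0.15
    n_replicates: int = 30
    stratified: bool = True
    base_seed: int = 0

    def __post_init__(self):
        for f in (self.train_frac, self.val_frac, self.test_frac):
            if not (0.0 < f < 1.0):
                raise ValueError("split fractions must be in (0, 1)")
        total = self.train_frac + self.val_frac + self.test_frac
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {total}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "train_frac", "val_frac", "test_frac", "n_replicates",
            "stratified", "base_seed")}


@dataclass
class MetricsReport:
    tp: int
    tn: int
    fp: int
    fn: int
    balanced_accuracy: float
    precision: float
    recall: float

    @property
    def n_records(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class TrainingLog:
    """Per-epoch record of the training run."""

    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = 0
    stopped_early: bool = False

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.epochs)


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split_dataset(records: Sequence, spec: SplitSpec, replicate_index: int):
    """Deterministic (train, val, test) partition for one replicate.

    Sizes are the rounded fractions: n_test = round(n * test_frac),
    n_val = round(n * val_frac), the rest is training.  The partition is a
    pure function of (base_seed, replicate_index).
    """
    if replicate_index < 0 or replicate_index >= spec.n_replicates:
        raise ValueError(
            f"replicate_index {replicate_index} outside [0, {spec.n_replicates})")
    n = len(records)
    if n < 10:
        raise ValueError(f"need at least 10 records to split, got {n}")

    n_test = round(n * spec.test_frac)
    n_val = round(n * spec.val_frac)
    if n_test < 1 or n_val < 1 or n - n_test - n_val < 1:
        raise ValueError("split fractions leave an empty part")

    seed_rng = np.random.default_rng([spec.base_seed, replicate_index])
    state_a = int(seed_rng.integers(2**31 - 1))
    state_b = int(seed_rng.integers(2**31 - 1))

    indices = np.arange(n)
    labels = np.array([r.label for r in records])
    rest, test = train_test_split(
        indices, test_size=n_test, random_state=state_a,
        stratify=labels if spec.stratified else None)
    train, val = train_test_split(
        rest, test_size=n_val, random_state=state_b,
        stratify=labels[rest] if spec.stratified else None)
    pick = lambda idx: [records[i] for i in sorted(idx)]
    return pick(train), pick(val), pick(test)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def compute_metrics(labels: Sequence[int], predictions: Sequence[int]) -> MetricsReport:
    """Confusion counts and BACC / precision / recall.

    BACC = (TP/(TP+FN) + TN/(TN+FP)) / 2, precision = TP/(TP+FP),
    recall = TP/(TP+FN).  A zero denominator yields NaN (the undefined
    marker) instead of a number.
    """
    y = np.asarray(labels)
    p = np.asarray(predictions)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} labels vs {p.shape} predictions")
    if not (np.isin(y, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ValueError("labels and predictions must be binary (0/1)")

    tp = int(np.sum((y == 1) & (p == 1)))
    tn = int(np.sum((y == 0) & (p == 0)))
    fp = int(np.sum((y == 0) & (p == 1)))
    fn = int(np.sum((y == 1) & (p == 0)))

    sensitivity = tp / (tp + fn) if tp + fn > 0 else UNDEFINED
    specificity = tn / (tn + fp) if tn + fp > 0 else UNDEFINED
    bacc = (sensitivity + specificity) / 2.0  # NaN propagates if either is undefined
    precision = tp / (tp + fp) if tp + fp > 0 else UNDEFINED
    return MetricsReport(tp=tp, tn=tn, fp=fp, fn=fn,
                         balanced_accuracy=bacc, precision=precision,
                         recall=sensitivity)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, tensors: list[Tensor], beta1=0.9, beta2=0.999, eps=1e-8):
        self.tensors = tensors
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(t.data) for t in tensors]
        self.v = [np.zeros_like(t.data) for t in tensors]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, tensor in enumerate(self.tensors):
            g = tensor.grad
            if g is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1 ** self.t)
            v_hat = self.v[i] / (1 - b2 ** self.t)
            tensor.data -= lr * m_hat / (np.sqrt(v_hat) + self.eps)


class Trainer:
    """Runs one training job; separated into a class so the validation
    pass can be stubbed out in tests of the stopping logic."""

    def __init__(self, model_config: gc.ClassifierConfig, train_config: TrainConfig):
        self.model_config = model_config
        self.train_config = train_config

    def _validation_metrics(self, params: gc.ModelParameters,
                            val_graphs: list[DuplexGraph],
                            val_labels: np.ndarray) -> tuple[float, float]:
        """(validation loss, validation balanced accuracy)."""
        batch = gc.collate(val_graphs)
        logits = gc.forward_batch(batch, params, self.model_config, mode="EVAL")
        loss = softmax_cross_entropy(logits, val_labels).data.item()
        preds = np.argmax(logits.data, axis=1)
        bacc = compute_metrics(val_labels, preds).balanced_accuracy
        return loss, bacc

    def fit(self, train: Sequence[tuple[DuplexGraph, int]],
            val: Sequence[tuple[DuplexGraph, int]]) -> tuple[gc.ModelParameters, TrainingLog]:
        if len(train) == 0 or len(val) == 0:
            raise ValueError("train and validation sets must be non-empty")
        tc = self.train_config
        train_graphs = [g for g, _ in train]
        train_labels = np.array([y for _, y in train])
        val_graphs = [g for g, _ in val]
        val_labels = np.array([y for _, y in val])

        rng = np.random.default_rng(tc.seed)
        params = gc.init_parameters(self.model_config, rng)
        adam = _Adam(params.tensors())
        lr = tc.initial_lr
        log = TrainingLog()

        best_loss = math.inf
        best_arrays = params.copy_arrays()
        best_epoch = 0
        since_best = 0
        since_lr_drop = 0

        n = len(train)
        for epoch in range(1, tc.max_epochs + 1):
            order = rng.permutation(n)
            epoch_losses = []
            for start in range(0, n, tc.batch_size):
                sel = order[start:start + tc.batch_size]
                batch = gc.collate([train_graphs[i] for i in sel])
                logits = gc.forward_batch(batch, params, self.model_config,
                                          mode="TRAIN", rng=rng)
                loss = softmax_cross_entropy(logits, train_labels[sel])
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch} "
                        f"(lr={lr}); aborting")
                for t in params.tensors():
                    t.zero_grad()
                backward(loss)
                adam.step(lr)
                epoch_losses.append(loss.data.item())

            val_loss, val_bacc = self._validation_metrics(params, val_graphs, val_labels)
            if not np.isfinite(val_loss):
                raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
            log.epochs.append({
                "epoch": epoch, "lr": lr,
                "train_loss": float(np.mean(epoch_losses)),
                "val_loss": val_loss, "val_bacc": val_bacc,
            })

            if val_loss < best_loss:
                best_loss = val_loss
                best_arrays = params.copy_arrays()
                best_epoch = epoch
                since_best = 0
                since_lr_drop = 0
            else:
                since_best += 1
                since_lr_drop += 1
                if since_lr_drop >= tc.lr_reduce_patience:
                    lr = max(lr * tc.lr_reduce_factor, tc.lr_floor)
                    since_lr_drop = 0
                if since_best >= tc.early_stop_patience:
                    log.stopped_early = True
                    break

        log.best_epoch = best_epoch
        params.load_arrays(best_arrays)
        logger.info("training finished: best epoch %d (val loss %.5f), %d epochs run",
                    best_epoch, best_loss, len(log.epochs))
        return params, log


def train_model(train: Sequence[tuple[DuplexGraph, int]],
                val: Sequence[tuple[DuplexGraph, int]],
                model_config: gc.ClassifierConfig,
                train_config: TrainConfig) -> tuple[gc.ModelParameters, TrainingLog]:
    """Train a classifier, returning best-validation-loss parameters and the log."""
    return Trainer(model_config, train_config).fit(train, val)


# ---------------------------------------------------------------------------
# replicate orchestration
# ---------------------------------------------------------------------------

def fit_embedding_tables(train_records: Sequence[DuplexRecord],
                         cbow: CbowParams = CbowParams()) -> tuple[EmbeddingTable, EmbeddingTable]:
    """Fit the two per-corpus embedding tables on training records only."""
    mirna_corpus, mrna_corpus = build_corpora(train_records)
    kwargs = dict(dimension=cbow.dimension, window=cbow.window, epochs=cbow.epochs,
                  negative=cbow.negative, min_count=cbow.min_count)
    mirna_table = train_cbow(mirna_corpus, seed=cbow.seed, **kwargs)
    mrna_table = train_cbow(mrna_corpus, seed=cbow.seed + 1, **kwargs)
    return mirna_table, mrna_table


def build_graphs(records: Sequence[DuplexRecord], mirna_table: EmbeddingTable,
                 mrna_table: EmbeddingTable) -> list[DuplexGraph]:
    """Tokenise, embed (OOV -> zeros) and assemble one graph per record."""
    graphs = []
    for r in records:
        mirna_rows = embed_tokens(tokenize_sequence(r.mirna_seq), mirna_table)
        mrna_rows = embed_tokens(tokenize_sequence(r.site_seq), mrna_table)
        graphs.append(build_duplex_graph(mirna_rows, mrna_rows))
    return graphs


def summarize_replicates(table: pd.DataFrame,
                         metrics: tuple[str, ...] = ("balanced_accuracy", "precision", "recall")
                         ) -> pd.DataFrame:
    """Mean and normal-approximation 95% CI (mean +/- 1.96 * SE) per metric."""
    if len(table) == 0:
        raise ValueError("no completed replicates to summarize")
    rows = []
    for metric in metrics:
        values = table[metric].to_numpy(dtype=float)
        mean = float(np.mean(values))
        if len(values) > 1:
            se = float(np.std(values, ddof=1) / np.sqrt(len(values)))
        else:
            se = 0.0
        rows.append({"metric": metric, "mean": mean,
                     "ci_low": mean - 1.96 * se, "ci_high": mean + 1.96 * se})
    return pd.DataFrame(rows)


def run_replicates(records: Sequence[DuplexRecord],
                   model_config: gc.ClassifierConfig,
                   train_config: TrainConfig,
                   split_spec: SplitSpec,
                   cbow: CbowParams = CbowParams()) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One full train/evaluate cycle per replicate split.

    Every replicate gets its own split and its own CBOW fit (on that
    replicate's training portion).  Failures are recorded per replicate and
    the summary is computed over completed replicates only.

    Returns (replicate table, summary table).
    """
    rows = []
    for rep in range(split_spec.n_replicates):
        try:
            train_recs, val_recs, test_recs = split_dataset(records, split_spec, rep)
            rep_cbow = CbowParams(dimension=cbow.dimension, window=cbow.window,
                                  epochs=cbow.epochs, negative=cbow.negative,
                                  min_count=cbow.min_count,
                                  seed=cbow.seed + 1000 * rep)
            mirna_table, mrna_table = fit_embedding_tables(train_recs, rep_cbow)
            to_pairs = lambda recs: list(zip(
                build_graphs(recs, mirna_table, mrna_table),
                [r.label for r in recs]))
            rep_tc = TrainConfig(**{**train_config.as_dict(),
                                    "seed": train_config.seed + rep})
            params, log = train_model(to_pairs(train_recs), to_pairs(val_recs),
                                      model_config, rep_tc)
            probs = gc.predict_proba(build_graphs(test_recs, mirna_table, mrna_table),
                                     params, model_config)
            preds = np.argmax(probs, axis=1)
            report = compute_metrics([r.label for r in test_recs], preds)
            rows.append({
                "replicate": rep, "status": "ok",
                "balanced_accuracy": report.balanced_accuracy,
                "precision": report.precision, "recall": report.recall,
                "n_test": len(test_recs), "epochs_run": len(log.epochs),
                "best_epoch": log.best_epoch, "error": "",
            })
            logger.info("replicate %d: BACC=%.4f", rep, report.balanced_accuracy)
        except Exception as exc:  # noqa: BLE001 - surfaced in the table
            logger.error("replicate %d failed: %s", rep, exc)
            rows.append({
                "replicate": rep, "status": "failed",
                "balanced_accuracy": UNDEFINED, "precision": UNDEFINED,
                "recall": UNDEFINED, "n_test": 0, "epochs_run": 0,
                "best_epoch": 0, "error": str(exc),
            })
    table = pd.DataFrame(rows)
    completed = table[table["status"] == "ok"]
    summary = summarize_replicates(completed)
    return table, summary
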