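"""Training of the decoy scorer.

Decoy pools are heavily imbalanced (few acceptable models among many
incorrect ones), so every batch is class-balanced: half correct, half
incorrect, with correct decoys resampled with replacement when they
are scarce.  One epoch is one pass over all incorrect decoys.

The loss is binary cross-entropy on the logistic output, optimized
with Adam (defaults: learning rate 0.002, weight decay 0, batch size
32, dropout 0.3).  When validation records are supplied, the
parameters with the best validation accuracy are retained.
Fine-tuning continues from a supplied parameter set at a smaller
learning rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from . import autodiff as ad
from .autodiff import Adam
from .capri_metrics import CapriMetrics, QualityClass, classify_quality
from .interface_graph import InterfaceGraphPair
from .scoring_network import (
    NetworkConfig,
    NetworkParams,
    forward_logits,
    init_params,
    score_many,
)

logger = logging.getLogger(__name__)


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite."""


@dataclass
class TrainingConfig:
    learning_rate: float = 0.002
    weight_decay: float = 0.0
    epochs: int = 100
    batch_size: int = 32
    dropout: float = 0.3
    seed: int = 0
    fine_tune_lr: float = 0.0002
    fine_tune_lr_stage2: float = 0.00002

    def validate(self) -> None:
        if self.learning_rate < 0 or self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("learning rate, epochs and batch size must be positive")
        if self.batch_size % 2:
            raise ValueError("batch size must be even for class-balanced batches")


@dataclass
class DecoyRecord:
    decoy_id: str
    graph: InterfaceGraphPair
    label: str  # "correct" | "incorrect"
    metrics: CapriMetrics | None = None
    target_id: str = ""

    def __post_init__(self):
        if self.label not in ("correct", "incorrect"):
            raise ValueError(f"bad label {self.label!r}")
        if self.metrics is not None:
            derived = classify_quality(self.metrics) >= QualityClass.acceptable
            if derived != (self.label == "correct"):
                raise ValueError(
                    f"label {self.label!r} inconsistent with metrics for "
                    f"{self.decoy_id}")

    @property
    def y(self) -> float:
        return 1.0 if self.label == "correct" else 0.0


def balanced_batches(records: list[DecoyRecord], batch_size: int,
                     seed: int) -> list[list[DecoyRecord]]:
    """Class-balanced batches: batch_size/2 correct + batch_size/2 incorrect.

    Incorrect decoys are shuffled and consumed once per epoch (a
    trailing remainder smaller than half a batch is dropped to keep
    every batch exactly balanced); correct decoys are sampled with
    replacement whenever fewer are available than needed.
    """
    if batch_size % 2:
        raise ValueError("batch size must be even")
    half = batch_size // 2
    pos = [r for r in records if r.label == "correct"]
    neg = [r for r in records if r.label == "incorrect"]
    if not pos or not neg:
        raise ValueError("need at least one record of each class")
    rng = np.random.default_rng(seed)
    neg_order = rng.permutation(len(neg))
    n_batches = max(len(neg) // half, 1)
    batches = []
    for b in range(n_batches):
        chunk = neg_order[b * half:(b + 1) * half]
        if len(chunk) < half:  # only possible when len(neg) < half
            chunk = rng.choice(len(neg), size=half, replace=True)
        if len(pos) >= half:
            pos_idx = rng.choice(len(pos), size=half, replace=False)
        else:
            pos_idx = rng.choice(len(pos), size=half, replace=True)
        batch = [neg[i] for i in chunk] + [pos[i] for i in pos_idx]
        batches.append(batch)
    return batches


def _bce_loss(logits: ad.Tensor, y: np.ndarray) -> ad.Tensor:
    """mean( softplus(z) - y*z ), the stable form of BCE on logits."""
    y = y.reshape(logits.shape)
    return ad.mean(ad.sub(ad.softplus(logits), ad.mul(y, logits)))


def train(records: list[DecoyRecord], config: TrainingConfig,
          init: NetworkParams | None = None,
          val_records: list[DecoyRecord] | None = None,
          ) -> tuple[NetworkParams, list[dict]]:
    """Train (or fine-tune) the scorer; returns (params, per-epoch log).

    With validation records the returned parameters are the best-
    validation-accuracy snapshot, otherwise the final ones.
    """
    config.validate()
    if init is not None:
        params = init.copy()
    else:
        params = init_params(NetworkConfig(dropout=config.dropout),
                             seed=config.seed)
    opt = Adam(params.parameters(), lr=config.learning_rate,
               weight_decay=config.weight_decay)
    dropout_rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 0xD0]))

    log: list[dict] = []
    best_acc = -1.0
    best_params = params
    for epoch in range(config.epochs):
        batches = balanced_batches(
            records, config.batch_size,
            seed=int(np.random.default_rng(
                np.random.SeedSequence([config.seed, epoch])).integers(2**31)))
        losses, correct, total = [], 0, 0
        for batch in batches:
            graphs = [r.graph for r in batch]
            y = np.array([r.y for r in batch])
            logits = forward_logits(graphs, params, training_mode=True,
                                    rng=dropout_rng)
            loss = _bce_loss(logits, y)
            if not np.isfinite(loss.data):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            probs = 1.0 / (1.0 + np.exp(-logits.data[:, 0]))
            correct += int(((probs >= 0.5) == (y == 1.0)).sum())
            total += len(batch)
        entry = {
            "epoch": epoch,
            "train_loss": float(np.mean(losses)),
            "train_acc": correct / total,
            "mu": float(params.mu.data),
            "sigma": float(params.sigma.data),
        }
        if val_records:
            vloss, vacc, vauc = validate(val_records, params)
            entry.update(val_loss=vloss, val_acc=vacc, val_auc=vauc)
            if vacc > best_acc:
                best_acc = vacc
                best_params = params.copy()
        log.append(entry)
        logger.info("epoch %d: %s", epoch, entry)
    return (best_params if val_records else params), log


def validate(records: list[DecoyRecord],
             params: NetworkParams) -> tuple[float, float, float]:
    """(BCE loss, accuracy at 0.5, ROC AUC) with dropout disabled.

    AUC is NaN when only one class is present.
    """
    if not records:
        raise ValueError("empty validation set")
    probs = score_many([r.graph for r in records], params)
    y = np.array([r.y for r in records])
    eps = 1e-12
    loss = float(-np.mean(y * np.log(probs + eps)
                          + (1 - y) * np.log(1 - probs + eps)))
    acc = float(((probs >= 0.5) == (y == 1.0)).mean())
    auc = float(roc_auc_score(y, probs)) if len(np.unique(y)) == 2 else float("nan")
    return loss, acc, auc
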