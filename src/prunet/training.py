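"""Training protocol: Adam on the soft Dice loss with k-fold cross-validation.

Defaults mirror the study protocol: Adam at learning rate 2e-4 with weight
decay 1e-4, batch size 8, 200 epochs, per-sample augmentation probability
0.5 and a 0.5 binarization threshold. Desk-scale runs override the epoch
budget explicitly; every override travels with the run manifest. All
randomness (shuffling, augmentation, weight init) derives from the config
seed, so runs are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ArchConfig
from .data import SegmentationSample, augment_pair, samples_to_arrays
from .metrics import (
    ConfusionCounts,
    MetricRecord,
    aggregate_metrics,
    binarize,
    confusion_counts,
    metric_record,
    record_from_counts,
    records_to_table,
    soft_dice_loss,
)
from .models import SegmentationNet, assemble_model
from .nn import Adam

logger = logging.getLogger(__name__)


class TrainingDivergenceError(RuntimeError):
    """Training loss became non-finite."""


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 2e-4
    weight_decay: float = 1e-4
    epochs: int = 200
    batch_size: int = 8
    augment_ratio: float = 0.5
    threshold: float = 0.5
    dice_epsilon: float = 1.0
    seed: int = 0
    deterministic: bool = True  # retained for the manifest; NumPy runs are
    # deterministic given the seed regardless

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def overrides(self) -> dict:
        """Fields that differ from the protocol defaults."""
        default = TrainConfig()
        return {f.name: getattr(self, f.name) for f in dataclasses.fields(self)
                if getattr(self, f.name) != getattr(default, f.name)}


@dataclass
class TrainHistory:
    epochs: list[dict] = field(default_factory=list)

    def losses(self) -> np.ndarray:
        return np.array([e["loss"] for e in self.epochs])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.epochs)


def kfold_split(n: int, k: int, seed: int = 0) -> list[np.ndarray]:
    """Partition {0..n-1} into k disjoint validation index sets.

    Fold sizes differ by at most one; the partition is a deterministic
    function of (n, k, seed).
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if n < k:
        raise ValueError(f"need at least k={k} samples, got n={n}")
    perm = np.random.default_rng(seed).permutation(n)
    return [np.sort(fold) for fold in np.array_split(perm, k)]


def train_model(model: SegmentationNet, samples: list[SegmentationSample],
                config: TrainConfig,
                val_samples: list[SegmentationSample] | None = None
                ) -> tuple[SegmentationNet, TrainHistory]:
    """Optimise the soft Dice loss; returns the model and its loss history."""
    if not samples:
        raise ValueError("training set must be non-empty")
    history = TrainHistory()
    if config.epochs == 0:
        return model, history
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xA06]))
    opt = Adam(model.parameters(), lr=config.learning_rate,
               weight_decay=config.weight_decay)
    n = len(samples)
    for epoch in range(1, config.epochs + 1):
        t0 = time.perf_counter()
        model.train()
        perm = rng.permutation(n)
        total, seen = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            batch = [augment_pair(samples[i], config.augment_ratio, rng)
                     for i in idx]
            x, y = samples_to_arrays(batch)
            opt.zero_grad()
            probs = model(x)
            loss = soft_dice_loss(probs, y, epsilon=config.dice_epsilon)
            value = loss.item()
            if not np.isfinite(value):
                raise TrainingDivergenceError(
                    f"non-finite Dice loss at epoch {epoch}")
            loss.backward()
            opt.step()
            total += value * len(idx)
            seen += len(idx)
        entry = {"epoch": epoch, "loss": total / seen,
                 "seconds": time.perf_counter() - t0}
        if val_samples:
            report = evaluate_model(model, val_samples, config.threshold,
                                    batch_size=config.batch_size)
            entry["val_dice"] = report.mean.dc
            entry["val_acc"] = report.mean.acc
        history.epochs.append(entry)
    return model, history


@dataclass
class EvalReport:
    records: list[MetricRecord]
    mean: MetricRecord            # per-image mean scope
    pooled: MetricRecord          # global (pooled pixel counts) scope
    counts: ConfusionCounts


def evaluate_model(model: SegmentationNet, samples: list[SegmentationSample],
                   threshold: float = 0.5, batch_size: int = 8,
                   fold: int | None = None) -> EvalReport:
    """Forward, binarize, per-image metrics, both aggregation scopes."""
    if not samples:
        raise ValueError("evaluation set must be non-empty")
    records = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    for start in range(0, len(samples), batch_size):
        batch = samples[start:start + batch_size]
        x, _ = samples_to_arrays(batch)
        probs = model.predict_proba(x)
        for j, s in enumerate(batch):
            sr = binarize(probs[j, 0], threshold)
            records.append(metric_record(sr, s.mask, fold=fold))
            pooled = pooled + confusion_counts(sr, s.mask)
    return EvalReport(records=records,
                      mean=aggregate_metrics(records, fold=fold),
                      pooled=record_from_counts(pooled, fold=fold),
                      counts=pooled)


def _fold_seed(base_seed: int, fold: int) -> int:
    return int(np.random.SeedSequence([base_seed, fold]).generate_state(1)[0]
               % (2 ** 31))


@dataclass
class CrossValResult:
    table: pd.DataFrame            # per-image-mean scope, rows 1..k-fold + Average
    table_global: pd.DataFrame     # pooled-count scope
    fold_records: list[MetricRecord]
    histories: list[TrainHistory]
    fold_indices: list[np.ndarray]
    folds_hash: str


def cross_validate(arch: ArchConfig, samples: list[SegmentationSample],
                   k: int, config: TrainConfig) -> CrossValResult:
    """One train/evaluate cycle per fold over a shared deterministic split."""
    folds = kfold_split(len(samples), k, config.seed)
    digest = hashlib.sha256()
    for fold in folds:
        digest.update(fold.tobytes())
    fold_records, global_records, histories = [], [], []
    for f, val_idx in enumerate(folds, start=1):
        val_set = set(val_idx.tolist())
        train_idx = [i for i in range(len(samples)) if i not in val_set]
        assert not val_set.intersection(train_idx), "fold leakage"
        model = assemble_model(arch, seed=_fold_seed(config.seed, f))
        fold_cfg = dataclasses.replace(config, seed=_fold_seed(config.seed, 100 + f))
        model, history = train_model(model, [samples[i] for i in train_idx],
                                     fold_cfg)
        report = evaluate_model(model, [samples[i] for i in val_idx],
                                config.threshold,
                                batch_size=config.batch_size, fold=f)
        fold_records.append(report.mean)
        global_records.append(report.pooled)
        histories.append(history)
        logger.info("fold %d/%d: DC=%.4f (mean), DC=%.4f (pooled)", f, k,
                    report.mean.dc, report.pooled.dc)
    return CrossValResult(
        table=records_to_table(fold_records),
        table_global=records_to_table(global_records),
        fold_records=fold_records,
        histories=histories,
        fold_indices=folds,
        folds_hash=digest.hexdigest(),
    )
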