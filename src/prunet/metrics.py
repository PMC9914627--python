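"""Dice loss and the six binary-segmentation evaluation indicators.

Conventions, stated once:

* ``binarize`` uses a >= threshold rule, so a pixel exactly at the
  threshold counts as foreground.
* Pixel-ratio metrics (ACC, SE, PRE, F1) return 0 for a 0/0 case, with a
  logged warning.
* Overlap metrics treat two empty masks as a perfect match (JS = DC = 1);
  this is the one place the 0/0 convention differs, because an empty
  prediction of an empty ground truth *is* correct.
* Aggregation over an image set is reported in two scopes: the arithmetic
  mean of per-image metrics (``per_image_mean``) and the metrics of the
  pooled pixel counts (``global``). The two differ whenever image sizes or
  prevalences differ, so both are always computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nn import Tensor
from .nn import autograd as ag

logger = logging.getLogger(__name__)

METRIC_COLUMNS = ["ACC", "PRE", "SE", "F1-Score", "JS", "DC"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


@dataclass
class MetricRecord:
    acc: float
    pre: float
    se: float
    f1: float
    js: float
    dc: float
    scope: str = "per_image_mean"
    fold: int | None = None

    def as_dict(self) -> dict:
        return {"ACC": self.acc, "PRE": self.pre, "SE": self.se,
                "F1-Score": self.f1, "JS": self.js, "DC": self.dc}

    def as_array(self) -> np.ndarray:
        return np.array([self.acc, self.pre, self.se, self.f1, self.js, self.dc])


@dataclass
class DiceLossValue:
    ldice: float
    epsilon: float


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def soft_dice_loss(probabilities, ground_truth, epsilon: float = 1.0):
    """Soft Dice loss 1 - (2*sum(p*g) + eps) / (sum(p) + sum(g) + eps).

    Differentiable in the probabilities; computed on probabilities rather
    than binarized maps so it can drive training. A 4-D input is treated as
    a batch: the loss is the mean of per-sample losses. Returns a scalar
    :class:`~prunet.nn.Tensor` when given one (so gradients flow), else a
    :class:`DiceLossValue`.
    """
    is_tensor = isinstance(probabilities, Tensor)
    p_data = probabilities.data if is_tensor else np.asarray(probabilities, dtype=float)
    g = np.asarray(ground_truth)
    if p_data.shape != g.shape:
        raise ValueError(
            f"shape mismatch: probabilities {p_data.shape} vs ground truth {g.shape}")
    if not np.isin(np.unique(g), (0, 1)).all():
        raise ValueError("ground truth must be binary")
    g = g.astype(p_data.dtype)
    batched = p_data.ndim == 4
    axes = tuple(range(1, p_data.ndim)) if batched else None

    if is_tensor:
        gt = Tensor(g)
        inter = ag.tsum(ag.mul(probabilities, gt), axis=axes)
        sums = ag.add(ag.tsum(probabilities, axis=axes), ag.tsum(gt, axis=axes))
        dice = ag.div(ag.add(ag.mul(inter, 2.0), epsilon), ag.add(sums, epsilon))
        loss = ag.add(ag.mul(dice, -1.0), 1.0)
        return ag.tmean(loss) if batched else loss
    inter = (p_data * g).sum(axis=axes)
    sums = p_data.sum(axis=axes) + g.sum(axis=axes)
    loss = float(np.mean(1.0 - (2.0 * inter + epsilon) / (sums + epsilon)))
    return DiceLossValue(ldice=loss, epsilon=epsilon)


# ---------------------------------------------------------------------------
# thresholding and counts
# ---------------------------------------------------------------------------

def binarize(prob_map, threshold: float = 0.5) -> np.ndarray:
    """Binary mask: pixel = 1 iff probability >= threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    return (np.asarray(prob_map) >= threshold).astype(np.uint8)


def _check_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if not np.isin(np.unique(arr), (0, 1)).all():
        raise ValueError(f"{name} must be binary (values in {{0,1}})")
    return arr.astype(bool)


def confusion_counts(sr, gt) -> ConfusionCounts:
    """Exact pixel tallies between a segmentation result and ground truth."""
    sr = _check_binary(sr, "SR")
    gt = _check_binary(gt, "GT")
    if sr.shape != gt.shape:
        raise ValueError(f"shape mismatch: SR {sr.shape} vs GT {gt.shape}")
    tp = int(np.count_nonzero(sr & gt))
    fp = int(np.count_nonzero(sr & ~gt))
    fn = int(np.count_nonzero(~sr & gt))
    tn = sr.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("%s is 0/0; returning 0 by convention", name)
        return 0.0
    return num / den


def pixel_metrics(counts: ConfusionCounts) -> tuple[float, float, float, float]:
    """(ACC, SE, PRE, F1) from pixel counts."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics over zero pixels")
    acc = (counts.tp + counts.tn) / counts.total
    se = _ratio(counts.tp, counts.tp + counts.fn, "SE")
    pre = _ratio(counts.tp, counts.tp + counts.fp, "PRE")
    f1 = _ratio(2.0 * pre * se, pre + se, "F1")
    return acc, se, pre, f1


def overlap_metrics(sr, gt) -> tuple[float, float]:
    """(JS, DC): Jaccard similarity and Dice coefficient of binary masks."""
    sr = _check_binary(sr, "SR")
    gt = _check_binary(gt, "GT")
    if sr.shape != gt.shape:
        raise ValueError(f"shape mismatch: SR {sr.shape} vs GT {gt.shape}")
    inter = int(np.count_nonzero(sr & gt))
    union = int(np.count_nonzero(sr | gt))
    size_sum = int(np.count_nonzero(sr)) + int(np.count_nonzero(gt))
    if union == 0:  # both masks empty: perfect agreement
        return 1.0, 1.0
    return inter / union, 2.0 * inter / size_sum


def metric_record(sr, gt, fold: int | None = None,
                  scope: str = "per_image") -> MetricRecord:
    """All six indicators for one binarized prediction/ground-truth pair."""
    counts = confusion_counts(sr, gt)
    acc, se, pre, f1 = pixel_metrics(counts)
    js, dc = overlap_metrics(sr, gt)
    return MetricRecord(acc=acc, pre=pre, se=se, f1=f1, js=js, dc=dc,
                        scope=scope, fold=fold)


def record_from_counts(counts: ConfusionCounts, scope: str = "global",
                       fold: int | None = None) -> MetricRecord:
    """Metrics of pooled pixel counts (for binary masks the overlap metrics
    follow from the same counts: intersection = TP, union = TP+FP+FN)."""
    acc, se, pre, f1 = pixel_metrics(counts)
    pos = counts.tp + counts.fp + counts.fn
    if pos == 0:
        js = dc = 1.0
    else:
        js = counts.tp / pos
        dc = 2.0 * counts.tp / (2 * counts.tp + counts.fp + counts.fn)
    return MetricRecord(acc=acc, pre=pre, se=se, f1=f1, js=js, dc=dc,
                        scope=scope, fold=fold)


# ---------------------------------------------------------------------------
# aggregation and reporting
# ---------------------------------------------------------------------------

def aggregate_metrics(records: list[MetricRecord],
                      fold: int | None = None) -> MetricRecord:
    """Arithmetic mean of per-image records (per_image_mean scope)."""
    if not records:
        raise ValueError("cannot aggregate an empty record list")
    arr = np.stack([r.as_array() for r in records]).mean(axis=0)
    return MetricRecord(acc=arr[0], pre=arr[1], se=arr[2], f1=arr[3],
                        js=arr[4], dc=arr[5], scope="per_image_mean", fold=fold)


def records_to_table(records: list[MetricRecord],
                     with_average: bool = True) -> pd.DataFrame:
    """Fold rows plus an Average row in the canonical column order."""
    rows = []
    for r in records:
        label = f"{r.fold}-fold" if r.fold is not None else ""
        rows.append({"k-Fold": label, **r.as_dict()})
    df = pd.DataFrame(rows, columns=["k-Fold"] + METRIC_COLUMNS)
    if with_average and records:
        avg = np.stack([r.as_array() for r in records]).mean(axis=0)
        df.loc[len(df)] = ["Average"] + list(avg)
    return df


def write_metric_table(df: pd.DataFrame, csv_path=None, json_path=None) -> None:
    if csv_path is not None:
        df.to_csv(csv_path, index=False)
    if json_path is not None:
        df.to_json(json_path, orient="records", indent=2)
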