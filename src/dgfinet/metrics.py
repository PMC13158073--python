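"""Pixel-level evaluation: confusion counts, Dice, Jaccard and Mcc.

    Dice    = 2TP / (2TP + FN + FP)
    Jaccard =  TP / (TP + FN + FP)
    Mcc     = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FN)(TN+FP))

Degenerate conventions: when TP = FP = FN = 0 (nothing to find, nothing
predicted) Dice and Jaccard are defined as 1; when any Mcc marginal is zero
Mcc is defined as 0.  Dataset-level aggregation is either the mean of
per-image metrics (``per_image_mean``) or the metrics of one confusion table
pooled over all pixels (``global_pool``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np

AGGREGATIONS = ("per_image_mean", "global_pool")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


@dataclass
class MetricReport:
    dice: float
    mcc: float
    jaccard: float
    n_samples: int
    aggregation: str
    threshold: float = 0.5

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s


def confusion_counts(pred, target, threshold: float = 0.5) -> ConfusionCounts:
    """Binarize ``pred`` at ``threshold`` (>= rule) and count the four cells."""
    pred = np.asarray(pred)
    target = np.asarray(target)
    if pred.shape != target.shape:
        raise ValueError(f"pred shape {pred.shape} != target shape {target.shape}")
    pb = pred >= threshold
    tb = target >= 0.5
    tp = int(np.count_nonzero(pb & tb))
    fp = int(np.count_nonzero(pb & ~tb))
    fn = int(np.count_nonzero(~pb & tb))
    tn = int(np.count_nonzero(~pb & ~tb))
    return ConfusionCounts(tp, fp, fn, tn)


def dice_score(c: ConfusionCounts) -> float:
    denom = 2 * c.tp + c.fn + c.fp
    if denom == 0:
        return 1.0
    return 2.0 * c.tp / denom


def jaccard_score(c: ConfusionCounts) -> float:
    denom = c.tp + c.fn + c.fp
    if denom == 0:
        return 1.0
    return c.tp / denom


def mcc_score(c: ConfusionCounts) -> float:
    # integer arithmetic in the radicand avoids float overflow on big images
    denom2 = (c.tp + c.fn) * (c.tp + c.fp) * (c.tn + c.fn) * (c.tn + c.fp)
    if denom2 == 0:
        return 0.0
    num = c.tp * c.tn - c.fp * c.fn
    return num / math.sqrt(denom2)


def report_from_counts(counts: ConfusionCounts, n_samples: int,
                       aggregation: str, threshold: float = 0.5) -> MetricReport:
    return MetricReport(dice_score(counts), mcc_score(counts),
                        jaccard_score(counts), n_samples, aggregation,
                        threshold)


def evaluate_predictions(preds, targets, threshold: float = 0.5,
                         aggregation: str = "per_image_mean") -> MetricReport:
    """Metrics over paired lists/arrays of per-image predictions and masks."""
    if aggregation not in AGGREGATIONS:
        raise ValueError(f"aggregation must be one of {AGGREGATIONS}, "
                         f"got {aggregation!r}")
    n = len(preds)
    if n == 0:
        raise ValueError("cannot evaluate an empty sample list")
    if aggregation == "global_pool":
        total = ConfusionCounts(0, 0, 0, 0)
        for p, t in zip(preds, targets):
            total = total + confusion_counts(p, t, threshold)
        return report_from_counts(total, n, aggregation, threshold)
    dices, mccs, jacs = [], [], []
    for p, t in zip(preds, targets):
        c = confusion_counts(p, t, threshold)
        dices.append(dice_score(c))
        mccs.append(mcc_score(c))
        jacs.append(jaccard_score(c))
    return MetricReport(float(np.mean(dices)), float(np.mean(mccs)),
                        float(np.mean(jacs)), n, aggregation, threshold)


def evaluate(model, samples, threshold: float = 0.5,
             aggregation: str = "per_image_mean",
             batch_size: int = 8) -> MetricReport:
    """Run ``model`` over ``samples`` and aggregate the metric triple."""
    if len(samples) == 0:
        raise ValueError("cannot evaluate an empty sample list")
    images = np.stack([s.image[None] for s in samples]).astype(np.float32)
    preds = model.predict(images, batch_size=batch_size)[:, 0]
    targets = [s.mask for s in samples]
    return evaluate_predictions(list(preds), targets, threshold, aggregation)
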