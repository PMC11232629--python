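"""Pixel-level segmentation metrics and the soft-Dice training loss.

From the confusion counts TP/FP/TN/FN accumulated over evaluated pixels:

    Dice        = 2 TP / (2 TP + FP + FN)
    Accuracy    = (TP + TN) / (TP + TN + FP + FN)
    Precision   = TP / (TP + FP)
    Sensitivity = TP / (TP + FN)
    Specificity = TN / (TN + FP)

Zero-denominator convention: a metric whose denominator vanishes is 1.0
when the complementary error counts are also zero (a correctly empty
prediction scores perfectly) and 0.0 otherwise.  The training loss is the
soft relaxation of the Dice coefficient over probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


@dataclass
class MetricsReport:
    dice: float
    accuracy: float
    precision: float
    sensitivity: float
    specificity: float

    def as_dict(self) -> dict[str, float]:
        return {"Dice": self.dice, "Acc": self.accuracy, "Pre": self.precision,
                "Sen": self.sensitivity, "Spec": self.specificity}


def _check_binary(mask: np.ndarray, label: str) -> np.ndarray:
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError(f"{label} must be binary (values in {{0, 1}})")
    return mask.astype(np.int64)


def confusion_counts(pred_mask: np.ndarray, gt_mask: np.ndarray) -> ConfusionCounts:
    """Tabulate pixelwise TP/FP/TN/FN between two binary masks."""
    pred = _check_binary(pred_mask, "prediction mask")
    gt = _check_binary(gt_mask, "ground-truth mask")
    if pred.shape != gt.shape:
        raise ValueError(
            f"shape mismatch: prediction {pred.shape} vs ground truth {gt.shape}")
    tp = int((pred * gt).sum())
    fp = int((pred * (1 - gt)).sum())
    fn = int(((1 - pred) * gt).sum())
    tn = pred.size - tp - fp - fn
    return ConfusionCounts(tp, fp, tn, fn)


def _ratio(num: int, den: int, errors_empty: bool) -> float:
    if den == 0:
        return 1.0 if errors_empty else 0.0
    return num / den


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Evaluate the five metrics from accumulated confusion counts."""
    if c.total == 0:
        raise ValueError("no pixels evaluated (all confusion counts zero)")
    return MetricsReport(
        dice=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, c.fp == 0 and c.fn == 0),
        accuracy=(c.tp + c.tn) / c.total,
        precision=_ratio(c.tp, c.tp + c.fp, c.fn == 0),
        sensitivity=_ratio(c.tp, c.tp + c.fn, c.fp == 0),
        specificity=_ratio(c.tn, c.tn + c.fp, c.fn == 0),
    )


def micro_average(counts: list[ConfusionCounts]) -> MetricsReport:
    """Pool confusion counts over all images, then apply the formulas."""
    if not counts:
        raise ValueError("no confusion counts to aggregate")
    total = counts[0]
    for c in counts[1:]:
        total = total + c
    return compute_metrics(total)


def macro_average(counts: list[ConfusionCounts]) -> MetricsReport:
    """Average per-image metric values (each image weighted equally)."""
    if not counts:
        raise ValueError("no confusion counts to aggregate")
    reports = [compute_metrics(c) for c in counts]
    return MetricsReport(*(float(np.mean([getattr(r, f) for r in reports]))
                           for f in ("dice", "accuracy", "precision",
                                     "sensitivity", "specificity")))


def dice_loss(pred_prob: np.ndarray, gt_mask: np.ndarray,
              eps: float = 1.0) -> float:
    """Soft Dice loss: 1 - (2 sum(p*g) + eps) / (sum(p) + sum(g) + eps).

    ``pred_prob`` holds foreground probabilities in [0, 1]; ``eps`` is the
    smoothing term that keeps the ratio defined (and the empty-empty case
    lossless).  Differentiable in ``pred_prob``; see :func:`dice_loss_grad`.
    """
    loss, _ = dice_loss_grad(pred_prob, gt_mask, eps, need_grad=False)
    return loss


def dice_loss_grad(pred_prob: np.ndarray, gt_mask: np.ndarray, eps: float = 1.0,
                   need_grad: bool = True) -> tuple[float, np.ndarray | None]:
    """Soft Dice loss and its gradient with respect to ``pred_prob``."""
    p = np.asarray(pred_prob)
    g = _check_binary(gt_mask, "ground-truth mask").astype(p.dtype)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("predicted probabilities must lie in [0, 1]")
    inter = float((p * g).sum())
    denom = float(p.sum() + g.sum()) + eps
    num = 2.0 * inter + eps
    loss = 1.0 - num / denom
    if not need_grad:
        return loss, None
    grad = -(2.0 * g * denom - num) / (denom * denom)
    return loss, grad.astype(p.dtype)
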