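"""Pixel confusion counts, Dice / IoU, and the combined BCE + Dice loss.

Dice = 2TP / (2TP + FP + FN) and IoU = TP / (TP + FP + FN) on binarised
masks; the two are tied by the identity IoU = Dice / (2 − Dice).  An image
where prediction and ground truth are both empty scores Dice = IoU = 1
(the standard convention).  Dataset-level metrics are the mean of the
per-image values.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .autodiff import Tensor

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_counts",
    "dice_iou",
    "combined_loss",
    "evaluate_masks",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricReport:
    """Per-image Dice/IoU plus dataset means."""

    ids: list[str]
    dice: list[float]
    iou: list[float]

    @property
    def mean_dice(self) -> float:
        return float(np.mean(self.dice)) if self.dice else float("nan")

    @property
    def mean_iou(self) -> float:
        return float(np.mean(self.iou)) if self.iou else float("nan")

    def write(self, csv_path: str | Path, json_path: str | Path | None = None) -> None:
        with open(csv_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["image_id", "dice", "iou"])
            for i, d, j in zip(self.ids, self.dice, self.iou):
                w.writerow([i, f"{d:.6f}", f"{j:.6f}"])
        if json_path is not None:
            Path(json_path).write_text(
                json.dumps(
                    {"mean_dice": self.mean_dice, "mean_iou": self.mean_iou,
                     "n_images": len(self.ids)},
                    indent=2,
                )
            )


def confusion_counts(pred_prob, gt_mask, threshold: float = 0.5) -> ConfusionCounts:
    """Binarise ``pred_prob`` at ``threshold`` and tally TP/FP/TN/FN pixels."""
    pred = np.asarray(pred_prob.data if isinstance(pred_prob, Tensor) else pred_prob)
    gt = np.asarray(gt_mask.data if isinstance(gt_mask, Tensor) else gt_mask)
    pred = np.squeeze(pred)
    gt = np.squeeze(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    uniq = np.unique(gt)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError("ground-truth mask must be binary (0/1)")
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0,1), got {threshold}")
    p = pred > threshold
    g = gt.astype(bool)
    tp = int(np.sum(p & g))
    fp = int(np.sum(p & ~g))
    fn = int(np.sum(~p & g))
    tn = int(np.sum(~p & ~g))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def dice_iou(c: ConfusionCounts) -> tuple[float, float]:
    """Dice and IoU from pixel tallies; empty-vs-empty scores (1, 1)."""
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return 1.0, 1.0
    dice = 2 * c.tp / denom
    iou = c.tp / (c.tp + c.fp + c.fn)
    return float(dice), float(iou)


def combined_loss(
    logits: Tensor,
    gt_mask,
    w_ce: float = 0.5,
    w_dice: float = 0.5,
    smooth: float = 1e-5,
) -> Tensor:
    """w_ce · BCE(σ(logits), gt) + w_dice · (1 − soft Dice).

    The BCE term is computed in the numerically stable logit form
    ``softplus(z) − z·y``; soft Dice uses probabilities with additive
    smoothing ε in numerator and denominator, so the loss is finite and
    differentiable for any input, including empty masks.
    """
    gt = np.asarray(gt_mask.data if isinstance(gt_mask, Tensor) else gt_mask)
    gt = gt.astype(logits.dtype).reshape(logits.shape)
    y = Tensor(gt)
    z = logits
    # softplus(z) = relu(z) + log(1 + exp(-|z|)), stable for large |z|
    softplus = z.relu() + ((-(z.abs())).exp() + 1.0).log()
    bce = (softplus - z * y).mean()
    p = z.sigmoid()
    # per-image soft Dice (averaged), matching the per-image evaluation metric
    axes = tuple(range(1, p.ndim)) if p.ndim > 1 else None
    inter = (p * y).sum(axis=axes)
    soft_dice = ((2.0 * inter + smooth) / (p.sum(axis=axes) + y.sum(axis=axes) + smooth)).mean()
    return w_ce * bce + w_dice * (1.0 - soft_dice)


def evaluate_masks(
    pred_probs: list[np.ndarray],
    gt_masks: list[np.ndarray],
    ids: list[str] | None = None,
    threshold: float = 0.5,
) -> MetricReport:
    """Per-image Dice/IoU for paired probability maps and binary masks."""
    ids = ids or [str(i) for i in range(len(pred_probs))]
    dices, ious = [], []
    for p, g in zip(pred_probs, gt_masks):
        d, j = dice_iou(confusion_counts(p, g, threshold))
        dices.append(d)
        ious.append(j)
    return MetricReport(ids=list(ids), dice=dices, iou=ious)
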