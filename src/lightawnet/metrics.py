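"""Segmentation metrics and the binary cross-entropy training loss.

All four evaluation metrics derive from pixel confusion counts:

    DSC = 2TP / (2TP + FP + FN)       IoU = TP / (TP + FP + FN)
    UR  = FN / (TP + FP + FN)         FNR = FN / (TP + FN)

UR (under-segmentation rate) normalises missed foreground by the union, so
UR <= FNR always. When prediction and truth are both empty the pair is a
perfect match by convention: DSC = IoU = 1, UR = FNR = 0; FNR is 0 whenever
the ground truth is empty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, clip, log, mean, mul

BCE_EPS = 1e-7


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class SegMetrics:
    dsc: float
    iou: float
    ur: float
    fnr: float

    def as_dict(self) -> dict:
        return {"dsc": self.dsc, "iou": self.iou, "ur": self.ur,
                "fnr": self.fnr}


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixel tallies between two binary masks of identical shape."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(
            f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    p = pred.astype(bool)
    t = truth.astype(bool)
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp, fp, fn, tn)


def compute_metrics(c: ConfusionCounts) -> SegMetrics:
    union = c.tp + c.fp + c.fn
    if union == 0:
        return SegMetrics(dsc=1.0, iou=1.0, ur=0.0, fnr=0.0)
    dsc = 2 * c.tp / (2 * c.tp + c.fp + c.fn)
    iou = c.tp / union
    ur = c.fn / union
    fnr = c.fn / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    return SegMetrics(dsc=dsc, iou=iou, ur=ur, fnr=fnr)


def dice_score(pred: np.ndarray, truth: np.ndarray) -> float:
    return compute_metrics(confusion(pred, truth)).dsc


def bce_loss(probs: Tensor, targets: np.ndarray | Tensor) -> Tensor:
    """Binary cross-entropy, averaged per pixel then over slices.

    ``probs`` are network outputs in (0, 1); they are clamped to
    [eps, 1-eps] before the logarithm so saturated predictions stay finite.
    The loss is the mean over batch slices of the per-slice pixel-mean BCE.
    """
    if isinstance(targets, Tensor):
        targets = targets.data
    targets = np.asarray(targets, dtype=np.float32)
    p = clip(probs, BCE_EPS, 1.0 - BCE_EPS)
    pos = mul(Tensor(targets), log(p))
    neg = mul(Tensor(1.0 - targets), log(1.0 - p))
    return -mean(pos + neg)


def bce_loss_np(probs: np.ndarray, targets: np.ndarray) -> float:
    """Plain-array BCE with the same clamping (evaluation convenience)."""
    p = np.clip(np.asarray(probs, dtype=np.float64), BCE_EPS, 1 - BCE_EPS)
    t = np.asarray(targets, dtype=np.float64)
    return float(-(t * np.log(p) + (1 - t) * np.log(1 - p)).mean())


def aggregate(per_case: list[SegMetrics]) -> dict:
    """Mean and sample (n-1) standard deviation per metric across cases."""
    if not per_case:
        raise ValueError("aggregate() needs at least one case")
    out = {}
    for key in ("dsc", "iou", "ur", "fnr"):
        vals = np.array([getattr(m, key) for m in per_case], dtype=np.float64)
        std = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        out[key] = {"mean": float(vals.mean()), "std": std}
    return out
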