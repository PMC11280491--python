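"""Composite training loss and the six-metric evaluation suite.

Losses (soft Dice + binary cross-entropy) accept either numpy arrays or
autodiff :class:`~dentseg.nn.Tensor` probability maps; metrics operate
on hard binary masks.

Conventions (explicit because they matter at the edges):

* Dice/IoU are foreground-only; if both masks are empty they are 100%.
* HD95 works on 8-connected boundary pixels of each mask, pools the two
  directed nearest-neighbour distance sets and takes the 95th
  percentile; if either mask is empty the value is undefined (NaN) and
  excluded from aggregation with a logged count.
* Confusion-based metrics threshold probabilities at 0.5; an MCC with a
  zero denominator is 0 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .nn import Tensor

__all__ = [
    "ConfusionCounts", "MetricReport", "dice_loss", "ce_loss",
    "composite_loss", "confusion", "dsc", "iou", "hd95",
    "accuracy", "kappa", "mcc", "evaluate_dataset", "boundary_pixels",
]

DICE_SMOOTH = 1.0
CE_CLIP = 1e-7

_CONN8 = np.ones((3, 3), dtype=bool)


# --------------------------------------------------------------------------
# losses (autodiff-aware)
# --------------------------------------------------------------------------

def _is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def dice_loss(prob_map, mask, smooth: float = DICE_SMOOTH):
    """Soft Dice loss 1 - (2 sum(p*y) + eps) / (sum(p) + sum(y) + eps)."""
    if _is_tensor(prob_map):
        y = mask if _is_tensor(mask) else Tensor(np.asarray(mask, dtype=np.float64))
        inter = (prob_map * y).sum()
        denom = prob_map.sum() + y.sum() + smooth
        return 1.0 - (2.0 * inter + smooth) / denom
    p = np.asarray(prob_map, dtype=np.float64)
    y = np.asarray(mask, dtype=np.float64)
    return float(1.0 - (2.0 * (p * y).sum() + smooth) / (p.sum() + y.sum() + smooth))


def ce_loss(prob_map, mask, clip: float = CE_CLIP):
    """Mean binary cross-entropy with probabilities clipped away from {0,1}."""
    if _is_tensor(prob_map):
        y = mask if _is_tensor(mask) else Tensor(np.asarray(mask, dtype=np.float64))
        p = prob_map.clamp(clip, 1.0 - clip)
        per = y * p.log() + (1.0 - y) * (1.0 - p).log()
        return -per.mean()
    p = np.clip(np.asarray(prob_map, dtype=np.float64), clip, 1.0 - clip)
    y = np.asarray(mask, dtype=np.float64)
    return float(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).mean())


def composite_loss(prob_map, mask, w_dice: float = 1.0, w_ce: float = 1.0):
    """w_dice * dice_loss + w_ce * ce_loss."""
    return w_dice * dice_loss(prob_map, mask) + w_ce * ce_loss(prob_map, mask)


# --------------------------------------------------------------------------
# confusion counts and derived metrics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _binarise(x) -> np.ndarray:
    x = np.asarray(x)
    if x.dtype == bool:
        return x
    return x > 0.5 if np.issubdtype(x.dtype, np.floating) else x.astype(bool)


def confusion(pred_mask, true_mask) -> ConfusionCounts:
    """Hard pixel tallies (probabilities thresholded at 0.5)."""
    p = _binarise(pred_mask)
    t = _binarise(true_mask)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    return ConfusionCounts(
        tp=int(np.sum(p & t)), tn=int(np.sum(~p & ~t)),
        fp=int(np.sum(p & ~t)), fn=int(np.sum(~p & t)))


def dsc(pred_mask, true_mask) -> float:
    """Foreground Dice similarity coefficient in percent (both empty -> 100)."""
    p = _binarise(pred_mask)
    t = _binarise(true_mask)
    denom = p.sum() + t.sum()
    if denom == 0:
        return 100.0
    return float(200.0 * np.sum(p & t) / denom)


def iou(pred_mask, true_mask) -> float:
    """Foreground intersection-over-union in percent (both empty -> 100)."""
    p = _binarise(pred_mask)
    t = _binarise(true_mask)
    union = np.sum(p | t)
    if union == 0:
        return 100.0
    return float(100.0 * np.sum(p & t) / union)


def boundary_pixels(mask) -> np.ndarray:
    """(M, 2) array of (row, col) boundary pixels: foreground pixels with
    at least one of their 8 neighbours (or the image border) outside."""
    m = _binarise(mask)
    eroded = ndimage.binary_erosion(m, structure=_CONN8, border_value=0)
    return np.argwhere(m & ~eroded)


def hd95(pred_mask, true_mask, percentile: float = 95.0) -> float:
    """Pooled-percentile boundary Hausdorff distance in pixels.

    Returns NaN (undefined) if either mask has no foreground.
    """
    p = _binarise(pred_mask)
    t = _binarise(true_mask)
    if not p.any() or not t.any():
        return float("nan")
    pb = p & ~ndimage.binary_erosion(p, structure=_CONN8, border_value=0)
    tb = t & ~ndimage.binary_erosion(t, structure=_CONN8, border_value=0)
    dt_t = ndimage.distance_transform_edt(~tb)
    dt_p = ndimage.distance_transform_edt(~pb)
    pooled = np.concatenate([dt_t[pb], dt_p[tb]])
    return float(np.percentile(pooled, percentile))


def accuracy(c: ConfusionCounts) -> float:
    """(TP+TN)/total in percent."""
    return 100.0 * (c.tp + c.tn) / c.total


def kappa(c: ConfusionCounts) -> float:
    """Cohen's kappa in percent, from observed vs chance agreement."""
    T = c.total
    po = (c.tp + c.tn) / T
    pe = ((c.tp + c.fp) * (c.tp + c.fn) + (c.tn + c.fn) * (c.tn + c.fp)) / (T * T)
    if pe == 1.0:
        return 100.0 if po == 1.0 else 0.0
    return float(100.0 * (po - pe) / (1.0 - pe))


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient in percent (0 when undefined)."""
    denom = np.sqrt(float(c.tp + c.fp) * (c.tp + c.fn)
                    * (c.tn + c.fp) * (c.tn + c.fn))
    if denom == 0:
        return 0.0
    return float(100.0 * (float(c.tp) * c.tn - float(c.fp) * c.fn) / denom)


# --------------------------------------------------------------------------
# dataset-level aggregation
# --------------------------------------------------------------------------

METRIC_NAMES = ("dsc", "hd95", "iou", "accuracy", "kappa", "mcc")


@dataclass
class MetricReport:
    """Per-image metrics plus mean +/- sd aggregates."""

    per_image: pd.DataFrame
    sample_sd: bool = True
    hd95_undefined: int = 0

    def mean(self, name: str) -> float:
        return float(self.per_image[name].dropna().mean())

    def sd(self, name: str) -> float:
        vals = self.per_image[name].dropna()
        if len(vals) < 2:
            return 0.0
        return float(vals.std(ddof=1 if self.sample_sd else 0))

    def summary(self) -> dict[str, tuple[float, float]]:
        return {name: (self.mean(name), self.sd(name)) for name in METRIC_NAMES}

    def to_csv(self, path) -> None:
        """Per-image rows plus one trailing summary row (mean values)."""
        df = self.per_image.copy()
        summary = {"id": "mean"}
        summary.update({name: self.mean(name) for name in METRIC_NAMES})
        df = pd.concat([df, pd.DataFrame([summary])], ignore_index=True)
        df.to_csv(path, index=False)


def per_image_metrics(pred_mask, true_mask) -> dict[str, float]:
    c = confusion(pred_mask, true_mask)
    return {
        "dsc": dsc(pred_mask, true_mask),
        "hd95": hd95(pred_mask, true_mask),
        "iou": iou(pred_mask, true_mask),
        "accuracy": accuracy(c),
        "kappa": kappa(c),
        "mcc": mcc(c),
    }


def evaluate_dataset(pairs, ids=None, sample_sd: bool = True) -> MetricReport:
    """Evaluate (pred_mask, true_mask) pairs; aggregates are mean +/- sd
    across images, with HD95-undefined images excluded from its mean."""
    rows = []
    for i, (pred, true) in enumerate(pairs):
        row = {"id": ids[i] if ids is not None else f"img_{i:04d}"}
        row.update(per_image_metrics(pred, true))
        rows.append(row)
    if not rows:
        raise ValueError("no image pairs to evaluate")
    df = pd.DataFrame(rows)
    undefined = int(df["hd95"].isna().sum())
    return MetricReport(per_image=df, sample_sd=sample_sd,
                        hd95_undefined=undefined)
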