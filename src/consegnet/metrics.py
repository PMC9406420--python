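"""Pixel-wise segmentation metrics and the differentiable IoU training loss.

From a pixel confusion (TP/FP/FN/TN) the module computes precision, recall,
Dice and IoU (Jaccard):

    precision = TP/(TP+FP)          recall = TP/(TP+FN)
    Dice = 2*precision*recall/(precision+recall) = 2TP/(2TP+FP+FN)
    IoU  = TP/(TP+FP+FN)            Dice = 2*IoU/(1+IoU)

and renders the per-ground-truth-class normalized 2x2 confusion table
(each class row sums to 100%).  ``soft_iou_loss`` is the differentiable
surrogate used for training (see :mod:`consegnet.nn.functional`); the NumPy
version here is for evaluation code that never needs gradients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, ShapeError
from .nn import functional as _F
from .nn.tensor import Tensor, no_grad

__all__ = ["PixelConfusion", "Metrics", "soft_iou_loss", "pixel_confusion",
           "compute_metrics", "normalized_confusion_report"]


@dataclass(frozen=True)
class PixelConfusion:
    """Pixel counts of a binary segmentation against ground truth."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise DataError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "PixelConfusion") -> "PixelConfusion":
        return PixelConfusion(self.tp + other.tp, self.fp + other.fp,
                              self.fn + other.fn, self.tn + other.tn)


@dataclass(frozen=True)
class Metrics:
    """Precision, recall, Dice and IoU as fractions in [0,1]."""

    precision: float
    recall: float
    dice: float
    iou: float

    def as_percent_dict(self, ndigits: int = 2) -> dict[str, float]:
        return {k: round(100.0 * v, ndigits) for k, v in self.__dict__.items()}


def soft_iou_loss(pred: np.ndarray, target: np.ndarray, epsilon: float = 1e-6) -> float:
    """Differentiable-IoU loss value (1 - soft Jaccard) for one prediction.

    ``pred`` may be fractional in [0,1]; ``target`` must be binary.  Returns
    0 exactly when a binary prediction equals its target.
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target)
    if pred.shape != target.shape:
        raise ShapeError(f"shape mismatch: pred {pred.shape} vs target {target.shape}")
    if pred.min() < 0 or pred.max() > 1:
        raise DataError("predictions must lie in [0,1]")
    if not np.isin(target, (0, 1)).all():
        raise DataError("target must be binary")
    with no_grad():
        loss = _F.soft_iou_loss(Tensor(pred[None]), target[None].astype(np.float32),
                                eps=epsilon)
    return float(loss.data)


def _check_binary(arr: np.ndarray, what: str) -> np.ndarray:
    arr = np.asarray(arr)
    if not np.isin(arr, (0, 1)).all():
        raise DataError(f"{what} must be binary (0/1)")
    return arr.astype(bool)


def pixel_confusion(pred_binary: np.ndarray, target: np.ndarray) -> PixelConfusion:
    """Count TP/FP/FN/TN pixels of a binary prediction against a binary mask."""
    p = _check_binary(pred_binary, "prediction")
    g = _check_binary(target, "target")
    if p.shape != g.shape:
        raise ShapeError(f"shape mismatch: pred {p.shape} vs target {g.shape}")
    return PixelConfusion(
        tp=int(np.count_nonzero(p & g)),
        fp=int(np.count_nonzero(p & ~g)),
        fn=int(np.count_nonzero(~p & g)),
        tn=int(np.count_nonzero(~p & ~g)),
    )


def _ratio(num: float, den: float, empty_value: float = 1.0) -> float:
    return num / den if den > 0 else empty_value


def compute_metrics(conf: PixelConfusion) -> Metrics:
    """Precision/recall/Dice/IoU from pixel counts.

    When prediction and ground truth are both empty (TP=FP=FN=0) there is
    nothing to disagree about, so every metric is 1 by convention.
    """
    tp, fp, fn = conf.tp, conf.fp, conf.fn
    return Metrics(
        precision=_ratio(tp, tp + fp),
        recall=_ratio(tp, tp + fn),
        dice=_ratio(2 * tp, 2 * tp + fp + fn),
        iou=_ratio(tp, tp + fp + fn),
    )


def normalized_confusion_report(conf: PixelConfusion) -> pd.DataFrame:
    """2x2 percentage table normalized within each ground-truth class.

    Rows are the ground-truth classes (tumor, non-tumor): the tumor row
    splits into TP%/FN%, the non-tumor row into FP%/TN%; each row sums
    to 100%.
    """
    pos = conf.tp + conf.fn
    neg = conf.tn + conf.fp
    if pos == 0 or neg == 0:
        raise DataError("normalized confusion undefined: a ground-truth class is empty")
    return pd.DataFrame(
        [[100.0 * conf.tp / pos, 100.0 * conf.fn / pos],
         [100.0 * conf.fp / neg, 100.0 * conf.tn / neg]],
        index=["Tumor", "Non-Tumor"],
        columns=["Pred Tumor", "Pred Non-Tumor"],
    )
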