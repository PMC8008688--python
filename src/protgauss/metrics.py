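"""Evaluation metrics for multi-label and binary classification.

Subset accuracy (exact label-set match), micro-averaged area under the
precision-recall curve (all label-sample pairs pooled into one vector),
confusion counts and the Matthews correlation coefficient:

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with the convention MCC = 0 when any factor of the denominator is 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score

from .errors import ValidationError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n if self.n else 0.0


def _as_binary(a, name: str) -> np.ndarray:
    arr = np.asarray(a)
    if not np.isin(arr, (0, 1)).all():
        raise ValidationError(f"{name} must contain only 0/1 entries")
    return arr.astype(int)


def subset_accuracy(y_true, y_pred) -> float:
    """Fraction of samples whose full predicted label set is exactly right.

    For a single label (m = 1) this reduces to ordinary accuracy.
    """
    yt = _as_binary(y_true, "y_true")
    yp = _as_binary(y_pred, "y_pred")
    if yt.shape != yp.shape:
        raise ValidationError(f"shape mismatch: {yt.shape} vs {yp.shape}")
    yt = np.atleast_2d(yt.T).T if yt.ndim == 1 else yt
    yp = np.atleast_2d(yp.T).T if yp.ndim == 1 else yp
    return float((yt == yp).all(axis=1).mean())


def micro_aupr(y_true, scores) -> float:
    """Area under the pooled precision-recall curve.

    Both arrays are flattened to length n*m; the PR curve is traced over
    distinct score thresholds (tied scores enter together) and the area
    is the step-wise precision-at-recall-change summation.
    """
    yt = _as_binary(y_true, "y_true").ravel()
    sc = np.asarray(scores, dtype=float).ravel()
    if yt.shape != sc.shape:
        raise ValidationError(f"shape mismatch: {yt.shape} vs {sc.shape}")
    if yt.sum() == 0:
        raise ValidationError("micro-AUPR undefined without any positive label")
    return float(average_precision_score(yt, sc))


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Standard binary confusion counts with positive class = 1."""
    yt = _as_binary(y_true, "y_true").ravel()
    yp = _as_binary(y_pred, "y_pred").ravel()
    if yt.shape != yp.shape:
        raise ValidationError(f"length mismatch: {yt.shape} vs {yp.shape}")
    return ConfusionCounts(
        tp=int(((yt == 1) & (yp == 1)).sum()),
        tn=int(((yt == 0) & (yp == 0)).sum()),
        fp=int(((yt == 0) & (yp == 1)).sum()),
        fn=int(((yt == 1) & (yp == 0)).sum()),
    )


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 on a degenerate denominator."""
    if min(c.tp, c.tn, c.fp, c.fn) < 0:
        raise ValidationError("confusion counts must be non-negative")
    denom_factors = (
        (c.tp + c.fp),
        (c.tp + c.fn),
        (c.tn + c.fp),
        (c.tn + c.fn),
    )
    if any(f == 0 for f in denom_factors):
        return 0.0
    num = c.tp * c.tn - c.fp * c.fn
    return float(num / np.sqrt(np.prod(np.array(denom_factors, dtype=float))))
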