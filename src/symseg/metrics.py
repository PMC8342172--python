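"""Segmentation accuracy metrics for predicted vs. reference binary masks.

The confusion fractions are all normalised by the reference area |A_b|:

    TP = |A_a ∩ A_b| / |A_b|,  FN = (|A_b| − |A_a ∩ A_b|) / |A_b|,
    FP = (|A_a| − |A_a ∩ A_b|) / |A_b|,

so TP + FN = 1 for a nonempty reference. Precision, recall, F1 and IoU are
derived from them; precision P = TP/(TP+FP) then reduces to the standard
|A_a ∩ A_b| / |A_a|.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateInputError, ParameterError


@dataclass(frozen=True)
class MetricsReport:
    """Confusion fractions and derived scores for one mask pair."""

    tp: float
    fn: float
    fp: float
    precision: float
    recall: float
    f1: float
    iou: float
    flags: tuple[str, ...] = field(default=())

    def as_row(self) -> dict[str, float]:
        return {
            "TP": self.tp, "FN": self.fn, "FP": self.fp,
            "prec": self.precision, "reca": self.recall,
            "F1": self.f1, "IoU": self.iou,
        }


def _as_mask(m, name: str) -> np.ndarray:
    arr = np.asarray(m)
    if arr.ndim != 2:
        raise ParameterError(f"{name} must be a 2-D mask")
    return arr.astype(bool)


def confusion_fractions(pred, ref) -> tuple[float, float, float]:
    """(TP, FN, FP) fractions, each normalised by the reference area."""
    pred = _as_mask(pred, "pred")
    ref = _as_mask(ref, "ref")
    if pred.shape != ref.shape:
        raise ParameterError(f"mask shapes differ: {pred.shape} vs {ref.shape}")
    n_ref = int(ref.sum())
    if n_ref == 0:
        raise DegenerateInputError("reference mask is empty")
    n_pred = int(pred.sum())
    n_inter = int((pred & ref).sum())
    tp = n_inter / n_ref
    fn = (n_ref - n_inter) / n_ref
    fp = (n_pred - n_inter) / n_ref
    return tp, fn, fp


def segmentation_metrics(pred, ref) -> MetricsReport:
    """Precision, recall, F1 and IoU for a predicted vs. reference mask.

    An empty prediction against a nonempty reference yields all-zero scores
    with an ``"empty-prediction"`` flag; both masks empty is an error (no
    defined score).
    """
    pred = _as_mask(pred, "pred")
    ref = _as_mask(ref, "ref")
    if pred.shape != ref.shape:
        raise ParameterError(f"mask shapes differ: {pred.shape} vs {ref.shape}")
    if not pred.any() and not ref.any():
        raise DegenerateInputError("both masks empty; metrics undefined")
    tp, fn, fp = confusion_fractions(pred, ref)
    flags: list[str] = []
    if tp + fp == 0:
        precision = 0.0
        flags.append("empty-prediction")
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn)  # tp + fn == 1 for nonempty ref
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    union = int((pred | ref).sum())
    iou = int((pred & ref).sum()) / union
    return MetricsReport(tp, fn, fp, precision, recall, f1, iou, tuple(flags))


def write_metrics_table(path, rows: dict[str, MetricsReport]) -> None:
    """Write one delimited row per image plus a mean row.

    Columns: file, TP, FN, FP, prec, reca, F1, IoU. The mean row averages
    each column across images.
    """
    fieldnames = ["file", "TP", "FN", "FP", "prec", "reca", "F1", "IoU"]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        writer.writeheader()
        for name in sorted(rows):
            writer.writerow({"file": name, **{k: f"{v:.6f}" for k, v in rows[name].as_row().items()}})
        if rows:
            keys = ["TP", "FN", "FP", "prec", "reca", "F1", "IoU"]
            means = {
                k: float(np.mean([r.as_row()[k] for r in rows.values()])) for k in keys
            }
            writer.writerow({"file": "mean", **{k: f"{v:.6f}" for k, v in means.items()}})
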