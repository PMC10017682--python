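"""Evaluation of predicted tissue masks against ground truth.

Four pixel-level statistics are computed per (predicted, truth) pair —
Jaccard index, sensitivity, false positive rate and pixel accuracy — and
aggregated per masking method as mean ± SD across an image set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "jaccard_index",
    "sensitivity",
    "false_positive_rate",
    "pixel_accuracy",
    "MaskMetrics",
    "evaluate_mask",
    "CANONICAL_METHOD_ORDER",
    "summarize_benchmark",
]

#: Method order used in benchmark reports.
CANONICAL_METHOD_ORDER = (
    "entropy",
    "otsu",
    "adaptive_mean",
    "adaptive_gaussian",
    "slidemask",
)


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel confusion counts of a predicted mask against ground truth."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _as_bool_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {mask.shape!r}")
    return mask.astype(bool)


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """TP/FP/TN/FN pixel counts; masks must share the same shape."""
    pred = _as_bool_mask(pred)
    truth = _as_bool_mask(truth)
    if pred.shape != truth.shape:
        raise ValueError(
            f"mask shapes differ: {pred.shape!r} vs {truth.shape!r}"
        )
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = pred.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def jaccard_index(c: ConfusionCounts) -> float:
    """TP / (TP + FP + FN); two empty masks are identical, hence 1."""
    denom = c.tp + c.fp + c.fn
    if denom == 0:
        warnings.warn(
            "both masks empty: Jaccard index of two empty masks defined as 1",
            stacklevel=2,
        )
        return 1.0
    return c.tp / denom


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN); NaN when the truth mask is empty."""
    denom = c.tp + c.fn
    if denom == 0:
        warnings.warn("truth mask empty: sensitivity undefined", stacklevel=2)
        return float("nan")
    return c.tp / denom


def false_positive_rate(c: ConfusionCounts) -> float:
    """FP / (FP + TN); NaN when the truth mask covers every pixel."""
    denom = c.fp + c.tn
    if denom == 0:
        warnings.warn(
            "truth mask covers all pixels: false positive rate undefined",
            stacklevel=2,
        )
        return float("nan")
    return c.fp / denom


def pixel_accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / total."""
    if c.total == 0:
        raise ValueError("empty masks: pixel accuracy undefined")
    return (c.tp + c.tn) / c.total


@dataclass(frozen=True)
class MaskMetrics:
    """The four evaluation statistics for one (predicted, truth) pair."""

    jaccard: float
    sensitivity: float
    false_positive_rate: float
    pixel_accuracy: float


def evaluate_mask(pred: np.ndarray, truth: np.ndarray) -> MaskMetrics:
    """All four metrics for one predicted mask against its ground truth."""
    c = confusion_counts(pred, truth)
    return MaskMetrics(
        jaccard=jaccard_index(c),
        sensitivity=sensitivity(c),
        false_positive_rate=false_positive_rate(c),
        pixel_accuracy=pixel_accuracy(c),
    )


_COLUMNS = {
    "jaccard": "Jaccard",
    "sensitivity": "Sensitivity",
    "false_positive_rate": "FPR",
    "pixel_accuracy": "PixelAcc",
}


def summarize_benchmark(
    results: Iterable[tuple[str, MaskMetrics]]
) -> pd.DataFrame:
    """Per-method mean and sample SD of each metric.

    Parameters
    ----------
    results : iterable of (method name, MaskMetrics)
        One entry per evaluated image.

    Returns
    -------
    DataFrame with columns Method, {Jaccard,Sensitivity,FPR,PixelAcc}_{mean,sd}
    and N.  SD uses the n-1 denominator (0 when n = 1).  Methods appear in
    the canonical order, any unknown method names after that.
    """
    results = list(results)
    if not results:
        raise ValueError("no benchmark results to summarize")

    records = [
        {"Method": method, **{col: getattr(m, attr) for attr, col in _COLUMNS.items()}}
        for method, m in results
    ]
    df = pd.DataFrame.from_records(records)

    known = [m for m in CANONICAL_METHOD_ORDER if m in set(df["Method"])]
    extra = sorted(set(df["Method"]) - set(CANONICAL_METHOD_ORDER))
    rows = []
    for method in known + extra:
        sub = df[df["Method"] == method]
        row: dict[str, object] = {"Method": method}
        for col in _COLUMNS.values():
            vals = sub[col].to_numpy(dtype=np.float64)
            row[f"{col}_mean"] = float(vals.mean())
            row[f"{col}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        row["N"] = int(len(sub))
        rows.append(row)
    return pd.DataFrame(rows)
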