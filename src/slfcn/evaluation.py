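"""Pixel-level segmentation metrics and mean ± std aggregation.

Metrics follow the usual confusion-count definitions: accuracy, precision,
recall, F1 = 2TP/(2TP+FP+FN) and Jaccard = TP/(TP+FP+FN).  For multi-class
outputs each foreground class is scored one-vs-rest, plus a "foreground"
roll-up that treats any nonzero class as positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ConfusionCounts", "confusion", "metrics", "evaluate_pair",
           "aggregate", "METRIC_NAMES"]

METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "jaccard")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(pred: np.ndarray, ref: np.ndarray) -> ConfusionCounts:
    """Pixelwise confusion counts for two binary masks of equal shape."""
    pred = np.asarray(pred, dtype=bool)
    ref = np.asarray(ref, dtype=bool)
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {ref.shape}")
    tp = int(np.count_nonzero(pred & ref))
    fp = int(np.count_nonzero(pred & ~ref))
    fn = int(np.count_nonzero(~pred & ref))
    tn = int(np.count_nonzero(~pred & ~ref))
    return ConfusionCounts(tp, tn, fp, fn)


def metrics(c: ConfusionCounts) -> dict:
    """The five metrics, with zero-denominator conventions flagged.

    If TP+FP+FN = 0 (both masks empty) the overlap metrics are 1 by
    convention; otherwise an undefined ratio scores 0.  The returned dict
    carries a ``degenerate`` flag when a convention was applied.
    """
    if c.total <= 0:
        raise ValueError("no evaluated pixels")
    degenerate = False

    def ratio(num, den, empty_ok):
        nonlocal degenerate
        if den == 0:
            degenerate = True
            return 1.0 if empty_ok else 0.0
        return num / den

    empty = (c.tp + c.fp + c.fn) == 0
    out = {
        "accuracy": (c.tp + c.tn) / c.total,
        "precision": ratio(c.tp, c.tp + c.fp, empty),
        "recall": ratio(c.tp, c.tp + c.fn, empty),
        "f1": ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, empty),
        "jaccard": ratio(c.tp, c.tp + c.fp + c.fn, empty),
    }
    out["degenerate"] = degenerate
    return out


def evaluate_pair(pred_labels: np.ndarray, ref_labels: np.ndarray,
                  num_classes: int | None = None) -> dict:
    """One-vs-rest metrics per foreground class plus a foreground roll-up.

    Returns ``{"foreground": {...}, "class_1": {...}, ...}``; class rows are
    emitted for every foreground index present in either map (or 1..N-1 when
    ``num_classes`` is given).
    """
    pred_labels = np.asarray(pred_labels)
    ref_labels = np.asarray(ref_labels)
    if num_classes is None:
        present = np.union1d(np.unique(pred_labels), np.unique(ref_labels))
        classes = [int(c) for c in present if c != 0]
    else:
        classes = list(range(1, num_classes))
    out = {"foreground": metrics(confusion(pred_labels != 0, ref_labels != 0))}
    for cls in classes:
        out[f"class_{cls}"] = metrics(
            confusion(pred_labels == cls, ref_labels == cls))
    return out


def aggregate(rows) -> pd.DataFrame:
    """Mean ± sample std (ddof=1; 0 for a single row) over per-image metrics.

    ``rows`` is a list of per-image metric dicts or a DataFrame with metric
    columns.  Returns a DataFrame indexed by metric with columns
    ``mean``, ``std``, ``n`` and a formatted ``report`` column in the
    conventional "mean ± std %" style.
    """
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no metric rows to aggregate")
    cols = [c for c in METRIC_NAMES if c in df.columns]
    stats = pd.DataFrame({
        "mean": df[cols].mean(),
        "std": df[cols].std(ddof=1).fillna(0.0) if len(df) > 1
               else pd.Series(0.0, index=cols),
        "n": len(df),
    })
    stats["report"] = [f"{m * 100:.2f} ± {s * 100:.2f}%"
                       for m, s in zip(stats["mean"], stats["std"])]
    return stats
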