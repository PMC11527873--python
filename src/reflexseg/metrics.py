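"""Overlap metrics (Dice, IoU, Precision, Recall) for binary segmentation.

Metrics are derived from per-image confusion counts.  By default a
dataset-level report macro-averages per-image values (each image counts
equally, which matters when target sizes vary); micro averaging over
pooled pixels is available by flag.  When an image has an empty ground
truth and an empty prediction all four metrics default to 1 — the
prediction is exactly right — configurable to excluding such images.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

METRIC_NAMES = ("dice", "iou", "precision", "recall")


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-image TP/FP/FN/TN; integral for hard masks, real for soft."""

    tp: float
    fp: float
    fn: float
    tn: float

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.fn + self.tn


def binarize(prob_map: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map; strictly greater-than convention."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    prob_map = np.asarray(prob_map)
    return (prob_map > threshold).astype(np.uint8)


def confusion_counts(pred: np.ndarray, truth: np.ndarray,
                     soft: bool = False) -> ConfusionCounts:
    """Confusion counts of a prediction against a binary ground truth.

    Hard mode expects a binary prediction; soft mode accepts a
    probability map and returns the expected counts tp = sum(p*g),
    fp = sum(p*(1-g)), fn = sum((1-p)*g), tn = sum((1-p)*(1-g)).
    """
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if not soft and not np.isin(pred, (0, 1)).all():
        raise ValueError("hard mode requires a binary prediction")
    tp = float((pred * truth).sum())
    fp = float((pred * (1.0 - truth)).sum())
    fn = float(((1.0 - pred) * truth).sum())
    tn = float(((1.0 - pred) * (1.0 - truth)).sum())
    return ConfusionCounts(tp, fp, fn, tn)


def _safe_ratio(num: float, den: float, empty_value: float = 1.0) -> float:
    return num / den if den > 0 else empty_value


def dice(c: ConfusionCounts) -> float:
    return _safe_ratio(2.0 * c.tp, 2.0 * c.tp + c.fp + c.fn)


def iou(c: ConfusionCounts) -> float:
    return _safe_ratio(c.tp, c.tp + c.fp + c.fn)


def precision(c: ConfusionCounts) -> float:
    return _safe_ratio(c.tp, c.tp + c.fp)


def recall(c: ConfusionCounts) -> float:
    return _safe_ratio(c.tp, c.tp + c.fn)


_METRIC_FNS = {"dice": dice, "iou": iou, "precision": precision,
               "recall": recall}


@dataclass
class MetricsReport:
    """Aggregate metrics plus the per-image table they were averaged from."""

    dice: float
    iou: float
    precision: float
    recall: float
    n_images: int
    per_image: pd.DataFrame
    std: dict[str, float] | None = None

    def to_json(self) -> str:
        import json
        d = {m: getattr(self, m) for m in METRIC_NAMES}
        d["n_images"] = self.n_images
        if self.std:
            d["std"] = self.std
        return json.dumps(d, indent=2)

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        self.per_image.to_csv(prefix.with_suffix(".csv"), index=False)
        prefix.with_suffix(".json").write_text(self.to_json())


def evaluate_dataset(preds, truths, threshold: float = 0.5,
                     average: str = "macro",
                     empty_policy: str = "one") -> MetricsReport:
    """Evaluate paired predictions and ground truths.

    ``preds`` may be probability maps (binarised at ``threshold``) or
    binary masks.  ``average`` is "macro" (per-image metrics averaged) or
    "micro" (counts pooled over all pixels first).  ``empty_policy``
    decides how an empty-truth/empty-prediction image scores: "one"
    (all metrics 1) or "exclude" (dropped from the aggregate).
    """
    preds, truths = list(preds), list(truths)
    if len(preds) == 0:
        raise ValueError("evaluate_dataset requires at least one image pair")
    if len(preds) != len(truths):
        raise ValueError("preds and truths must have equal length")
    if average not in ("macro", "micro"):
        raise ValueError(f"unknown average {average!r}")
    if empty_policy not in ("one", "exclude"):
        raise ValueError(f"unknown empty_policy {empty_policy!r}")

    rows = []
    counts = []
    for i, (p, g) in enumerate(zip(preds, truths)):
        p = np.asarray(p)
        pb = binarize(p, threshold) if p.dtype.kind == "f" else p.astype(np.uint8)
        c = confusion_counts(pb, np.asarray(g))
        counts.append(c)
        row = {"image": i, **{m: _METRIC_FNS[m](c) for m in METRIC_NAMES}}
        row["empty_pair"] = (c.tp + c.fp + c.fn) == 0
        rows.append(row)
    table = pd.DataFrame(rows)

    if average == "micro":
        pooled = ConfusionCounts(*(sum(getattr(c, f) for c in counts)
                                   for f in ("tp", "fp", "fn", "tn")))
        agg = {m: _METRIC_FNS[m](pooled) for m in METRIC_NAMES}
        used = table
    else:
        used = table[~table.empty_pair] if empty_policy == "exclude" else table
        if len(used) == 0:
            raise ValueError("no images left to aggregate after exclusion")
        agg = {m: float(used[m].mean()) for m in METRIC_NAMES}
    std = {m: float(used[m].std(ddof=1)) if len(used) > 1 else 0.0
           for m in METRIC_NAMES}
    return MetricsReport(**agg, n_images=len(preds),
                         per_image=table.drop(columns="empty_pair"), std=std)


__all__ = ["ConfusionCounts", "MetricsReport", "METRIC_NAMES", "binarize",
           "confusion_counts", "dice", "iou", "precision", "recall",
           "evaluate_dataset"]
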