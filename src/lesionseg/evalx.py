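"""Pixel confusion counting and the six-metric segmentation panel.

Metrics: precision TP/(TP+FP), sensitivity TP/(TP+FN), Jaccard
TP/(TP+FN+FP), Dice 2TP/(2TP+FP+FN), specificity TN/(TN+FP) and false
positive rate FP/(FP+TN).  For a single confusion table the algebraic
identities J = D/(2-D) and FPR = 1 - specificity hold exactly; note that
they do NOT carry over to arithmetic means of per-slice metrics, which is
the expected behavior of averaged panels, not an error.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ConfusionCounts", "MetricReport", "confusion", "metric_panel",
           "aggregate", "relative_improvement", "ablation_table"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricReport:
    precision: float
    sensitivity: float
    jaccard: float
    dice: float
    specificity: float
    fpr: float
    aggregation: str = "single"

    def as_dict(self) -> dict[str, float]:
        return {"dice": self.dice, "jaccard": self.jaccard,
                "precision": self.precision, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "fpr": self.fpr}


def confusion(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Exact pixel tallies between two binary masks of identical shape."""
    p = np.asarray(pred)
    g = np.asarray(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: prediction {p.shape} vs ground truth {g.shape}")
    for name, arr in (("prediction", p), ("ground truth", g)):
        if not np.all(np.isin(arr, (0, 1))):
            raise ValueError(f"{name} mask is not binary")
    p = p.astype(bool)
    g = g.astype(bool)
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & g)),
        fp=int(np.count_nonzero(p & ~g)),
        fn=int(np.count_nonzero(~p & g)),
        tn=int(np.count_nonzero(~p & ~g)),
    )


def _ratio(num: int, den: int) -> float:
    """Zero-denominator convention: 1.0 when the numerator condition is
    vacuously satisfied (nothing to find, nothing found), since num <= den
    always holds here; the value is exact otherwise."""
    if den == 0:
        return 1.0
    return num / den


def metric_panel(c: ConfusionCounts, aggregation: str = "single") -> MetricReport:
    specificity = _ratio(c.tn, c.tn + c.fp)
    return MetricReport(
        precision=_ratio(c.tp, c.tp + c.fp),
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        jaccard=_ratio(c.tp, c.tp + c.fn + c.fp),
        dice=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
        specificity=specificity,
        fpr=(c.fp / (c.fp + c.tn)) if (c.fp + c.tn) > 0 else 0.0,
        aggregation=aggregation,
    )


def aggregate(items, mode: str = "per_slice_mean") -> MetricReport:
    """Summarize a collection of per-slice results.

    ``per_slice_mean``: arithmetic mean of each metric over per-slice panels.
    ``pooled_counts``: one panel from the summed confusion counts.
    ``items`` may contain ConfusionCounts (either mode) or MetricReport
    (per_slice_mean only).
    """
    items = list(items)
    if not items:
        raise ValueError("nothing to aggregate")
    if mode == "pooled_counts":
        if not all(isinstance(i, ConfusionCounts) for i in items):
            raise TypeError("pooled_counts aggregation needs ConfusionCounts")
        total = items[0]
        for c in items[1:]:
            total = total + c
        return metric_panel(total, aggregation="pooled_counts")
    if mode == "per_slice_mean":
        reports = [metric_panel(i) if isinstance(i, ConfusionCounts) else i
                   for i in items]
        mean = {k: float(np.mean([r.as_dict()[k] for r in reports]))
                for k in reports[0].as_dict()}
        return MetricReport(precision=mean["precision"], sensitivity=mean["sensitivity"],
                            jaccard=mean["jaccard"], dice=mean["dice"],
                            specificity=mean["specificity"], fpr=mean["fpr"],
                            aggregation="per_slice_mean")
    raise ValueError(f"unknown aggregation mode {mode!r}")


def relative_improvement(new_dice: float, ref_dice: float) -> float:
    """Percent improvement 100 * (new - ref) / ref, rounded to 2 decimals.

    Use ``relative_improvement_exact`` for the unrounded value.
    """
    return round(relative_improvement_exact(new_dice, ref_dice), 2)


def relative_improvement_exact(new_dice: float, ref_dice: float) -> float:
    if ref_dice <= 0:
        raise ValueError("reference Dice must be positive")
    return 100.0 * (new_dice - ref_dice) / ref_dice


def ablation_table(results: dict[float, MetricReport], path=None) -> pd.DataFrame:
    """One row per test-split fraction with the six-metric panel."""
    if not results:
        raise ValueError("no results to tabulate")
    rows = []
    for fraction in sorted(results):
        row = {"test_fraction": fraction}
        row.update(results[fraction].as_dict())
        rows.append(row)
    table = pd.DataFrame(rows, columns=["test_fraction", "dice", "jaccard",
                                        "precision", "specificity", "sensitivity",
                                        "fpr"])
    if path is not None:
        table.to_csv(Path(path), index=False)
    return table
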