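"""Evaluation metrics and fold aggregation (malignant = positive class).

Accuracy, sensitivity (recall), specificity, precision and F1 from confusion
counts, plus the pairwise-ranking AUC estimator
AUC(f) = sum_{t0 in D0} sum_{t1 in D1} B(f(t0) < f(t1)) / (|D0| |D1|),
where D0/D1 are the negative/positive score sets.  In ``strict`` tie mode a
tied pair contributes 0 (the literal indicator); ``half`` mode credits ties
0.5 (the Mann-Whitney convention).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "confusion",
    "summary_metrics",
    "auc_eq16",
    "aggregate_folds",
    "write_report",
]

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision", "f1", "auc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(labels, predictions) -> ConfusionCounts:
    y = np.asarray(labels).astype(int)
    p = np.asarray(predictions).astype(int)
    if y.shape != p.shape:
        raise ValueError("labels and predictions must have equal length")
    return ConfusionCounts(
        tp=int(((y == 1) & (p == 1)).sum()),
        tn=int(((y == 0) & (p == 0)).sum()),
        fp=int(((y == 0) & (p == 1)).sum()),
        fn=int(((y == 1) & (p == 0)).sum()),
    )


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined (zero denominator); reporting NaN",
                      stacklevel=3)
        return float("nan")
    return num / den


def summary_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, precision and F1 from counts."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    acc = _safe_div(tp + tn, counts.n, "accuracy")
    sens = _safe_div(tp, tp + fn, "sensitivity")
    spec = _safe_div(tn, tn + fp, "specificity")
    prec = _safe_div(tp, tp + fp, "precision")
    if math.isnan(prec) or math.isnan(sens) or prec + sens == 0:
        warnings.warn("f1 undefined; reporting NaN", stacklevel=2)
        f1 = float("nan")
    else:
        f1 = 2 * prec * sens / (prec + sens)
    return {
        "accuracy": acc,
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "f1": f1,
    }


def auc_eq16(scores_pos, scores_neg, tie_mode: str = "strict") -> float:
    """Pairwise-ranking AUC over all (negative, positive) score pairs."""
    pos = np.asarray(scores_pos, dtype=np.float64)
    neg = np.asarray(scores_neg, dtype=np.float64)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be nonempty")
    if tie_mode not in ("strict", "half"):
        raise ValueError("tie_mode must be 'strict' or 'half'")
    diff = pos[None, :] - neg[:, None]
    wins = (diff > 0).sum()
    if tie_mode == "half":
        wins = wins + 0.5 * (diff == 0).sum()
    return float(wins) / (pos.size * neg.size)


@dataclass
class EvalReport:
    """Six metrics for one evaluation (typically one CV fold)."""

    counts: ConfusionCounts
    metrics: dict[str, float]
    fold: int | None = None

    @classmethod
    def from_scores(cls, labels, scores, threshold: float = 0.5,
                    fold: int | None = None, tie_mode: str = "strict"):
        y = np.asarray(labels).astype(int)
        s = np.asarray(scores, dtype=np.float64)
        counts = confusion(y, (s >= threshold).astype(int))
        m = summary_metrics(counts)
        m["auc"] = auc_eq16(s[y == 1], s[y == 0], tie_mode=tie_mode)
        return cls(counts=counts, metrics=m, fold=fold)


def aggregate_folds(reports: list[EvalReport]) -> dict[str, tuple[float, float]]:
    """Unweighted mean and population standard deviation across folds."""
    if not reports:
        raise ValueError("need at least one fold report")
    out = {}
    for name in METRIC_NAMES:
        vals = np.array([r.metrics[name] for r in reports], dtype=np.float64)
        out[name] = (float(np.nanmean(vals)), float(np.nanstd(vals)))
    return out


def write_report(reports: list[EvalReport], path: str | Path) -> pd.DataFrame:
    """Per-fold + mean table as CSV, mirroring the usual six-metric layout."""
    rows = []
    for r in reports:
        rows.append({"fold": r.fold, **{k: r.metrics[k] for k in METRIC_NAMES}})
    agg = aggregate_folds(reports)
    rows.append({"fold": "mean", **{k: agg[k][0] for k in METRIC_NAMES}})
    rows.append({"fold": "sd", **{k: agg[k][1] for k in METRIC_NAMES}})
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
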