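"""Binary-classification metrics for PPI evaluation.

Implements the confusion-matrix family (sensitivity, precision, F1, MCC)
and the threshold-free ranking metrics (AUROC as the Mann-Whitney
probability with tie correction, AUPR as step-wise average precision).

Conventions, chosen so that fold aggregation never propagates NaN:

* thresholded predictions use ``probability >= threshold``;
* any zero denominator in Sen/Pre/F1/MCC yields 0.0 and a log message;
* AUROC/AUPR on degenerate inputs (a single class / no positives) raise
  :class:`UndefinedMetricError` rather than silently returning a number.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "UndefinedMetricError",
    "confusion",
    "sensitivity",
    "precision",
    "f1_score",
    "mcc",
    "auroc",
    "aupr",
    "roc_points",
    "pr_points",
]


class UndefinedMetricError(ValueError):
    """A ranking metric was requested on input where it is undefined."""


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


@dataclass
class MetricsReport:
    """One evaluation's worth of metrics (the Sen/Pre/AUPR/AUC/F1/MCC set)."""

    sensitivity: float
    precision: float
    f1: float
    mcc: float
    aupr: float
    auc: float
    threshold: float = 0.5

    @classmethod
    def from_scores(cls, probs, labels, threshold: float = 0.5) -> "MetricsReport":
        c = confusion(probs, labels, threshold)
        return cls(
            sensitivity=sensitivity(c),
            precision=precision(c),
            f1=f1_score(c),
            mcc=mcc(c),
            aupr=aupr(probs, labels),
            auc=auroc(probs, labels),
            threshold=threshold,
        )

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def _validate(probs, labels):
    probs = np.asarray(probs, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel().astype(np.int64)
    if probs.shape != labels.shape:
        raise ValueError(
            f"probs and labels lengths differ: {probs.size} vs {labels.size}")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary (0/1)")
    return probs, labels


def confusion(probs, labels, threshold: float = 0.5) -> ConfusionCounts:
    """Threshold probabilities (``>= threshold`` is positive) and count."""
    probs, labels = _validate(probs, labels)
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    pred = probs >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        logger.info("%s undefined (zero denominator); returning 0.0", name)
        return 0.0
    return num / den


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN) — recall on the interacting class."""
    return _ratio(c.tp, c.tp + c.fn, "sensitivity")


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP)."""
    return _ratio(c.tp, c.tp + c.fp, "precision")


def f1_score(c: ConfusionCounts) -> float:
    """Harmonic mean of precision and sensitivity, 2PR/(P+R)."""
    p, r = precision(c), sensitivity(c)
    if p + r == 0.0:
        logger.info("f1 undefined (precision + recall = 0); returning 0.0")
        return 0.0
    return 2.0 * p * r / (p + r)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient, overflow-safe.

    (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); any zero factor
    in the denominator yields 0.0 by convention.
    """
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    factors = [tp + fp, tp + fn, tn + fp, tn + fn]
    if 0 in factors:
        logger.info("mcc undefined (degenerate margin); returning 0.0")
        return 0.0
    # Python ints are exact; split the sqrt to stay in float range.
    num = tp * tn - fp * fn
    denom = math.prod(math.sqrt(f) for f in factors)
    return num / denom


def auroc(probs, labels) -> float:
    """Area under the ROC curve as the Mann-Whitney probability.

    Equals (concordant pairs + 0.5 * tied pairs) / (n_pos * n_neg),
    computed via midranks so ties are handled exactly.
    """
    probs, labels = _validate(probs, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError(
            f"AUROC needs both classes; got {n_pos} positives / {n_neg} negatives")
    ranks = rankdata(probs)  # average ranks resolve ties as 0.5 credit
    rank_sum = ranks[labels == 1].sum()
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def _ranked(probs, labels):
    """Sort by descending score, ties broken by stable original order."""
    order = np.argsort(-probs, kind="stable")
    return labels[order]


def aupr(probs, labels) -> float:
    """Area under the precision-recall curve as step-wise average precision.

    Walks the ranking in descending-score order (stable tie-break) and sums
    precision-at-rank over the positives, divided by the positive count —
    i.e. sum of (delta recall) * (precision at that rank), with no
    trapezoidal interpolation.
    """
    probs, labels = _validate(probs, labels)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise UndefinedMetricError("AUPR needs at least one positive")
    y = _ranked(probs, labels)
    cum_pos = np.cumsum(y)
    ranks = np.arange(1, y.size + 1)
    return float(np.sum((cum_pos / ranks)[y == 1]) / n_pos)


def write_report_tsv(reports, path, summary: dict | None = None) -> None:
    """Write per-fold rows (and an optional mean +/- sd row) as TSV.

    Columns follow the conventional presentation: sensitivity and precision
    as percentages, the remaining metrics as fractions.
    """
    import pandas as pd

    rows = []
    for i, r in enumerate(reports):
        rows.append({"fold": i, "sen_pct": 100 * r.sensitivity,
                     "pre_pct": 100 * r.precision, "aupr": r.aupr,
                     "auc": r.auc, "f1": r.f1, "mcc": r.mcc})
    df = pd.DataFrame(rows)
    if summary is not None:
        mean_row = {"fold": "mean", "sen_pct": 100 * summary["sensitivity"]["mean"],
                    "pre_pct": 100 * summary["precision"]["mean"],
                    "aupr": summary["aupr"]["mean"], "auc": summary["auc"]["mean"],
                    "f1": summary["f1"]["mean"], "mcc": summary["mcc"]["mean"]}
        sd_row = {"fold": "sd", "sen_pct": 100 * summary["sensitivity"]["sd"],
                  "pre_pct": 100 * summary["precision"]["sd"],
                  "aupr": summary["aupr"]["sd"], "auc": summary["auc"]["sd"],
                  "f1": summary["f1"]["sd"], "mcc": summary["mcc"]["sd"]}
        df = pd.concat([df, pd.DataFrame([mean_row, sd_row])], ignore_index=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def roc_points(probs, labels) -> np.ndarray:
    """(FPR, TPR) points of the ROC curve, one per distinct threshold."""
    probs, labels = _validate(probs, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("ROC curve needs both classes")
    order = np.argsort(-probs, kind="stable")
    y, p = labels[order], probs[order]
    distinct = np.r_[np.nonzero(np.diff(p))[0], y.size - 1]
    tpr = np.cumsum(y)[distinct] / n_pos
    fpr = np.cumsum(1 - y)[distinct] / n_neg
    return np.column_stack([np.r_[0.0, fpr], np.r_[0.0, tpr]])


def pr_points(probs, labels) -> np.ndarray:
    """(recall, precision) points of the PR curve along the ranking."""
    probs, labels = _validate(probs, labels)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise UndefinedMetricError("PR curve needs at least one positive")
    y = _ranked(probs, labels)
    cum_pos = np.cumsum(y)
    ranks = np.arange(1, y.size + 1)
    return np.column_stack([cum_pos / n_pos, cum_pos / ranks])
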