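"""Classifier evaluation: confusion-matrix metrics, ROC/AUC, fold changes.

``confusion_metrics`` produces the exact integer confusion matrix and the
derived fractions (sensitivity, specificity, accuracy, PPV, NPV).  For a
label-only (binary) predictor the ROC has a single operating point, so its
AUC is exactly ``(sensitivity + specificity) / 2``; that value is attached to
the metrics.  ``roc_auc`` handles continuous scores via the Mann-Whitney
formulation (ties contribute 1/2) with a DeLong 95% confidence interval.

Unclassifiable predictions count as errors against the sample's true class,
which keeps n fixed and is conservative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_preprocess import ExpressionMatrix

__all__ = [
    "ClassMetrics",
    "confusion_metrics",
    "roc_auc",
    "binary_auc",
    "roc_points",
    "fold_change_summary",
]


@dataclass
class ClassMetrics:
    """Confusion counts with derived rates; fractions in [0, 1]."""

    tp: int
    fp: int
    tn: int
    fn: int
    auc: float | None = None
    auc_ci95: tuple[float, float] | None = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp)

    @property
    def npv(self) -> float:
        return self.tn / (self.tn + self.fn)

    def to_dict(self) -> dict:
        out = {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "n": self.n,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "ppv": self.ppv,
            "npv": self.npv,
        }
        if self.auc is not None:
            out["auc"] = self.auc
        if self.auc_ci95 is not None:
            out["auc_ci95"] = list(self.auc_ci95)
        return out

    def report(self) -> str:
        """Percentages formatted to two decimals."""
        lines = [
            f"n = {self.n} (TP={self.tp} FP={self.fp} TN={self.tn} FN={self.fn})",
            f"sensitivity = {self.sensitivity * 100:.2f}%",
            f"specificity = {self.specificity * 100:.2f}%",
            f"accuracy    = {self.accuracy * 100:.2f}%",
            f"PPV         = {self.ppv * 100:.2f}%",
            f"NPV         = {self.npv * 100:.2f}%",
        ]
        if self.auc is not None:
            ci = ""
            if self.auc_ci95 is not None:
                ci = f" (95% CI {self.auc_ci95[0] * 100:.2f}-{self.auc_ci95[1] * 100:.2f}%)"
            lines.append(f"AUC         = {self.auc * 100:.2f}%{ci}")
        return "\n".join(lines)


def confusion_metrics(
    predicted: Sequence[str],
    truth: Sequence[str],
    positive_label: str,
    negative_label: str | None = None,
) -> ClassMetrics:
    """Exact confusion matrix; predictions outside {positive, negative} are errors.

    ``negative_label`` defaults to the single non-positive label found in
    ``truth``.  An "unclassifiable" prediction counts against the sample's
    true class (FN for a true positive, FP for a true negative).
    """
    predicted = list(predicted)
    truth = list(truth)
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth must have equal length")
    true_labels = set(truth)
    if positive_label not in true_labels:
        raise ValueError(f"positive label {positive_label!r} absent from truth")
    negatives = true_labels - {positive_label}
    if negative_label is None:
        if len(negatives) != 1:
            raise ValueError(f"cannot infer negative label from truth labels {sorted(true_labels)}")
        negative_label = next(iter(negatives))
    if negatives - {negative_label}:
        raise ValueError(f"unknown truth labels: {sorted(negatives - {negative_label})}")

    tp = fp = tn = fn = 0
    for p, t in zip(predicted, truth):
        if t == positive_label:
            if p == positive_label:
                tp += 1
            else:  # wrong label or unclassifiable
                fn += 1
        else:
            if p == negative_label:
                tn += 1
            else:
                fp += 1
    metrics = ClassMetrics(tp=tp, fp=fp, tn=tn, fn=fn)
    metrics.auc = binary_auc(metrics)
    return metrics


def binary_auc(metrics: ClassMetrics) -> float:
    """AUC of a label-only predictor: (sensitivity + specificity) / 2."""
    return (metrics.sensitivity + metrics.specificity) / 2


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def roc_auc(
    scores: Sequence[float],
    truth: Sequence[str],
    positive_label: str,
) -> tuple[float, tuple[float, float]]:
    """Mann-Whitney AUC with a DeLong 95% confidence interval.

    ``AUC = U / (n_pos * n_neg)`` with ties contributing 1/2.  The interval
    uses the DeLong structural-component variance (tie-corrected, asymptotic
    normal), clipped to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(list(truth), dtype=object)
    pos = scores[truth == positive_label]
    neg = scores[truth != positive_label]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("need at least one positive and one negative sample")
    if np.isnan(scores).any():
        raise ValueError("scores contain NaN")

    tz = _midrank(np.concatenate([pos, neg]))
    tx = _midrank(pos)
    ty = _midrank(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
    # DeLong structural components
    v01 = (tz[:m] - tx) / n
    v10 = 1.0 - (tz[m:] - ty) / m
    var = 0.0
    if m > 1:
        var += np.var(v01, ddof=1) / m
    if n > 1:
        var += np.var(v10, ddof=1) / n
    se = float(np.sqrt(var))
    z = stats.norm.ppf(0.975)
    lo = float(np.clip(auc - z * se, 0.0, 1.0))
    hi = float(np.clip(auc + z * se, 0.0, 1.0))
    return float(auc), (lo, hi)


def roc_points(
    scores: Sequence[float],
    truth: Sequence[str],
    positive_label: str,
) -> pd.DataFrame:
    """Operating points of the empirical ROC: one row per score threshold.

    A sample is called positive when its score >= the row's threshold, so the
    frame runs from (0, 0) at +inf down to (1, 1) at the minimum score.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(list(truth), dtype=object)
    is_pos = truth == positive_label
    m, n = int(is_pos.sum()), int((~is_pos).sum())
    if m == 0 or n == 0:
        raise ValueError("need at least one positive and one negative sample")
    rows = [{"fpr": 0.0, "tpr": 0.0, "threshold": np.inf}]
    for t in sorted(np.unique(scores), reverse=True):
        called = scores >= t
        rows.append(
            {
                "fpr": float((called & ~is_pos).sum() / n),
                "tpr": float((called & is_pos).sum() / m),
                "threshold": float(t),
            }
        )
    return pd.DataFrame(rows, columns=["fpr", "tpr", "threshold"])


def fold_change_summary(
    matrix: ExpressionMatrix,
    pair: tuple[str, str],
    labels: pd.Series | None = None,
) -> dict[str, dict[str, float]]:
    """Per-class min/median/max of the expression ratio E(first)/E(second).

    Requires strictly positive values for both genes; samples missing either
    gene are excluded.  With ``labels`` absent, one summary over all samples
    is returned under the key ``"all"``.
    """
    num_gene, den_gene = pair
    sub = matrix.subset_genes([num_gene, den_gene])
    num = sub.values.loc[num_gene]
    den = sub.values.loc[den_gene]
    observed = ~(num.isna() | den.isna())
    if ((num[observed] <= 0) | (den[observed] <= 0)).any():
        raise ValueError("fold-change summary requires strictly positive expression values")
    ratio = num[observed] / den[observed]
    if labels is None:
        groups = {"all": ratio}
    else:
        groups = {
            str(cls): ratio[[s for s in ratio.index if labels.get(s) == cls]]
            for cls in pd.unique(labels.loc[ratio.index])
        }
    out: dict[str, dict[str, float]] = {}
    for cls, vals in groups.items():
        if len(vals) == 0:
            continue
        out[cls] = {
            "min": float(vals.min()),
            "median": float(vals.median()),
            "max": float(vals.max()),
        }
    return out
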