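"""Classifier evaluation: confusion metrics, ROC/AUC, cross-validation.

The four headline metrics are the standard ones for site predictors:
sensitivity Sn = TP/(TP+FN), specificity Sp = TN/(TN+FP), accuracy
Acc = (TP+TN)/N, and the Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

defined as 0 whenever a denominator factor vanishes. ROC curves sweep all
decision-score thresholds; the trapezoid AUC equals the Mann-Whitney
statistic with ties counted 1/2. Cross-validated metrics are pooled over
the concatenated out-of-fold predictions so the count-based formulas stay
exact.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .model import SVMConfig, decision_values, train_svm


@dataclass
class EvaluationReport:
    """Confusion counts, derived metrics, and (optionally) the ROC curve."""

    tp: int
    tn: int
    fp: int
    fn: int
    sn: float
    sp: float
    acc: float
    mcc: float
    roc_points: Optional[np.ndarray] = None  # (n, 2) array of (FPR, TPR)
    auc: Optional[float] = None

    def to_dict(self) -> dict:
        d = {
            "TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn,
            "Sn": self.sn, "Sp": self.sp, "Acc": self.acc, "MCC": self.mcc,
        }
        if self.auc is not None:
            d["AUC"] = self.auc
        return d

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def roc_to_tsv(self, path: Union[str, Path]) -> None:
        if self.roc_points is None:
            raise ValueError("report carries no ROC curve")
        pd.DataFrame(self.roc_points, columns=["FPR", "TPR"]).to_csv(
            path, sep="\t", index=False
        )


def _rate(num: int, den: int) -> float:
    return num / den if den else 0.0


def metrics_from_counts(tp: int, tn: int, fp: int, fn: int) -> EvaluationReport:
    """Sn/Sp/Acc/MCC from a contingency table.

    MCC is 0 when any of the four denominator factors is 0 (the standard
    convention for degenerate tables).
    """
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("empty contingency table")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return EvaluationReport(
        tp=tp, tn=tn, fp=fp, fn=fn,
        sn=_rate(tp, tp + fn),
        sp=_rate(tn, tn + fp),
        acc=(tp + tn) / total,
        mcc=mcc,
    )


def confusion_metrics(
    labels: Sequence[int], predicted: Sequence[int]
) -> EvaluationReport:
    """Confusion counts and metrics from 0/1 label and prediction vectors."""
    y = np.asarray(labels)
    p = np.asarray(predicted)
    if y.shape != p.shape or y.ndim != 1:
        raise ValueError("labels and predictions must be equal-length vectors")
    if y.size == 0:
        raise ValueError("empty input")
    tp = int(np.sum((y == 1) & (p == 1)))
    tn = int(np.sum((y == 0) & (p == 0)))
    fp = int(np.sum((y == 0) & (p == 1)))
    fn = int(np.sum((y == 1) & (p == 0)))
    return metrics_from_counts(tp, tn, fp, fn)


def roc_auc(
    labels: Sequence[int], scores: Sequence[float]
) -> Tuple[np.ndarray, float]:
    """ROC curve over all score thresholds and its trapezoid AUC.

    Returns ``(points, auc)`` with points an (n, 2) array of (FPR, TPR)
    running from (0, 0) to (1, 1). The trapezoid area equals the
    Mann-Whitney probability that a positive outscores a negative, ties
    counted 1/2.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc


def evaluate_scores(
    labels: Sequence[int],
    scores: Sequence[float],
    threshold: float = 0.0,
) -> EvaluationReport:
    """Full report (confusion metrics at ``threshold`` + ROC/AUC)."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    report = confusion_metrics(y, (s > threshold).astype(int))
    report.roc_points, report.auc = roc_auc(y, s)
    return report


def cross_validate(
    X: Union[pd.DataFrame, np.ndarray],
    labels: Sequence[int],
    config: SVMConfig,
) -> Tuple[List[EvaluationReport], EvaluationReport]:
    """Stratified k-fold cross-validation of the RBF C-SVC.

    Each sample is scored exactly once, by the model trained on the other
    folds (scaling refit per fold). Returns per-fold reports plus a pooled
    report over the concatenated out-of-fold scores.
    """
    y = np.asarray(labels)
    Xm = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    if y.size < config.folds:
        raise ValueError("fewer samples than folds")
    skf = StratifiedKFold(
        n_splits=config.folds, shuffle=True, random_state=config.seed
    )
    pooled_scores = np.empty(y.size)
    fold_reports: List[EvaluationReport] = []
    for tr, te in skf.split(Xm, y):
        model = train_svm(Xm[tr], y[tr], config)
        scores = decision_values(model, Xm[te])
        pooled_scores[te] = scores
        fold_reports.append(evaluate_scores(y[te], scores))
    pooled = evaluate_scores(y, pooled_scores)
    return fold_reports, pooled


def reports_to_tsv(
    rows: List[dict], path: Union[str, Path]
) -> None:
    """Flat TSV export for sweep results (one row per configuration)."""
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
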