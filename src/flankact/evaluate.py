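"""Performance metrics and validation protocols.

Metrics: accuracy (percentage), sensitivity, specificity, F1 (computed in
its closed 2TP/(2TP+FN+FP) form) and ROC AUC.  Undefined ratios (empty
denominators) are reported as NaN, never silently zero.

Protocols: stratified 5-fold cross-validation with pooled out-of-fold
predictions, self-consistency (evaluate on own training data),
exchange-testing (evaluate each subset model on the other subset), and
independent testing; the three leading protocols feed the overfitting-aware
model-selection score

    score = sum over Eva in {AUC, Sn, Sp} of  cv_Eva * exchange_Eva / self_Eva

where a lower score flags a more overfit model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, KFold

POSITIVE = "Ac"
NEGATIVE = "NAc"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class EvaluationReport:
    acc: float  # percentage 0..100
    sn: float
    sp: float
    f1: float
    auc: float = np.nan

    def as_dict(self) -> dict:
        return {
            "Acc(%)": self.acc,
            "AUC": self.auc,
            "F1": self.f1,
            "Sn": self.sn,
            "Sp": self.sp,
        }


def _as_binary(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "UO":
        return (arr == POSITIVE).astype(int)
    return arr.astype(int)


def confusion_counts(pred, truth) -> ConfusionCounts:
    p = _as_binary(pred)
    t = _as_binary(truth)
    if len(p) != len(t):
        raise ValueError("prediction and truth lengths differ")
    return ConfusionCounts(
        tp=int(((p == 1) & (t == 1)).sum()),
        fp=int(((p == 1) & (t == 0)).sum()),
        tn=int(((p == 0) & (t == 0)).sum()),
        fn=int(((p == 0) & (t == 1)).sum()),
    )


def confusion_metrics(pred, truth) -> EvaluationReport:
    c = confusion_counts(pred, truth)
    acc = 100.0 * (c.tp + c.tn) / c.n if c.n else np.nan
    sn = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else np.nan
    sp = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else np.nan
    f1 = 2 * c.tp / (2 * c.tp + c.fn + c.fp) if (2 * c.tp + c.fn + c.fp) else np.nan
    return EvaluationReport(acc=acc, sn=sn, sp=sp, f1=f1)


def auc_score(scores, truth) -> float:
    """ROC AUC (trapezoidal; ties averaged, i.e. the rank statistic)."""
    t = _as_binary(truth)
    if t.min() == t.max():
        raise ValueError("both classes must be present to compute AUC")
    return float(roc_auc_score(t, np.asarray(scores, dtype=float)))


def full_report(scores, truth, threshold: float = 0.5) -> EvaluationReport:
    """Threshold scores at ``threshold`` for the confusion metrics, add AUC."""
    pred = (np.asarray(scores, dtype=float) >= threshold).astype(int)
    rep = confusion_metrics(pred, _as_binary(truth))
    rep.auc = auc_score(scores, truth)
    return rep


def kfold_cv(labels, fit_score, k: int = 5, seed: int = 0, keys=None) -> EvaluationReport:
    """Stratified k-fold CV with metrics pooled over out-of-fold predictions.

    ``fit_score(train_idx, test_idx) -> scores`` trains on the first index
    set and returns activation scores for the second.  When ``keys`` (unique
    record identifiers) are given, rows are processed in the canonical order
    sorted by (label, key), so fold assignment depends only on the seed and
    the records themselves, not on input row order.
    """
    y = _as_binary(labels)
    n = len(y)
    if n < k:
        raise ValueError(f"need at least {k} records for {k}-fold CV")
    if keys is not None:
        order = np.lexsort((np.asarray(keys), y))
    else:
        order = np.arange(n)
    y_ord = y[order]
    counts = np.bincount(y, minlength=2)
    if counts.min() >= k:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(n), y_ord)
    else:
        import warnings

        warnings.warn(
            "a class has fewer records than folds; falling back to plain k-fold"
        )
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(n))
    pooled_scores = np.empty(n, dtype=float)
    for train_pos, test_pos in splits:
        train_idx, test_idx = order[train_pos], order[test_pos]
        pooled_scores[test_idx] = np.asarray(
            fit_score(train_idx, test_idx), dtype=float
        )
    return full_report(pooled_scores, y)


@dataclass
class ModelSelectionScore:
    per_metric: dict[str, float]
    total: float


def model_selection_score(
    cv: EvaluationReport, ex: EvaluationReport, self_: EvaluationReport
) -> ModelSelectionScore:
    """Overfitting-aware score: sum over AUC/Sn/Sp of cv * exchange / self."""
    per = {}
    for name in ("auc", "sn", "sp"):
        s = getattr(self_, name)
        if not s or np.isnan(s):
            raise ValueError(f"self-consistency {name} is zero/undefined")
        per[name] = getattr(cv, name) * getattr(ex, name) / s
    return ModelSelectionScore(per_metric=per, total=float(sum(per.values())))


def protocol_table(reports: dict[tuple[str, str], EvaluationReport]) -> pd.DataFrame:
    """Long-format table: one row per (model, protocol)."""
    rows = []
    for (model, protocol), rep in reports.items():
        row = {"model": model, "protocol": protocol}
        row.update(rep.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
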