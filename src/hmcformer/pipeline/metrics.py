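"""Confusion-matrix metrics: accuracy, sensitivity, specificity, precision,
recall, F1, Cohen's kappa and rank-based AUC.

Binary metrics follow the usual TP/TN/FP/FN definitions with
``error_rate = 1 - accuracy`` and the kappa chance term
``P_e = ((TP+FP)(TP+FN) + (FN+TN)(FP+TN)) / N^2``.  Multi-class reports
use one-vs-rest macro averaging and the standard multi-class kappa from
the full confusion matrix.  AUC is the fraction of (positive, negative)
score pairs ranked correctly, ties counting one half.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np


@dataclass
class MetricsReport:
    accuracy: float
    sensitivity: float
    specificity: float
    error_rate: float
    precision: float
    recall: float
    f1: float
    kappa: float
    auc: float | None = None
    mode: str = "binary"

    def to_dict(self) -> dict:
        return asdict(self)


def _safe_div(a: float, b: float) -> float:
    return a / b if b else 0.0


def compute_binary_metrics(tp: int, tn: int, fp: int, fn: int) -> MetricsReport:
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("empty confusion counts")
    acc = (tp + tn) / total
    sens = _safe_div(tp, tp + fn)
    spec = _safe_div(tn, tn + fp)
    prec = _safe_div(tp, tp + fp)
    rec = sens
    f1 = _safe_div(2 * rec * prec, rec + prec)
    p_o = acc
    p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / total ** 2
    kappa = _safe_div(p_o - p_e, 1 - p_e) if p_e < 1 else 1.0
    return MetricsReport(accuracy=acc, sensitivity=sens, specificity=spec,
                         error_rate=1 - acc, precision=prec, recall=rec,
                         f1=f1, kappa=kappa, mode="binary")


def confusion_matrix(preds, labels, n_classes: int | None = None) -> np.ndarray:
    preds = np.asarray(preds, dtype=np.int64)
    labels = np.asarray(labels, dtype=np.int64)
    if preds.shape != labels.shape:
        raise ValueError("prediction/label length mismatch")
    k = n_classes or int(max(preds.max(), labels.max())) + 1
    cm = np.zeros((k, k), dtype=np.int64)
    np.add.at(cm, (labels, preds), 1)
    return cm


def compute_macro_metrics(cm: np.ndarray) -> MetricsReport:
    """One-vs-rest macro averages from a K x K confusion matrix
    (rows = true class, columns = predicted class)."""
    cm = np.asarray(cm, dtype=np.float64)
    k = cm.shape[0]
    if cm.shape != (k, k) or k < 2:
        raise ValueError("need a square confusion matrix, K >= 2")
    total = cm.sum()
    tp = np.diag(cm)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    tn = total - tp - fn - fp
    sens = np.array([_safe_div(t, t + f) for t, f in zip(tp, fn)])
    spec = np.array([_safe_div(t, t + f) for t, f in zip(tn, fp)])
    prec = np.array([_safe_div(t, t + f) for t, f in zip(tp, fp)])
    f1 = np.array([_safe_div(2 * s * p, s + p) for s, p in zip(sens, prec)])
    acc = tp.sum() / total
    p_e = float((cm.sum(axis=1) * cm.sum(axis=0)).sum()) / total ** 2
    kappa = _safe_div(acc - p_e, 1 - p_e) if p_e < 1 else 1.0
    return MetricsReport(accuracy=float(acc), sensitivity=float(sens.mean()),
                         specificity=float(spec.mean()),
                         error_rate=float(1 - acc),
                         precision=float(prec.mean()),
                         recall=float(sens.mean()), f1=float(f1.mean()),
                         kappa=float(kappa), mode="macro")


def compute_auc(pos_scores, neg_scores) -> float:
    """Rank-pair AUC: P(score_pos > score_neg), ties counted 0.5."""
    pos = np.asarray(pos_scores, dtype=np.float64)
    neg = np.asarray(neg_scores, dtype=np.float64)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need at least one positive and one negative score")
    diff = pos[:, None] - neg[None, :]
    wins = (diff > 0).sum() + 0.5 * (diff == 0).sum()
    return float(wins / (pos.size * neg.size))


def metrics_from_predictions(preds, labels, scores=None,
                             n_classes: int | None = None) -> MetricsReport:
    """Build the right report for the label arity; binary adds AUC when
    positive-class scores are supplied."""
    preds = np.asarray(preds, dtype=np.int64)
    labels = np.asarray(labels, dtype=np.int64)
    k = n_classes or int(max(preds.max(initial=0), labels.max(initial=0))) + 1
    if k <= 2:
        cm = confusion_matrix(preds, labels, 2)
        tn, fp, fn, tp = cm[0, 0], cm[0, 1], cm[1, 0], cm[1, 1]
        rep = compute_binary_metrics(tp, tn, fp, fn)
        if scores is not None:
            scores = np.asarray(scores, dtype=np.float64)
            rep.auc = compute_auc(scores[labels == 1], scores[labels == 0])
        return rep
    return compute_macro_metrics(confusion_matrix(preds, labels, k))


def average_reports(reports: list[MetricsReport]) -> MetricsReport:
    """Unweighted mean of per-fold reports (cross-validation aggregate)."""
    if not reports:
        raise ValueError("no reports to average")
    fields = ["accuracy", "sensitivity", "specificity", "error_rate",
              "precision", "recall", "f1", "kappa"]
    mean = {f: float(np.mean([getattr(r, f) for r in reports])) for f in fields}
    aucs = [r.auc for r in reports if r.auc is not None]
    return MetricsReport(**mean, auc=float(np.mean(aucs)) if aucs else None,
                         mode=reports[0].mode)
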