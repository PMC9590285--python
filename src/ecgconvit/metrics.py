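"""Confusion counts and the six-metric evaluation suite.

For each class c the 5x5 confusion matrix is reduced one-vs-rest to
TP/TN/FP/FN, from which accuracy, sensitivity (recall), specificity,
positive predictive value (precision), F1 and the Matthews correlation
coefficient are computed:

    Acc = (TP+TN)/(TP+TN+FP+FN)      Sen = TP/(TP+FN)
    Spe = TN/(TN+FP)                 Ppv = TP/(TP+FP)
    F1  = 2 Ppv Sen / (Ppv + Sen)    MCC = (TP TN - FP FN)/sqrt(prod of margins)

Overall accuracy is trace/total of the multi-class matrix.  A
``paper_literal`` F1 convention without the factor 2 is kept behind a flag
for comparison with sources that print the harmonic-mean formula that way.
Zero-denominator cells yield 0 and are flagged rather than NaN so macro
averages stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

DEFAULT_CLASSES = ("F", "N", "Q", "S", "V")


@dataclass
class ConfusionCounts:
    """A multi-class confusion matrix plus its one-vs-rest reductions."""

    matrix: np.ndarray          # (C, C), rows = true class, cols = predicted
    classes: tuple

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    def one_vs_rest(self, label) -> dict[str, int]:
        i = list(self.classes).index(label)
        tp = int(self.matrix[i, i])
        fn = int(self.matrix[i, :].sum() - tp)
        fp = int(self.matrix[:, i].sum() - tp)
        tn = self.total - tp - fn - fp
        return {"TP": tp, "TN": tn, "FP": fp, "FN": fn}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.classes),
                            columns=list(self.classes))


@dataclass
class MetricsReport:
    per_class: pd.DataFrame     # rows = classes, cols = Acc..MCC
    overall_accuracy: float
    macro: pd.Series
    degenerate: dict            # class -> list of metrics that hit a 0 denominator

    def to_json(self) -> str:
        import json
        return json.dumps({
            "per_class": self.per_class.to_dict(orient="index"),
            "overall_accuracy": self.overall_accuracy,
            "macro": self.macro.to_dict(),
            "degenerate": self.degenerate})


def confusion(true_labels, predicted_labels, classes=None) -> ConfusionCounts:
    """Exact integer confusion counts (rows true, columns predicted)."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if len(t) != len(p):
        raise ValueError(f"length mismatch: {len(t)} true vs {len(p)} predicted")
    if classes is None:
        classes = DEFAULT_CLASSES
    index = {c: i for i, c in enumerate(classes)}
    m = np.zeros((len(classes), len(classes)), dtype=int)
    for ti, pi in zip(t, p):
        if ti not in index or pi not in index:
            raise ValueError(f"label outside class set: {ti!r} / {pi!r}")
        m[index[ti], index[pi]] += 1
    return ConfusionCounts(m, tuple(classes))


def _safe_div(num: float, den: float, flags: list, name: str) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def metrics(counts: ConfusionCounts, f1_convention: str = "standard") -> MetricsReport:
    """Per-class Acc/Sen/Spe/Ppv/F1/MCC, macro averages and overall accuracy."""
    if f1_convention not in ("standard", "paper_literal"):
        raise ValueError(f"unknown F1 convention {f1_convention!r}")
    rows = {}
    degenerate: dict = {}
    for c in counts.classes:
        ovr = counts.one_vs_rest(c)
        tp, tn, fp, fn = ovr["TP"], ovr["TN"], ovr["FP"], ovr["FN"]
        flags: list[str] = []
        acc = _safe_div(tp + tn, tp + tn + fp + fn, flags, "Acc")
        sen = _safe_div(tp, tp + fn, flags, "Sen")
        spe = _safe_div(tn, tn + fp, flags, "Spe")
        ppv = _safe_div(tp, tp + fp, flags, "Ppv")
        f1_num = (2.0 if f1_convention == "standard" else 1.0) * ppv * sen
        f1 = _safe_div(f1_num, ppv + sen, flags, "F1")
        mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        mcc = _safe_div(tp * tn - fp * fn, mcc_den, flags, "MCC")
        rows[c] = {"Acc": acc, "Sen": sen, "Spe": spe, "Ppv": ppv,
                   "F1": f1, "MCC": mcc}
        if flags:
            degenerate[c] = flags
    per_class = pd.DataFrame.from_dict(rows, orient="index")
    overall = counts.matrix.trace() / counts.total if counts.total else 0.0
    return MetricsReport(per_class, float(overall), per_class.mean(axis=0), degenerate)


def evaluate(true_labels, predicted_labels, classes=None,
             f1_convention: str = "standard") -> MetricsReport:
    """Convenience wrapper: labels -> confusion -> metrics."""
    return metrics(confusion(true_labels, predicted_labels, classes), f1_convention)


def roc_auc(scores: np.ndarray, true_labels, classes=None) -> dict:
    """One-vs-rest ROC curves and trapezoidal AUC per class.

    ``scores`` is (n, C) with columns ordered like ``classes``.  Classes
    with no positives or no negatives get ``auc=None`` and an
    ``undefined`` flag instead of a curve.
    """
    scores = np.asarray(scores, dtype=float)
    t = np.asarray(true_labels)
    if classes is None:
        classes = DEFAULT_CLASSES
    if scores.ndim != 2 or scores.shape[1] != len(classes):
        raise ValueError(f"scores must be (n, {len(classes)})")
    if np.any(scores < 0) or np.any(scores > 1):
        raise ValueError("scores must lie in [0, 1]")
    out = {}
    for j, c in enumerate(classes):
        pos = (t == c).astype(int)
        if pos.sum() == 0 or pos.sum() == len(pos):
            out[c] = {"fpr": None, "tpr": None, "auc": None, "undefined": True}
            continue
        fpr, tpr, _ = _sk_roc_curve(pos, scores[:, j])
        out[c] = {"fpr": fpr, "tpr": tpr, "auc": float(_sk_auc(fpr, tpr)),
                  "undefined": False}
    return out
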