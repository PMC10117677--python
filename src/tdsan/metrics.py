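"""Evaluation report: accuracy, macro-F1 and per-class precision/recall/F1.

ACC = Σ_i TP_i / M (trace of the confusion matrix over the sample count) and
MF1 = (1/K) Σ_i 2 P_i R_i / (P_i + R_i), the unweighted mean of per-class F1.
Any metric whose denominator is zero (a class never predicted, or absent
from the truth) is reported as 0, so empty minority classes pull MF1 down
rather than being silently skipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from .io_preprocess import LABEL_NAMES

__all__ = ["EvalReport", "evaluate", "report_table"]


@dataclass
class EvalReport:
    confusion: np.ndarray  # (K, K) ints, rows = true, cols = predicted
    acc: float
    mf1: float
    per_class: list[tuple[float, float, float, int]]  # (P, R, F1, support)

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "acc": self.acc,
            "mf1": self.mf1,
            "per_class": [
                {"precision": p, "recall": r, "f1": f, "support": s}
                for p, r, f, s in self.per_class
            ],
        }


def evaluate(y_true, y_pred, k: int = 5) -> EvalReport:
    """Confusion matrix, ACC, MF1 and per-class P/R/F1 with support."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape[0]} true vs {y_pred.shape[0]} predicted"
        )
    labels = np.arange(k)
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    p, r, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0
    )
    acc = float(np.trace(cm)) / max(len(y_true), 1)
    return EvalReport(
        confusion=cm,
        acc=acc,
        mf1=float(f1.mean()),
        per_class=[
            (float(pi), float(ri), float(fi), int(si))
            for pi, ri, fi, si in zip(p, r, f1, support)
        ],
    )


def report_table(report: EvalReport, class_names=LABEL_NAMES) -> str:
    """Plain-text per-class table (percentages, two decimals)."""
    k = len(report.per_class)
    names = list(class_names)[:k]
    rows = [f"{'Stage':<6} {'Precision':>10} {'Recall':>10} {'F1-score':>10} {'Support':>8}"]
    for name, (p, r, f1, s) in zip(names, report.per_class):
        rows.append(f"{name:<6} {p * 100:>10.2f} {r * 100:>10.2f} {f1 * 100:>10.2f} {s:>8d}")
    m = int(report.confusion.sum())
    rows.append(f"{'ACC':<6} {report.acc * 100:>10.2f}%   MF1 {report.mf1 * 100:.2f}%   M={m}")
    return "\n".join(rows)
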