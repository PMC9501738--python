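"""Confusion matrices and macro precision / recall / F-score.

Per class c over a K x K confusion matrix (rows = true, cols = predicted):

    precision_c = TP_c / (TP_c + FP_c)
    recall_c    = TP_c / (TP_c + FN_c)
    F_c         = 2 * precision_c * recall_c / (precision_c + recall_c)

Macro values are the unweighted means across classes; accuracy is the
trace over the total. A class that is never predicted gets precision 0
and is flagged in the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion", "metrics", "fscore",
           "report", "format_report"]


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # K x K, rows = true class, cols = predicted

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricsReport:
    precision: np.ndarray      # per class
    recall: np.ndarray
    f: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f: float
    accuracy: float
    degenerate_classes: list[int] = field(default_factory=list)
    model_kind: str = ""
    partition: str = ""


def confusion(y_true, y_pred, n_classes: int) -> ConfusionMatrix:
    """Count matrix with ``counts[t, p] = #{i : y_true_i = t, y_pred_i = p}``."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if y.size and (y.min() < 0 or y.max() >= n_classes):
            raise ValueError(f"{name} contains labels outside [0, {n_classes})")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts)


def fscore(precision: float, recall: float) -> float:
    """Harmonic mean ``2pr/(p+r)``; defined as 0 when both are 0."""
    if precision == 0.0 and recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def metrics(cm: ConfusionMatrix, model_kind: str = "", partition: str = "") -> MetricsReport:
    """Per-class and macro-averaged precision/recall/F plus accuracy."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    counts = cm.counts.astype(float)
    tp = np.diag(counts)
    col = counts.sum(axis=0)  # TP + FP
    row = counts.sum(axis=1)  # TP + FN
    degenerate = np.flatnonzero(col == 0).tolist()
    precision = np.divide(tp, col, out=np.zeros_like(tp), where=col > 0)
    recall = np.divide(tp, row, out=np.zeros_like(tp), where=row > 0)
    f = np.array([fscore(p, r) for p, r in zip(precision, recall)])
    return MetricsReport(
        precision=precision,
        recall=recall,
        f=f,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f=float(f.mean()),
        accuracy=float(tp.sum() / cm.total),
        degenerate_classes=degenerate,
        model_kind=model_kind,
        partition=partition,
    )


def report(models, split, table) -> list[MetricsReport]:
    """Train and test metrics for each trained model, in a flat list.

    ``models`` are TrainedClassifier objects fitted on ``split.train_rows``
    of ``table``; the row counts must cover the table exactly.
    """
    if table.labels is None:
        raise ValueError("table must carry labels")
    n = table.n_samples
    covered = np.sort(np.concatenate([split.train_rows, split.test_rows]))
    if not np.array_equal(covered, np.arange(n)):
        raise ValueError("split does not cover the table's rows exactly")
    K = table.n_classes
    out = []
    for model in models:
        for tag, rows in (("training", split.train_rows), ("testing", split.test_rows)):
            y = table.labels[rows]
            pred = model.predict(table.X[rows])
            out.append(metrics(confusion(y, pred, K), model_kind=model.kind, partition=tag))
    return out


def format_report(reports: list[MetricsReport]) -> str:
    """Aligned plain-text table mirroring the macro P/R/F layout."""
    lines = [f"{'Model':<10}{'Set':<10}{'Precision':>10}{'Recall':>10}{'F-Score':>10}{'Accuracy':>10}"]
    for r in reports:
        lines.append(
            f"{r.model_kind:<10}{r.partition:<10}"
            f"{r.macro_precision:>10.4f}{r.macro_recall:>10.4f}"
            f"{r.macro_f:>10.4f}{r.accuracy:>10.4f}"
        )
    return "\n".join(lines)
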