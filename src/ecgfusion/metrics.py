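"""Confusion matrix and per-class heartbeat classification metrics.

Per class (one-vs-rest), with TP/FP/FN/TN the usual counts:

    Acc = (TP+TN)/(TP+FP+TN+FN) * 100
    PPV = TP/(TP+FP) * 100
    Se  = TP/(TP+FN) * 100
    F1  = 2*Se*PPV/(Se+PPV)
    Sp  = TN/(TN+FP) * 100

All values are percentages.  A 0/0 ratio is reported as ``nan`` (an
"undefined" marker) and excluded from any averaging.  The overall accuracy
is trace/total * 100.  Class order follows the AAMI taxonomy
(N, SVEB, VEB, F, Q).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .wfdb_io import AamiClass

__all__ = ["ConfusionMatrix", "ClassMetrics", "confusion", "metrics"]

_AAMI_NAMES = [c.name for c in AamiClass]


@dataclass
class ConfusionMatrix:
    """K x K count table: rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")
        if not self.class_names:
            k = self.counts.shape[0]
            self.class_names = _AAMI_NAMES[:k] if k <= 5 else [str(i) for i in range(k)]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_text(self) -> str:
        """Delimited text with header row/column labels."""
        lines = ["true\\pred\t" + "\t".join(self.class_names)]
        for name, row in zip(self.class_names, self.counts):
            lines.append(name + "\t" + "\t".join(str(int(v)) for v in row))
        return "\n".join(lines)


@dataclass
class ClassMetrics:
    """Per-class one-vs-rest counts and percentage metrics."""

    class_names: list[str]
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray
    acc: np.ndarray
    se: np.ndarray
    ppv: np.ndarray
    sp: np.ndarray
    f1: np.ndarray
    overall_acc: float

    def summary(self, include_q: bool = False, digits: int = 1) -> str:
        """Formatted per-class table; the Q class is optional (its beats
        stay in the confusion matrix either way)."""
        names = self.class_names
        rows = []
        for i, name in enumerate(names):
            if name == "Q" and not include_q:
                continue
            vals = [self.acc[i], self.se[i], self.ppv[i], self.sp[i], self.f1[i]]
            rows.append(
                f"{name:>5} "
                + " ".join("   nan" if np.isnan(v) else f"{v:6.{digits}f}" for v in vals)
            )
        head = f"{'class':>5} {'Acc':>6} {'Se':>6} {'PPV':>6} {'Sp':>6} {'F1':>6}"
        tail = f"overall Acc: {self.overall_acc:.{digits}f}%"
        return "\n".join([head, *rows, tail])


def confusion(y_true, y_pred, n_classes: int = 5) -> ConfusionMatrix:
    """Count table of true vs predicted labels, both in ``[0, n_classes)``."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size and (
        y_true.min() < 0 or y_true.max() >= n_classes
        or y_pred.min() < 0 or y_pred.max() >= n_classes
    ):
        raise ValueError(f"labels must lie in [0, {n_classes})")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts)


def _ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.full(num.shape, np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok] * 100.0
    return out


def metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """Per-class Acc/Se/PPV/Sp/F1 (percent) and overall accuracy."""
    counts = cm.counts
    if counts.sum() == 0:
        raise ValueError("empty confusion matrix")
    total = counts.sum()
    tp = np.diag(counts).astype(np.float64)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    tn = total - tp - fp - fn
    acc = (tp + tn) / total * 100.0
    se = _ratio(tp, tp + fn)
    ppv = _ratio(tp, tp + fp)
    sp = _ratio(tn, tn + fp)
    with np.errstate(invalid="ignore"):
        f1 = 2 * se * ppv / (se + ppv)
    f1[np.isnan(se) | np.isnan(ppv)] = np.nan
    zero_both = np.isclose(se, 0) & np.isclose(ppv, 0)
    f1[zero_both & ~np.isnan(se) & ~np.isnan(ppv)] = 0.0
    overall = float(tp.sum() / total * 100.0)
    return ClassMetrics(
        class_names=list(cm.class_names),
        tp=tp.astype(np.int64), fp=fp.astype(np.int64),
        fn=fn.astype(np.int64), tn=tn.astype(np.int64),
        acc=acc, se=se, ppv=ppv, sp=sp, f1=f1,
        overall_acc=overall,
    )
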