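"""Confusion-matrix bookkeeping and binary classification measures.

All measures are reported on the percentage scale.  A measure whose
denominator is zero is *undefined* and carried as ``None`` — never silently
replaced by a number — and undefined values are excluded (with a warning)
from cross-fold averages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class UndefinedMetricWarning(UserWarning):
    """A fold contributed an undefined metric that was excluded from a mean."""


@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


#: Field order mirrors the conventional cross-validation report layout.
METRIC_NAMES = ("sensitivity", "specificity", "precision", "fdr",
                "accuracy", "f_measure")


@dataclass(frozen=True)
class MetricSet:
    """The six performance measures, in percent; ``None`` marks undefined."""

    sensitivity: float | None
    specificity: float | None
    precision: float | None
    fdr: float | None
    accuracy: float | None
    f_measure: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def confusion(y_true: Sequence, y_pred: Sequence,
              positive_label="positive") -> ConfusionMatrix:
    """Tally a binary confusion matrix.

    Labels may be any hashables; everything equal to ``positive_label`` is
    the positive class and there must be at most one other label value.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be 1-D and equal-length")
    labels = set(y_true.tolist()) | set(y_pred.tolist())
    if len(labels - {positive_label}) > 1:
        raise ValueError(f"labels are not binary: {sorted(map(str, labels))}")
    t = y_true == positive_label
    p = y_pred == positive_label
    return ConfusionMatrix(TP=int(np.sum(t & p)), FP=int(np.sum(~t & p)),
                           TN=int(np.sum(~t & ~p)), FN=int(np.sum(t & ~p)))


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def metric_set(cm: ConfusionMatrix) -> MetricSet:
    """Compute the six measures from a confusion matrix (percent scale).

    precision = TP/(TP+FP); sensitivity = TP/(TP+FN);
    specificity = TN/(TN+FP); FDR = FP/(FP+TP);
    accuracy = (TP+TN)/total; F = harmonic mean of precision and sensitivity.
    """
    if cm.total == 0:
        raise ValueError("cannot compute metrics on zero evaluated samples")
    precision = _ratio(cm.TP, cm.TP + cm.FP)
    sensitivity = _ratio(cm.TP, cm.TP + cm.FN)
    specificity = _ratio(cm.TN, cm.TN + cm.FP)
    fdr = _ratio(cm.FP, cm.FP + cm.TP)
    accuracy = _ratio(cm.TP + cm.TN, cm.total)
    if precision is None or sensitivity is None or precision + sensitivity == 0:
        f_measure = None
    else:
        f_measure = 2 * precision * sensitivity / (precision + sensitivity)
    return MetricSet(sensitivity=sensitivity, specificity=specificity,
                     precision=precision, fdr=fdr, accuracy=accuracy,
                     f_measure=f_measure)


def mean_metric_sets(sets: Iterable[MetricSet]) -> MetricSet:
    """Component-wise arithmetic mean; undefined folds are excluded.

    A warning is emitted whenever an undefined value is dropped, because a
    mean over a subset of folds is not directly comparable across metrics.
    """
    sets = list(sets)
    if not sets:
        raise ValueError("cannot average an empty list of metric sets")
    out = {}
    for name in METRIC_NAMES:
        vals = [getattr(s, name) for s in sets]
        defined = [v for v in vals if v is not None]
        if len(defined) < len(vals):
            warnings.warn(
                f"{len(vals) - len(defined)} fold(s) had undefined "
                f"{name}; excluded from the mean", UndefinedMetricWarning,
                stacklevel=2)
        out[name] = sum(defined) / len(defined) if defined else None
    return MetricSet(**out)


def report_table(per_fold: Sequence[MetricSet],
                 mean: MetricSet | None = None) -> pd.DataFrame:
    """One row per fold plus an ``Average`` row, two-decimal percent values."""
    if mean is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UndefinedMetricWarning)
            mean = mean_metric_sets(per_fold)
    rows = [{"fold": i + 1, **m.as_dict()} for i, m in enumerate(per_fold)]
    rows.append({"fold": "Average", **mean.as_dict()})
    df = pd.DataFrame(rows).set_index("fold")
    return df.map(lambda v: None if v is None else round(v, 2))
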