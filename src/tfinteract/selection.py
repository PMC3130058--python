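"""Stratified cross-validation folds and wrapper forward feature selection.

The wrapper greedily grows a feature list: at every step each unselected
candidate is appended in turn, the QDA classifier is refit and evaluated
under k-fold cross-validation, and the candidate giving the best mean
performance is kept.  The fold partition is built once and reused — bit for
bit — for every candidate at every step, so scores are comparable across
the whole search.  Ties break toward the lowest candidate index, and a
candidate whose fit fails (singular covariance) scores zero rather than
aborting the search.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import SingularCovarianceError, StratificationError
from .metrics import (MetricSet, UndefinedMetricWarning, confusion,
                      mean_metric_sets, metric_set)
from .qda import DEFAULT_RIDGE, fit_qda, predict

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FoldAssignment:
    """Per-sample fold indices in 1..k, stratified by class.

    A deterministic function of ``(labels, k, seed)``: fold sizes differ by
    at most one overall and within every class.
    """

    fold_of: np.ndarray
    k: int
    seed: int

    def test_mask(self, fold: int) -> np.ndarray:
        return self.fold_of == fold

    def digest(self) -> str:
        h = hashlib.sha1()
        h.update(np.asarray(self.fold_of, dtype=np.int64).tobytes())
        h.update(f"k={self.k};seed={self.seed}".encode())
        return h.hexdigest()[:16]


def make_stratified_folds(labels: Sequence, k: int, seed: int
                          ) -> FoldAssignment:
    """Assign samples to k folds, as evenly as possible within each class.

    Within a class, sample order is shuffled by a seeded generator and base
    counts ``n_c // k`` go to every fold; each remainder sample goes to a
    currently smallest fold (ties broken by fold index), which keeps the
    overall fold sizes within one of each other as well.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if k < 2:
        raise StratificationError(f"k must be >= 2, got {k}")
    rng = np.random.default_rng(seed)
    fold_of = np.zeros(n, dtype=np.int64)
    totals = np.zeros(k, dtype=np.int64)
    for lab in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == lab)
        if len(idx) < k:
            raise StratificationError(
                f"class {lab!r} has {len(idx)} samples, fewer than k={k}")
        idx = idx[rng.permutation(len(idx))]
        counts = np.full(k, len(idx) // k, dtype=np.int64)
        for _ in range(len(idx) % k):
            # smallest running total, earliest fold on ties
            f = int(np.argmin(totals + counts))
            counts[f] += 1
        pos = 0
        for f in range(k):
            fold_of[idx[pos:pos + counts[f]]] = f + 1
            pos += counts[f]
        totals += counts
    return FoldAssignment(fold_of=fold_of, k=k, seed=seed)


def cv_evaluate(feature_subset: Sequence[int], X: np.ndarray, y: Sequence,
                folds: FoldAssignment, ridge: float = DEFAULT_RIDGE,
                positive_label="positive"
                ) -> tuple[list[MetricSet], MetricSet]:
    """k-fold evaluation of QDA restricted to ``feature_subset``.

    For each fold the model is fit on the out-of-fold samples and scored on
    the held-out fold.  Deterministic given its inputs.
    """
    feature_subset = list(feature_subset)
    if not feature_subset:
        raise ValueError("feature_subset must be non-empty")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(folds.fold_of) != X.shape[0]:
        raise ValueError("fold assignment does not cover all samples")
    Xs = X[:, feature_subset]
    per_fold: list[MetricSet] = []
    for f in range(1, folds.k + 1):
        test = folds.test_mask(f)
        try:
            model = fit_qda(Xs[~test], y[~test], ridge=ridge)
        except SingularCovarianceError as exc:
            raise SingularCovarianceError(
                f"fold {f}: {exc}", class_label=exc.class_label) from None
        cm = confusion(y[test], predict(model, Xs[test]),
                       positive_label=positive_label)
        per_fold.append(metric_set(cm))
    return per_fold, mean_metric_sets(per_fold)


@dataclass(frozen=True)
class SelectionStep:
    """One wrapper step: the feature added and its cross-validated metrics."""

    feature_index: int
    per_fold_metrics: list[MetricSet]
    mean_metrics: MetricSet
    folds_digest: str


@dataclass
class SelectionTrace:
    """Ordered record of the wrapper search."""

    steps: list[SelectionStep] = field(default_factory=list)
    folds: FoldAssignment | None = None
    ridge: float = DEFAULT_RIDGE
    candidate_pool: list[int] = field(default_factory=list)
    criterion: str = "accuracy"
    failed_candidates: list[tuple[int, int]] = field(default_factory=list)

    def selected_features(self) -> list[int]:
        return [s.feature_index for s in self.steps]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for t, s in enumerate(self.steps, start=1):
            row = {"step": t, "feature_index": s.feature_index}
            for f, m in enumerate(s.per_fold_metrics, start=1):
                row[f"fold{f}_accuracy"] = m.accuracy
            row["mean_accuracy"] = s.mean_metrics.accuracy
            row[f"mean_{self.criterion}"] = getattr(s.mean_metrics,
                                                    self.criterion)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        payload = {
            "criterion": self.criterion,
            "ridge": self.ridge,
            "candidate_pool": list(self.candidate_pool),
            "folds": None if self.folds is None else {
                "k": self.folds.k, "seed": self.folds.seed,
                "fold_of": self.folds.fold_of.tolist(),
                "digest": self.folds.digest()},
            "failed_candidates": [list(t) for t in self.failed_candidates],
            "steps": [{
                "step": t + 1,
                "feature_index": s.feature_index,
                "per_fold": [m.as_dict() for m in s.per_fold_metrics],
                "mean": s.mean_metrics.as_dict(),
                "folds_digest": s.folds_digest,
            } for t, s in enumerate(self.steps)],
        }
        return json.dumps(payload, indent=1)


def _criterion_value(mean: MetricSet, criterion: str) -> float:
    v = getattr(mean, criterion)
    return 0.0 if v is None else v


def forward_select(X: np.ndarray, y: Sequence, folds: FoldAssignment,
                   max_features: int = 150, ridge: float = DEFAULT_RIDGE,
                   candidate_pool: Sequence[int] | None = None,
                   criterion: str = "accuracy",
                   positive_label="positive") -> SelectionTrace:
    """Greedy wrapper search under one preserved fold partition.

    ``candidate_pool`` restricts the columns considered (defaults to all);
    step t therefore costs ``len(pool) - t + 1`` cross-validated fits.
    """
    X = np.asarray(X, dtype=float)
    pool = (list(range(X.shape[1])) if candidate_pool is None
            else sorted(int(c) for c in candidate_pool))
    if len(set(pool)) != len(pool):
        raise ValueError("candidate_pool contains duplicates")
    if max_features > len(pool):
        raise ValueError(
            f"max_features={max_features} exceeds the candidate pool "
            f"size {len(pool)}")
    if criterion not in MetricSet.__dataclass_fields__:
        raise ValueError(f"unknown selection criterion {criterion!r}")
    digest = folds.digest()
    trace = SelectionTrace(folds=folds, ridge=ridge, candidate_pool=pool,
                           criterion=criterion)
    selected: list[int] = []
    for step in range(1, max_features + 1):
        best: tuple[float, int] | None = None
        best_eval: tuple[list[MetricSet], MetricSet] | None = None
        for cand in pool:  # ascending order => lowest index wins ties
            if cand in selected:
                continue
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", UndefinedMetricWarning)
                    per_fold, mean = cv_evaluate(
                        selected + [cand], X, y, folds, ridge=ridge,
                        positive_label=positive_label)
                score = _criterion_value(mean, criterion)
            except SingularCovarianceError as exc:
                logger.warning("step %d: candidate %d failed (%s); scored 0",
                               step, cand, exc)
                trace.failed_candidates.append((step, cand))
                continue
            if best is None or score > best[0]:
                best = (score, cand)
                best_eval = (per_fold, mean)
        if best is None:
            logger.warning("step %d: no candidate could be fit; stopping",
                           step)
            break
        selected.append(best[1])
        trace.steps.append(SelectionStep(
            feature_index=best[1], per_fold_metrics=best_eval[0],
            mean_metrics=best_eval[1], folds_digest=digest))
    return trace


def best_subset(trace: SelectionTrace) -> list[int]:
    """Shortest trace prefix attaining the maximal mean criterion value."""
    if not trace.steps:
        raise ValueError("selection trace is empty")
    scores = [_criterion_value(s.mean_metrics, trace.criterion)
              for s in trace.steps]
    best_len = int(np.argmax(scores)) + 1  # argmax -> earliest == shortest
    return trace.selected_features()[:best_len]
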