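"""Stratified folds, cross-validated evaluation, and the wrapper search."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from tfinteract import (best_subset, cv_evaluate, forward_select,
                        make_stratified_folds)
from tfinteract.errors import StratificationError
from tfinteract.metrics import MetricSet, metric_set, ConfusionMatrix
from tfinteract.selection import SelectionStep, SelectionTrace


def _labels(n_pos, n_neg):
    return np.array(["positive"] * n_pos + ["negative"] * n_neg)


# ---------------------------------------------------------------------------
# Fold construction
# ---------------------------------------------------------------------------

def test_balanced_case_puts_one_of_each_class_per_fold():
    fa = make_stratified_folds(_labels(10, 10), k=10, seed=3)
    for f in range(1, 11):
        mask = fa.test_mask(f)
        assert mask.sum() == 2
        assert set(np.array(_labels(10, 10))[mask]) == \
            {"positive", "negative"}


def test_fold_assignment_is_deterministic():
    y = _labels(23, 31)
    a = make_stratified_folds(y, 5, seed=17)
    b = make_stratified_folds(y, 5, seed=17)
    assert np.array_equal(a.fold_of, b.fold_of)
    assert a.digest() == b.digest()
    c = make_stratified_folds(y, 5, seed=18)
    assert not np.array_equal(a.fold_of, c.fold_of)


@pytest.mark.parametrize("k, n_pos, n_neg", [(1, 5, 5), (5, 3, 10)])
def test_invalid_stratification_raises(k, n_pos, n_neg):
    with pytest.raises(StratificationError):
        make_stratified_folds(_labels(n_pos, n_neg), k, seed=0)


@given(n_pos=st.integers(4, 40), n_neg=st.integers(4, 40),
       k=st.integers(2, 4), seed=st.integers(0, 100))
@settings(max_examples=40, deadline=None)
def test_fold_sizes_balanced_overall_and_per_class(n_pos, n_neg, k, seed):
    y = _labels(n_pos, n_neg)
    fa = make_stratified_folds(y, k, seed)
    sizes = np.array([fa.test_mask(f).sum() for f in range(1, k + 1)])
    assert sizes.max() - sizes.min() <= 1
    for lab in ("positive", "negative"):
        cls = np.array([(fa.test_mask(f) & (y == lab)).sum()
                        for f in range(1, k + 1)])
        assert cls.max() - cls.min() <= 1
    assert sizes.sum() == len(y)


# ---------------------------------------------------------------------------
# Cross-validated evaluation
# ---------------------------------------------------------------------------

def _separable_data(n=100, noise_cols=3, seed=0):
    rng = np.random.default_rng(seed)
    y = _labels(n // 2, n // 2)
    X = rng.normal(size=(n, 1 + noise_cols))
    X[:n // 2, 0] += 10.0  # feature 0 separates with a wide margin
    return X, y


def test_separating_feature_reaches_full_accuracy():
    X, y = _separable_data()
    folds = make_stratified_folds(y, 5, seed=1)
    _, mean = cv_evaluate([0], X, y, folds)
    assert mean.accuracy == 100.0


def test_cv_is_deterministic_bitwise():
    X, y = _separable_data(seed=2)
    folds = make_stratified_folds(y, 5, seed=1)
    a = cv_evaluate([0, 1], X, y, folds)
    b = cv_evaluate([0, 1], X, y, folds)
    assert a == b


def test_permuted_labels_score_near_chance():
    # featureless noise: permuting the labels leaves no class structure
    rng = np.random.default_rng(10)
    X = rng.normal(size=(500, 4))
    y_perm = _labels(250, 250)[rng.permutation(500)]
    folds = make_stratified_folds(y_perm, 10, seed=2)
    _, mean = cv_evaluate([0, 1], X, y_perm, folds)
    lo = binom.ppf(0.005, 500, 0.5) / 5.0  # percent scale
    hi = binom.ppf(0.995, 500, 0.5) / 5.0
    assert lo <= mean.accuracy <= hi


# ---------------------------------------------------------------------------
# Forward selection
# ---------------------------------------------------------------------------

def test_dominant_feature_is_selected_first():
    X, y = _separable_data(noise_cols=6, seed=4)
    folds = make_stratified_folds(y, 5, seed=0)
    trace = forward_select(X, y, folds, max_features=3)
    assert trace.steps[0].feature_index == 0


def test_step_one_matches_exhaustive_single_feature_oracle():
    rng = np.random.default_rng(8)
    n, d = 200, 20
    y = _labels(n // 2, n // 2)
    X = rng.normal(size=(n, d))
    informative = [2, 7, 11, 13, 17]
    X[: n // 2, informative] += rng.uniform(0.8, 1.5, len(informative))
    folds = make_stratified_folds(y, 5, seed=5)
    trace = forward_select(X, y, folds, max_features=1)
    accs = [cv_evaluate([j], X, y, folds)[1].accuracy for j in range(d)]
    assert trace.steps[0].feature_index == int(np.argmax(accs))
    assert trace.steps[0].mean_metrics.accuracy == max(accs)


def test_trace_is_internally_consistent_and_fold_preserving():
    X, y = _separable_data(n=80, noise_cols=5, seed=6)
    folds = make_stratified_folds(y, 4, seed=6)
    trace = forward_select(X, y, folds, max_features=4)
    sel = trace.selected_features()
    assert len(set(sel)) == len(sel)  # no feature repeats
    digest = folds.digest()
    for t, step in enumerate(trace.steps, start=1):
        assert step.folds_digest == digest
        per_fold, mean = cv_evaluate(sel[:t], X, y, folds)
        assert mean == step.mean_metrics          # bitwise reproduction
        assert per_fold == step.per_fold_metrics


def test_restricted_pool_is_respected():
    X, y = _separable_data(noise_cols=6, seed=7)
    folds = make_stratified_folds(y, 4, seed=7)
    pool = [2, 3, 5]
    trace = forward_select(X, y, folds, max_features=2, candidate_pool=pool)
    assert set(trace.selected_features()) <= set(pool)
    with pytest.raises(ValueError):
        forward_select(X, y, folds, max_features=4, candidate_pool=pool)


# ---------------------------------------------------------------------------
# Best subset
# ---------------------------------------------------------------------------

def _fake_trace(accuracies):
    def ms(acc):
        return MetricSet(sensitivity=acc, specificity=acc, precision=acc,
                         fdr=100 - acc, accuracy=acc, f_measure=acc)
    steps = [SelectionStep(feature_index=i, per_fold_metrics=[ms(a)],
                           mean_metrics=ms(a), folds_digest="x")
             for i, a in enumerate(accuracies)]
    return SelectionTrace(steps=steps, criterion="accuracy")


def test_best_subset_monotone_trace_takes_everything():
    assert best_subset(_fake_trace([70, 80, 90])) == [0, 1, 2]


def test_best_subset_prefers_shortest_tie():
    assert best_subset(_fake_trace([80, 85, 85])) == [0, 1]


def test_best_subset_matches_exhaustive_prefix_scan():
    rng = np.random.default_rng(21)
    accs = rng.uniform(50, 95, 12).tolist()
    trace = _fake_trace(accs)
    best = max(range(len(accs)), key=lambda i: (accs[i], -i))
    assert best_subset(trace) == list(range(best + 1))
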