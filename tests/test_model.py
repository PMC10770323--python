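"""Tuning, Youden cutoff, metric battery, bootstrap, attribution."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from pe_immunodx.model import (TuningConfig, attribution_ranking, auroc,
                               bootstrap_evaluate, compute_metrics,
                               tune_and_train, youden_cutoff)


def brute_force_youden(scores, labels):
    best_j, best_t = -2.0, None
    for t in sorted(set(scores)):
        pred = scores >= t
        sen = (pred & (labels == 1)).sum() / (labels == 1).sum()
        spe = (~pred & (labels == 0)).sum() / (labels == 0).sum()
        j = sen + spe - 1
        if j > best_j + 1e-15:
            best_j, best_t = j, t
    return best_t, best_j


@given(st.lists(st.floats(0, 1, allow_nan=False, width=32), min_size=2,
                max_size=15),
       st.data())
def test_youden_equals_brute_force(scores, data):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(
        data.draw(st.lists(st.integers(0, 1), min_size=len(scores),
                           max_size=len(scores))))
    if labels.sum() in (0, len(labels)):
        labels[0], labels[-1] = 0, 1
    res = youden_cutoff(scores, labels)
    t_star, j_star = brute_force_youden(scores, labels)
    assert res.max_j == pytest.approx(j_star, abs=1e-12)
    assert res.optimal_cutoff == t_star


def test_youden_perfect_separation():
    scores = np.array([0.1, 0.2, 0.25, 0.6, 0.8, 0.9])
    labels = np.array([0, 0, 0, 1, 1, 1])
    res = youden_cutoff(scores, labels)
    assert res.max_j == 1.0
    assert res.optimal_cutoff == 0.6  # smallest positive-class score


def test_youden_identical_scores():
    res = youden_cutoff(np.full(8, 0.4), np.array([0, 1] * 4))
    assert res.max_j == 0.0


def test_metrics_arithmetic_oracle():
    """TP=3 FP=1 TN=5 FN=1 worked through by hand."""
    scores = np.array([0.9, 0.8, 0.7, 0.6,  # predicted positive
                       0.2, 0.1, 0.15, 0.05, 0.3, 0.25])
    labels = np.array([1, 1, 1, 0, 1, 0, 0, 0, 0, 0])
    m = compute_metrics(scores, labels, cutoff=0.5)
    assert (m.tp, m.fp, m.tn, m.fn) == (3, 1, 5, 1)
    assert m.sensitivity == pytest.approx(0.75)
    assert m.specificity == pytest.approx(5 / 6)
    assert m.ppv == pytest.approx(0.75)
    assert m.npv == pytest.approx(5 / 6)
    f1_pos = 2 * 3 / (2 * 3 + 1 + 1)
    f1_neg = 2 * 5 / (2 * 5 + 1 + 1)
    assert m.weighted_f1 == pytest.approx(0.4 * f1_pos + 0.6 * f1_neg)
    # sklearn cross-check of the weighted F1 convention
    from sklearn.metrics import f1_score

    assert m.weighted_f1 == pytest.approx(
        f1_score(labels, scores >= 0.5, average="weighted"))


def test_metrics_extremes():
    labels = np.array([0, 0, 1, 1])
    m = compute_metrics(labels.astype(float), labels, 0.5)
    assert m.auroc == 1.0
    assert m.sensitivity == m.specificity == m.ppv == m.npv == 1.0
    assert m.weighted_f1 == 1.0
    m2 = compute_metrics(1.0 - labels, labels, 0.5)
    assert m2.auroc == 0.0
    # cutoff 0 -> everything positive -> SEN 1; above max -> SPE 1
    assert compute_metrics(labels * 0.5, labels, 0.0).sensitivity == 1.0
    assert compute_metrics(labels * 0.5, labels, 0.9).specificity == 1.0


def test_auroc_matches_sklearn_and_is_monotone_invariant():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(0)
    scores = rng.random(60)
    scores[::7] = scores[0]  # inject ties
    labels = rng.integers(0, 2, 60)
    a = auroc(scores, labels)
    assert a == pytest.approx(roc_auc_score(labels, scores))
    assert auroc(np.exp(4 * scores), labels) == pytest.approx(a)


def test_tune_single_draw_and_separable_signal():
    rng = np.random.default_rng(1)
    y = np.r_[np.zeros(30, int), np.ones(30, int)]
    X = pd.DataFrame({
        "sig": y * 2.0 + rng.normal(size=60) * 0.05,
        "noise": rng.normal(size=60),
    })
    cfg = TuningConfig(n_search_iterations=1, seed=0)
    tm = tune_and_train(X, y, cfg)
    assert len(tm.cv_trace) == 1
    assert tm.cv_auroc >= 0.95  # linearly separable
    assert set(tm.best_params) == {"n_estimators", "max_depth",
                                   "max_features", "min_samples_leaf",
                                   "min_samples_split"}


def test_bootstrap_deterministic_and_consistent():
    rng = np.random.default_rng(2)
    n = 200
    y = rng.integers(0, 2, n)
    X = pd.DataFrame({"sig": y + rng.normal(size=n) * 0.6,
                      "noise": rng.normal(size=n)})
    from sklearn.ensemble import RandomForestClassifier

    clf = RandomForestClassifier(n_estimators=50, random_state=0).fit(X, y)
    b1 = bootstrap_evaluate(clf, X, y, 0.5, B=100, seed=9)
    b2 = bootstrap_evaluate(clf, X, y, 0.5, B=100, seed=9)
    assert b1.mean == b2.mean and b1.sd == b2.sd
    pos = int(np.where(clf.classes_ == 1)[0][0])
    point = auroc(clf.predict_proba(X)[:, pos], y)
    # bootstrap mean within 2*SD/sqrt(B) of the point estimate
    assert abs(b1.mean["auroc"] - point) <= 2 * b1.sd["auroc"] / np.sqrt(100)
    assert "±" in b1.formatted["auroc"]


def test_bootstrap_rejects_single_class():
    from sklearn.ensemble import RandomForestClassifier

    X = pd.DataFrame({"g": [0.0, 1.0, 0.2, 0.8]})
    y = np.array([0, 1, 0, 1])
    clf = RandomForestClassifier(n_estimators=5, random_state=0).fit(X, y)
    with pytest.raises(ValueError, match="single class"):
        bootstrap_evaluate(clf, X.iloc[:1], y[:1], 0.5)


def test_attribution_single_feature_ranks_first():
    rng = np.random.default_rng(3)
    n = 80
    y = rng.integers(0, 2, n)
    X = pd.DataFrame({"only": y + rng.normal(size=n) * 0.1})
    from sklearn.ensemble import RandomForestClassifier

    clf = RandomForestClassifier(n_estimators=20, random_state=0).fit(X, y)
    r = attribution_ranking(clf, X, top_k=20)
    assert r.table.index[0] == "only"
    assert r.top_k == 1  # fewer features than k


def test_attribution_unused_feature_zero():
    rng = np.random.default_rng(4)
    n = 100
    y = rng.integers(0, 2, n)
    X = pd.DataFrame({
        "sig": y * 2.0,
        "dead": np.zeros(n),  # constant: never split on
    })
    from sklearn.ensemble import RandomForestClassifier

    clf = RandomForestClassifier(n_estimators=10, random_state=0).fit(X, y)
    r = attribution_ranking(clf, X)
    assert r.table.loc["dead", "mean_abs_shap"] == 0.0
    assert r.table.loc["sig", "rank"] == 1
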