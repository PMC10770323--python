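"""Dual feature selection: mutual-information filter and Boruta.

A gene enters the diagnostic model only if it is identified by BOTH
methods on the training set.

The MI filter scores each gene by a k-nearest-neighbor (Ross-style) mutual
information estimate against the binary label (k = 3; negative estimates
clipped to 0).  Because the estimator's sampling noise under independence is
roughly symmetric around zero, a bare "estimate > 0" rule would retain about
half of all label-independent genes; the default selection rule therefore
requires the estimate to exceed the maximum estimate observed over a small
set of seeded label permutations (permutation-shadow threshold, 9
permutations ~ alpha 0.1).  The permissive > 0 rule remains available via
``threshold_mode="positive"``.

Boruta is implemented here in full: each iteration appends one permuted
"shadow" copy of every undecided feature, fits a class-weighted random
forest, and records a hit for features whose importance exceeds the maximum
shadow importance; a two-sided binomial test (p = 0.5) with Bonferroni
correction over the undecided features confirms or rejects them; after the
final iteration, remaining tentative features are resolved by comparing
their median importance with the median of the per-iteration shadow maxima.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import hashlib

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "FeatureScore", "BorutaParams", "BorutaState", "FeatureSelectionResult",
    "mi_filter", "boruta_select", "intersect_features",
    "EmptyIntersectionError",
]

log = logging.getLogger("pe_immunodx")


class EstimatorError(ValueError):
    pass


class EmptyIntersectionError(ValueError):
    pass


@dataclass
class FeatureScore:
    gene: str
    mi_estimate: float  # nats, clipped at 0
    selected_by_mi: bool


def _column_noise(x: np.ndarray, seed: int) -> np.ndarray:
    """Tiny tie-breaking jitter seeded from the column CONTENT, so that
    duplicated columns receive bit-identical noise (and hence identical MI
    estimates) regardless of their position in the matrix."""
    h = hashlib.blake2b(x.tobytes(), digest_size=8,
                        key=str(seed).encode()).digest()
    rng = np.random.default_rng(int.from_bytes(h, "big"))
    return 1e-10 * max(1.0, float(np.mean(np.abs(x)))) * rng.standard_normal(len(x))


def _knn_radius_sorted(arr: np.ndarray, k: int) -> np.ndarray:
    """Distance to the k-th nearest neighbor for each element of a SORTED
    1-D array, vectorized over the k+1 candidate windows."""
    n = len(arr)
    best = np.full(n, np.inf)
    idx = np.arange(n)
    for off in range(k + 1):
        lo = idx - off          # window [lo, lo + k] containing idx
        hi = lo + k
        valid = (lo >= 0) & (hi < n)
        d = np.full(n, np.inf)
        d[valid] = np.maximum(
            arr[idx[valid]] - arr[lo[valid]],
            arr[hi[valid]] - arr[idx[valid]],
        )
        best = np.minimum(best, d)
    return best


def _mi_cd_sorted(xs: np.ndarray, ys: np.ndarray, k: int) -> float:
    """Ross kNN estimator of I(X; Y) for continuous X (given SORTED values
    ``xs``) and a discrete label vector ``ys`` aligned with the sort order.

    Mirrors the standard convention: the search radius is the distance to
    the k-th same-class neighbor (shrunk by one ulp), ``m_i`` counts all
    points within that radius (self included), and the estimate is

        psi(n) + <psi(k_i)> - <psi(n_{y_i})> - <psi(m_i)>,   clipped at 0.
    """
    n = len(xs)
    radius = np.empty(n)
    k_all = np.empty(n)
    label_counts = np.empty(n)
    for label in np.unique(ys):
        pos = np.where(ys == label)[0]
        cnt = len(pos)
        label_counts[pos] = cnt
        k_eff = min(k, cnt - 1)
        k_all[pos] = k_eff
        radius[pos] = np.nextafter(_knn_radius_sorted(xs[pos], k_eff), 0)
    # neighborhood counts over ALL points: |x_j - x_i| <= radius_i.
    # searchsorted on xs +/- radius can be off by one from rounding of the
    # sum, so the window boundaries are corrected by explicit distance
    # checks afterwards.
    idx = np.arange(n)
    lo = np.searchsorted(xs, xs - radius, side="left")
    hi = np.searchsorted(xs, xs + radius, side="right") - 1
    for _ in range(3):
        bad = (lo < idx) & (xs[idx] - xs[np.minimum(lo, n - 1)] > radius)
        lo = np.where(bad, lo + 1, lo)
        bad = (hi > idx) & (xs[np.maximum(hi, 0)] - xs[idx] > radius)
        hi = np.where(bad, hi - 1, hi)
    m_all = hi - lo + 1
    mi = (
        digamma(n)
        + np.mean(digamma(k_all))
        - np.mean(digamma(label_counts))
        - np.mean(digamma(m_all))
    )
    return max(0.0, float(mi))


def mi_scores(X: np.ndarray, label_sets, k: int, seed: int) -> np.ndarray:
    """MI estimates for every column of ``X`` against each label vector in
    ``label_sets`` (the column sort is shared across label vectors).

    Returns an array of shape (len(label_sets), n_columns).
    """
    X = np.asarray(X, dtype=np.float64)
    n, p = X.shape
    out = np.zeros((len(label_sets), p))
    for j in range(p):
        x = X[:, j]
        sd = x.std()
        if sd == 0:
            continue  # constant column carries no information
        x = x / sd
        x = x + _column_noise(x, seed)
        order = np.argsort(x, kind="mergesort")
        xs = x[order]
        for i, y in enumerate(label_sets):
            out[i, j] = _mi_cd_sorted(xs, np.asarray(y)[order], k)
    return out


def mi_filter(train_X: pd.DataFrame, y, k_neighbors: int = 3,
              threshold_mode: str = "permutation", n_permutations: int = 9,
              seed: int = 0) -> list:
    """Score every gene and flag the MI-selected set.

    Returns a list of :class:`FeatureScore`, one per gene in column order.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < k_neighbors + 1:
        raise EstimatorError(
            f"each class needs more than k_neighbors={k_neighbors} samples"
        )
    X = np.asarray(train_X, dtype=float)
    if threshold_mode == "positive":
        mi = mi_scores(X, [y], k_neighbors, seed)[0]
        selected = mi > 0
    elif threshold_mode == "permutation":
        rng = np.random.default_rng(seed)
        label_sets = [y] + [rng.permutation(y) for _ in range(n_permutations)]
        all_mi = mi_scores(X, label_sets, k_neighbors, seed)
        mi = all_mi[0]
        shadow_max = all_mi[1:].max(axis=0)
        selected = (mi > 0) & (mi > shadow_max)
    else:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    return [
        FeatureScore(gene=g, mi_estimate=float(mi[j]), selected_by_mi=bool(selected[j]))
        for j, g in enumerate(train_X.columns)
    ]


@dataclass
class BorutaParams:
    max_iter: int = 100
    alpha: float = 0.05
    n_estimators: int = 100
    max_depth: int | None = 5
    seed: int = 0
    importance: str = "impurity"  # or "permutation"


@dataclass
class BorutaState:
    gene: str
    hit_count: int
    n_iterations: int
    decision: str  # confirmed | rejected | tentative
    resolved_by_median: bool = False


@dataclass
class FeatureSelectionResult:
    mi_set: list
    boruta_set: list
    intersection: list
    scores: list = field(default_factory=list)        # FeatureScore
    boruta_states: list = field(default_factory=list)  # BorutaState


def _importances(forest, X, y, mode, rng):
    if mode == "impurity":
        return forest.feature_importances_
    from sklearn.inspection import permutation_importance

    r = permutation_importance(
        forest, X, y, n_repeats=3,
        random_state=int(rng.integers(2**31)),
    )
    return r.importances_mean


def boruta_select(train_X: pd.DataFrame, y, params: BorutaParams | None = None):
    """Run Boruta; returns ``(states, boruta_set)``.

    ``states`` carries the per-gene hit counts and final decisions;
    ``boruta_set`` lists confirmed genes in the training column order.
    """
    params = params or BorutaParams()
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 5:
        raise EstimatorError("Boruta needs at least 5 samples per class")
    genes = list(train_X.columns)
    X = np.asarray(train_X, dtype=float)
    n, p = X.shape
    rng = np.random.default_rng(params.seed)

    decision = np.full(p, "tentative", dtype=object)
    constant = X.std(axis=0) == 0
    if constant.any():
        decision[constant] = "rejected"
        log.warning("Boruta auto-rejected %d constant feature(s)", int(constant.sum()))
    hits = np.zeros(p, dtype=int)
    n_tested = np.zeros(p, dtype=int)
    imp_history: list = [[] for _ in range(p)]
    shadow_max_history: list = []
    resolved_by_median = np.zeros(p, dtype=bool)

    undecided = np.where(decision == "tentative")[0]
    for _ in range(params.max_iter):
        if undecided.size == 0:
            break
        shadows = X[:, undecided].copy()
        for j in range(shadows.shape[1]):
            shadows[:, j] = rng.permutation(shadows[:, j])
        design = np.hstack([X[:, undecided], shadows])
        forest = RandomForestClassifier(
            n_estimators=params.n_estimators,
            max_depth=params.max_depth,
            class_weight="balanced",
            random_state=int(rng.integers(2**31)),
            n_jobs=1,
        ).fit(design, y)
        imp = _importances(forest, design, y, params.importance, rng)
        real_imp = imp[: undecided.size]
        shadow_top = float(imp[undecided.size :].max())
        shadow_max_history.append(shadow_top)
        for pos, j in enumerate(undecided):
            imp_history[j].append(float(real_imp[pos]))
        hits[undecided] += real_imp > shadow_top
        n_tested[undecided] += 1

        # two-sided binomial test, Bonferroni over currently undecided
        m = undecided.size
        for j in undecided:
            h, t = hits[j], n_tested[j]
            p_hi = stats.binom.sf(h - 1, t, 0.5)
            p_lo = stats.binom.cdf(h, t, 0.5)
            p_two = min(1.0, 2.0 * min(p_hi, p_lo))
            if p_two < params.alpha / m:
                decision[j] = "confirmed" if h > t / 2 else "rejected"
        undecided = np.where(decision == "tentative")[0]

    if shadow_max_history:
        shadow_median = float(np.median(shadow_max_history))
        for j in np.where(decision == "tentative")[0]:
            if imp_history[j]:
                med = float(np.median(imp_history[j]))
                decision[j] = "confirmed" if med > shadow_median else "rejected"
                resolved_by_median[j] = True

    states = [
        BorutaState(
            gene=genes[j], hit_count=int(hits[j]),
            n_iterations=int(n_tested[j]), decision=str(decision[j]),
            resolved_by_median=bool(resolved_by_median[j]),
        )
        for j in range(p)
    ]
    boruta_set = [genes[j] for j in range(p) if decision[j] == "confirmed"]
    return states, boruta_set


def intersect_features(mi_set, boruta_set, gene_order=None,
                       scores=None, boruta_states=None) -> FeatureSelectionResult:
    """Intersect the two selected sets in stable gene order.

    An empty intersection is a hard error: the two selectors disagree
    entirely and the model would have no features.
    """
    order = list(gene_order) if gene_order is not None else list(mi_set)
    mi = set(mi_set)
    bo = set(boruta_set)
    inter = [g for g in order if g in mi and g in bo]
    if not inter:
        raise EmptyIntersectionError(
            "MI and Boruta selections are disjoint; relax selection "
            "parameters (e.g. threshold_mode='positive' or larger max_iter)"
        )
    return FeatureSelectionResult(
        mi_set=[g for g in order if g in mi],
        boruta_set=[g for g in order if g in bo],
        intersection=inter,
        scores=scores or [],
        boruta_states=boruta_states or [],
    )
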