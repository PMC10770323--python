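"""Class-weighted random-forest diagnostics.

Covers hyperparameter tuning (random search scored by mean AUROC over
stratified 5-fold CV), the Youden-J optimal cutoff, the point metric
battery (AUROC, sensitivity, specificity, PPV, NPV, weighted F1, confusion
matrix), bootstrap evaluation of the independent test set, and global gene
ranking by mean absolute Shapley attribution.

The positive class is PE throughout; class weights are inverse class
frequencies ("balanced") because positives are the minority.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .treeshap import forest_shap_values

__all__ = [
    "TuningConfig", "TunedModel", "ThresholdSearchResult", "MetricsReport",
    "BootstrapSummary", "AttributionRanking", "tune_and_train",
    "youden_cutoff", "compute_metrics", "bootstrap_evaluate",
    "attribution_ranking", "auroc",
]

log = logging.getLogger("pe_immunodx")


class StratificationError(ValueError):
    pass


@dataclass
class TuningConfig:
    n_search_iterations: int = 100
    cv_folds: int = 5
    cv_repeats: int = 1
    seed: int = 0
    trees_range: tuple = (100, 1000)
    max_depth_choices: tuple = (None, *range(3, 21))
    max_features_choices: tuple = ("sqrt", "log2",
                                   *(round(0.1 * i, 1) for i in range(1, 11)))
    min_samples_leaf_range: tuple = (1, 10)
    min_samples_split_range: tuple = (2, 20)

    def __post_init__(self):
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.n_search_iterations < 1:
            raise ValueError("n_search_iterations must be >= 1")

    def draw(self, rng: np.random.Generator) -> dict:
        return {
            "n_estimators": int(rng.integers(self.trees_range[0],
                                             self.trees_range[1] + 1)),
            "max_depth": self.max_depth_choices[
                rng.integers(len(self.max_depth_choices))],
            "max_features": self.max_features_choices[
                rng.integers(len(self.max_features_choices))],
            "min_samples_leaf": int(rng.integers(
                self.min_samples_leaf_range[0],
                self.min_samples_leaf_range[1] + 1)),
            "min_samples_split": int(rng.integers(
                self.min_samples_split_range[0],
                self.min_samples_split_range[1] + 1)),
        }


@dataclass
class TunedModel:
    model: RandomForestClassifier
    best_params: dict
    cv_auroc: float
    cv_trace: list                 # mean CV AUROC per search draw
    oof_scores: np.ndarray         # out-of-fold scores of the best draw
    oof_labels: np.ndarray


@dataclass
class ThresholdSearchResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    j_statistic: np.ndarray
    optimal_cutoff: float
    max_j: float


@dataclass
class MetricsReport:
    auroc: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    weighted_f1: float
    tp: int
    fp: int
    tn: int
    fn: int
    cutoff: float
    undefined: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "auroc": self.auroc, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "ppv": self.ppv,
            "npv": self.npv, "weighted_f1": self.weighted_f1,
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "cutoff": self.cutoff, "undefined": self.undefined,
        }


@dataclass
class BootstrapSummary:
    n_resamples: int
    mean: dict
    sd: dict
    formatted: dict
    n_redrawn: int


@dataclass
class AttributionRanking:
    table: pd.DataFrame  # gene, mean_abs_shap, rank, top_k flag
    base_value: float
    top_k: int

    @property
    def top_genes(self) -> list:
        return list(self.table.index[self.table["in_top_k"]])


def auroc(scores, labels) -> float:
    """AUROC by the rank (Mann-Whitney) statistic with ties averaged."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def _score(model, X) -> np.ndarray:
    pos = int(np.where(np.asarray(model.classes_) == 1)[0][0])
    return model.predict_proba(np.asarray(X, dtype=float))[:, pos]


def tune_and_train(train_X, train_y, cfg: TuningConfig | None = None) -> TunedModel:
    """Random search over the RF hyperparameter space, scored by mean AUROC
    over stratified ``cv_folds``-fold CV; the best draw is refit on the full
    training set.  Out-of-fold scores of the winning draw are retained (they
    are what the Youden cutoff is derived from)."""
    cfg = cfg or TuningConfig()
    X = np.asarray(train_X, dtype=float)
    y = np.asarray(train_y)
    _, counts = np.unique(y, return_counts=True)
    if len(counts) < 2 or counts.min() < cfg.cv_folds:
        raise StratificationError(
            f"every fold needs both classes: minority class has "
            f"{counts.min() if len(counts) > 1 else 0} members for "
            f"{cfg.cv_folds} folds"
        )
    rng = np.random.default_rng(cfg.seed)
    best = None
    trace = []
    for it in range(cfg.n_search_iterations):
        params = cfg.draw(rng)
        fold_aucs = []
        oof = np.full(len(y), np.nan)
        for rep in range(cfg.cv_repeats):
            skf = StratifiedKFold(
                n_splits=cfg.cv_folds, shuffle=True,
                random_state=int(rng.integers(2**31)),
            )
            for tr, va in skf.split(X, y):
                clf = RandomForestClassifier(
                    class_weight="balanced", n_jobs=1,
                    random_state=int(rng.integers(2**31)), **params,
                ).fit(X[tr], y[tr])
                s = _score(clf, X[va])
                if rep == 0:
                    oof[va] = s
                fold_aucs.append(auroc(s, y[va]))
        mean_auc = float(np.mean(fold_aucs))
        trace.append(mean_auc)
        if best is None or mean_auc > best[0]:
            best = (mean_auc, params, oof)
    cv_auroc, best_params, oof = best
    final = RandomForestClassifier(
        class_weight="balanced", n_jobs=1,
        random_state=int(rng.integers(2**31)), **best_params,
    ).fit(X, y)
    return TunedModel(
        model=final, best_params=best_params, cv_auroc=cv_auroc,
        cv_trace=trace, oof_scores=oof, oof_labels=y.copy(),
    )


def youden_cutoff(scores, labels) -> ThresholdSearchResult:
    """Maximize J = sensitivity + specificity - 1 over every unique score,
    predicting positive at ``score >= t``; ties resolve to the smallest
    threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("Youden's J is undefined with a single class")
    thresholds = np.unique(scores)
    sens = np.empty(len(thresholds))
    spec = np.empty(len(thresholds))
    for i, t in enumerate(thresholds):
        pred = scores >= t
        sens[i] = (pred & (labels == 1)).sum() / n_pos
        spec[i] = (~pred & (labels == 0)).sum() / n_neg
    j = sens + spec - 1.0
    # smallest threshold among ties (thresholds are sorted ascending)
    best = int(np.flatnonzero(j >= j.max() - 1e-15)[0])
    return ThresholdSearchResult(
        thresholds=thresholds, sensitivity=sens, specificity=spec,
        j_statistic=j, optimal_cutoff=float(thresholds[best]),
        max_j=float(j[best]),
    )


def _safe_div(num: float, den: float, name: str, undefined: list) -> float:
    if den == 0:
        undefined.append(name)
        return float("nan")
    return num / den


def compute_metrics(scores, labels, cutoff: float) -> MetricsReport:
    """Metric battery at a fixed cutoff (``score >= cutoff`` = predict PE)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    pred = scores >= cutoff
    tp = int((pred & (labels == 1)).sum())
    fp = int((pred & (labels == 0)).sum())
    tn = int((~pred & (labels == 0)).sum())
    fn = int((~pred & (labels == 1)).sum())
    undefined: list = []
    sen = _safe_div(tp, tp + fn, "sensitivity", undefined)
    spe = _safe_div(tn, tn + fp, "specificity", undefined)
    ppv = _safe_div(tp, tp + fp, "ppv", undefined)
    npv = _safe_div(tn, tn + fn, "npv", undefined)
    # weighted F1 over both classes (class sizes as weights)
    n = len(labels)
    f1s = {}
    for cls, (tpc, fpc, fnc) in {1: (tp, fp, fn), 0: (tn, fn, fp)}.items():
        denom = 2 * tpc + fpc + fnc
        f1s[cls] = 2 * tpc / denom if denom > 0 else 0.0
    n_pos = int((labels == 1).sum())
    wf1 = (n_pos * f1s[1] + (n - n_pos) * f1s[0]) / n if n else float("nan")
    return MetricsReport(
        auroc=auroc(scores, labels), sensitivity=sen, specificity=spe,
        ppv=ppv, npv=npv, weighted_f1=wf1, tp=tp, fp=fp, tn=tn, fn=fn,
        cutoff=float(cutoff), undefined=undefined,
    )


_BOOT_METRICS = ("auroc", "sensitivity", "specificity", "ppv", "npv",
                 "weighted_f1")


def bootstrap_evaluate(model, test_X, test_y, cutoff: float, B: int = 100,
                       seed: int = 0) -> BootstrapSummary:
    """B resamples of the test set (same size, with replacement), each scored
    at the FIXED training-phase cutoff; single-class resamples are redrawn."""
    y = np.asarray(test_y)
    if len(y) == 0:
        raise ValueError("test set is empty")
    if len(np.unique(y)) < 2:
        raise ValueError(
            "test set has a single class; bootstrap metrics are degenerate"
        )
    scores = _score(model, test_X)
    rng = np.random.default_rng(seed)
    rows = []
    n_redrawn = 0
    for _ in range(B):
        while True:
            idx = rng.integers(0, len(y), len(y))
            if len(np.unique(y[idx])) == 2:
                break
            n_redrawn += 1
        rep = compute_metrics(scores[idx], y[idx], cutoff)
        rows.append({m: getattr(rep, m) for m in _BOOT_METRICS})
    if n_redrawn:
        log.info("bootstrap: redrew %d single-class resample(s)", n_redrawn)
    df = pd.DataFrame(rows)
    mean = df.mean().to_dict()
    sd = df.std(ddof=1).to_dict()
    formatted = {m: f"{mean[m]:.3f} ± {sd[m]:.3f}" for m in _BOOT_METRICS}
    return BootstrapSummary(
        n_resamples=B, mean=mean, sd=sd, formatted=formatted,
        n_redrawn=n_redrawn,
    )


def attribution_ranking(model, X: pd.DataFrame, top_k: int = 20) -> AttributionRanking:
    """Rank genes by mean absolute Shapley attribution across samples.

    Per-sample additivity (attributions + base = predicted PE probability)
    is asserted to 1e-6 inside the Shapley computation.
    """
    phi, base = forest_shap_values(model, np.asarray(X, dtype=float))
    mean_abs = np.abs(phi).mean(axis=0)
    table = pd.DataFrame(
        {"mean_abs_shap": mean_abs},
        index=pd.Index(X.columns, name="gene"),
    )
    # descending attribution, ties by gene name
    order = sorted(table.index, key=lambda g: (-table.at[g, "mean_abs_shap"], g))
    table = table.loc[order]
    table["rank"] = np.arange(1, len(table) + 1)
    k = min(top_k, len(table))
    table["in_top_k"] = table["rank"] <= k
    return AttributionRanking(table=table, base_value=base, top_k=k)
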