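"""Stratified splitting and train-fitted standardization.

The split is stratified by pseudo-cell label in a 7:3 ratio (per class,
round half up).  Standardization statistics (per-gene mean and population
SD) are fitted on the training set only and applied unchanged to the test
set — no test statistic ever influences the transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pseudocell import PseudoCellDataset

__all__ = ["SplitParams", "ScalerStats", "stratified_split", "fit_scaler",
           "apply_scaler", "SplitError"]


class SplitError(ValueError):
    pass


class SchemaError(ValueError):
    pass


@dataclass
class SplitParams:
    train_fraction: float = 0.7
    seed: int = 0
    group_by_patient: bool = False

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass
class ScalerStats:
    mean: pd.Series
    std: pd.Series  # population SD (ddof 0)

    @property
    def zero_variance_genes(self) -> list:
        return list(self.std.index[self.std.to_numpy() == 0.0])


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def stratified_split(d: PseudoCellDataset, p: SplitParams):
    """Split pseudo-cells into train/test, preserving the class ratio.

    With ``group_by_patient`` the unit of assignment is the patient (all of
    a patient's pseudo-cells travel together; stratification is then by
    patient group), a leakage-free alternative to the default per-pseudo-cell
    stratification.
    """
    rng = np.random.default_rng(p.seed)
    labels = d.labels
    train_idx, test_idx = [], []
    if p.group_by_patient:
        pt_label = d.labels.groupby(d.patient_ids).first()
        for cls in (0, 1):
            pts = sorted(pt_label.index[pt_label == cls])
            if len(pts) < 2:
                raise SplitError(f"class {cls} has fewer than 2 patients")
            order = rng.permutation(len(pts))
            n_train = _round_half_up(p.train_fraction * len(pts))
            chosen = {pts[i] for i in order[:n_train]}
            mask = d.patient_ids.isin(chosen)
            train_idx.extend(d.features.index[mask & (labels == cls)])
            test_idx.extend(d.features.index[(~mask) & (labels == cls)])
    else:
        for cls in (0, 1):
            members = list(labels.index[labels == cls])
            if len(members) < 2:
                raise SplitError(f"class {cls} has fewer than 2 members")
            order = rng.permutation(len(members))
            n_train = _round_half_up(p.train_fraction * len(members))
            train_idx.extend(members[i] for i in order[:n_train])
            test_idx.extend(members[i] for i in order[n_train:])
    return d.take(pd.Index(train_idx)), d.take(pd.Index(test_idx))


def fit_scaler(train: PseudoCellDataset | pd.DataFrame) -> ScalerStats:
    X = train.features if isinstance(train, PseudoCellDataset) else train
    if len(X) == 0:
        raise ValueError("cannot fit a scaler on an empty training set")
    return ScalerStats(mean=X.mean(axis=0), std=X.std(axis=0, ddof=0))


def apply_scaler(s: ScalerStats, data: PseudoCellDataset | pd.DataFrame) -> pd.DataFrame:
    """``z = (x - mu) / sigma`` with train statistics; sigma = 0 genes map to 0."""
    X = data.features if isinstance(data, PseudoCellDataset) else data
    if list(X.columns) != list(s.mean.index):
        raise SchemaError("feature set does not match the fitted scaler")
    std = s.std.replace(0.0, np.inf)  # zero-variance genes -> exactly 0
    return (X - s.mean) / std
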