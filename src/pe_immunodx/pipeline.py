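"""End-to-end orchestration of the cell-type-specific diagnostic pipeline.

Stage order: QC (cells, then genes) -> depth normalization + log transform
-> highly-variable genes -> per cell type: pseudo-cells -> stratified 7:3
split -> train-fitted standardization -> dual feature selection (MI &
Boruta) -> random-search tuning of the class-weighted random forest ->
Youden cutoff on the winning draw's out-of-fold scores -> test metrics ->
bootstrap -> Shapley gene ranking.  One global seed makes every stage
reproducible; per-cell-type child seeds are derived by stable hashing of
the cell-type name so adding a target never perturbs the others.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dataset as ds
from . import features as fs
from . import model as mdl
from . import pseudocell as pc
from . import qc

log = logging.getLogger("pe_immunodx")

__all__ = ["PipelineConfig", "CellTypeReport", "run_pipeline",
           "child_seed", "run_cell_type"]

#: Named unions of annotated cell types: one classifier per entry.
DEFAULT_TARGETS = {
    "total_mono": ("VCAN+ Mono", "Classical Mono",
                   "IFN- Non-classical Mono", "IFN+ Non-classical Mono"),
    "cd4_tn2": ("CD4+ Tn 2",),
    "cd8_tn2": ("CD8+ Tn 2",),
    "treg": ("Treg",),
}


@dataclass
class PipelineConfig:
    seed: int = 0
    cell_type_targets: dict = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_TARGETS.items()}
    )
    qc_params: qc.QCParams = field(default_factory=qc.QCParams)
    norm_params: qc.NormalizationParams = field(default_factory=qc.NormalizationParams)
    pseudocell_k: int = 5
    train_fraction: float = 0.7
    group_by_patient: bool = False
    feature_selection: str = "both"  # "both" or "none"
    mi_threshold_mode: str = "permutation"
    boruta_params: fs.BorutaParams = field(default_factory=fs.BorutaParams)
    tuning: mdl.TuningConfig = field(default_factory=mdl.TuningConfig)
    bootstrap_b: int = 100
    top_k: int = 20

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        simple = {
            "seed", "cell_type_targets", "pseudocell_k", "train_fraction",
            "group_by_patient", "feature_selection", "mi_threshold_mode",
            "bootstrap_b", "top_k",
        }
        for key, val in raw.items():
            if key in simple:
                kwargs[key] = val
            elif key == "qc_params":
                kwargs["qc_params"] = qc.QCParams(**val)
            elif key == "norm_params":
                kwargs["norm_params"] = qc.NormalizationParams(**val)
            elif key == "boruta_params":
                kwargs["boruta_params"] = fs.BorutaParams(**val)
            elif key == "tuning":
                kwargs["tuning"] = mdl.TuningConfig(**val)
            else:
                raise ValueError(f"unknown pipeline config key {key!r}")
        return cls(**kwargs)


@dataclass
class CellTypeReport:
    name: str
    seed: int
    selected_genes: list
    best_params: dict
    cv_auroc: float
    cutoff: float
    train_metrics: mdl.MetricsReport
    test_metrics: mdl.MetricsReport
    bootstrap: mdl.BootstrapSummary
    attribution_test: mdl.AttributionRanking
    attribution_train: mdl.AttributionRanking
    n_train: int
    n_test: int

    def metrics_dict(self) -> dict:
        return {
            "cell_type": self.name,
            "seed": self.seed,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "n_selected_genes": len(self.selected_genes),
            "best_params": {k: (None if v is None else v)
                            for k, v in self.best_params.items()},
            "cv_auroc": self.cv_auroc,
            "cutoff": self.cutoff,
            "train": self.train_metrics.as_dict(),
            "test": self.test_metrics.as_dict(),
            "bootstrap_mean": self.bootstrap.mean,
            "bootstrap_sd": self.bootstrap.sd,
            "bootstrap_formatted": self.bootstrap.formatted,
        }


def child_seed(seed: int, name: str) -> int:
    """Stable per-cell-type seed below 2**31."""
    h = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_cell_type(adata, name: str, cell_types, cfg: PipelineConfig,
                  hvgs) -> CellTypeReport:
    seed = child_seed(cfg.seed, name)
    pcs = pc.build_pseudocells(
        adata, pc.PseudoCellParams(cell_types=tuple(cell_types),
                                   k=cfg.pseudocell_k, seed=seed),
        genes=hvgs,
    )
    log.info("[%s] %d pseudo-cells (%s)", name, len(pcs),
             pc.summarize_dataset(pcs)["fraction_positive"])
    train, test = ds.stratified_split(
        pcs, ds.SplitParams(train_fraction=cfg.train_fraction, seed=seed,
                            group_by_patient=cfg.group_by_patient),
    )
    scaler = ds.fit_scaler(train)
    Xtr = ds.apply_scaler(scaler, train)
    Xte = ds.apply_scaler(scaler, test)
    ytr = train.labels.to_numpy()
    yte = test.labels.to_numpy()

    if cfg.feature_selection == "both":
        scores = fs.mi_filter(Xtr, ytr, threshold_mode=cfg.mi_threshold_mode,
                              seed=seed)
        mi_set = [s.gene for s in scores if s.selected_by_mi]
        bp = dataclasses.replace(cfg.boruta_params, seed=seed)
        states, boruta_set = fs.boruta_select(Xtr, ytr, bp)
        sel = fs.intersect_features(
            mi_set, boruta_set, gene_order=list(Xtr.columns),
            scores=scores, boruta_states=states,
        )
        genes = sel.intersection
        log.info("[%s] MI kept %d, Boruta %d, intersection %d", name,
                 len(mi_set), len(boruta_set), len(genes))
        Xtr, Xte = Xtr[genes], Xte[genes]
    elif cfg.feature_selection == "none":
        genes = list(Xtr.columns)
    else:
        raise ValueError(f"unknown feature_selection {cfg.feature_selection!r}")

    tuning = dataclasses.replace(cfg.tuning, seed=seed)
    tuned = mdl.tune_and_train(Xtr, ytr, tuning)
    cut = mdl.youden_cutoff(tuned.oof_scores, tuned.oof_labels)
    pos = int(np.where(np.asarray(tuned.model.classes_) == 1)[0][0])
    tr_scores = tuned.model.predict_proba(np.asarray(Xtr))[:, pos]
    te_scores = tuned.model.predict_proba(np.asarray(Xte))[:, pos]
    train_metrics = mdl.compute_metrics(tr_scores, ytr, cut.optimal_cutoff)
    test_metrics = mdl.compute_metrics(te_scores, yte, cut.optimal_cutoff)
    boot = mdl.bootstrap_evaluate(
        tuned.model, Xte, yte, cut.optimal_cutoff, B=cfg.bootstrap_b,
        seed=seed,
    )
    attr_test = mdl.attribution_ranking(tuned.model, Xte, top_k=cfg.top_k)
    attr_train = mdl.attribution_ranking(tuned.model, Xtr, top_k=cfg.top_k)
    return CellTypeReport(
        name=name, seed=seed, selected_genes=genes,
        best_params=tuned.best_params, cv_auroc=tuned.cv_auroc,
        cutoff=cut.optimal_cutoff, train_metrics=train_metrics,
        test_metrics=test_metrics, bootstrap=boot,
        attribution_test=attr_test, attribution_train=attr_train,
        n_train=len(ytr), n_test=len(yte),
    )


def run_pipeline(adata, cfg: PipelineConfig, outdir=None) -> dict:
    """Run QC, normalization, HVG selection and one diagnostic model per
    configured cell-type target.  Returns {target name: CellTypeReport};
    when ``outdir`` is given, one report directory is written per target.
    """
    filtered, qc_report = qc.filter_cells(adata, cfg.qc_params)
    filtered = qc.filter_genes(filtered, cfg.qc_params)
    log.info("QC: %d/%d cells kept, %d genes kept",
             qc_report["n_kept"], qc_report["n_input"], filtered.n_vars)
    normed = qc.normalize_log(filtered, cfg.norm_params)
    hvgs = qc.select_hvgs(normed, cfg.norm_params)

    reports = {}
    for name, cell_types in cfg.cell_type_targets.items():
        rep = run_cell_type(normed, name, cell_types, cfg, hvgs)
        reports[name] = rep
        if outdir is not None:
            _write_report(Path(outdir) / name, rep, qc_report, cfg)
    return reports


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(type(o).__name__)


def _write_report(d: Path, rep: CellTypeReport, qc_report: dict,
                  cfg: PipelineConfig) -> None:
    d.mkdir(parents=True, exist_ok=True)
    (d / "metrics.json").write_text(
        json.dumps(rep.metrics_dict(), indent=2, sort_keys=True,
                   default=_json_default) + "\n"
    )
    (d / "features.txt").write_text("\n".join(rep.selected_genes) + "\n")
    rep.attribution_test.table.head(rep.attribution_test.top_k).to_csv(
        d / "top_genes_test.csv"
    )
    rep.attribution_train.table.head(rep.attribution_train.top_k).to_csv(
        d / "top_genes_train.csv"
    )
    manifest = {
        "seed": rep.seed,
        "global_seed": cfg.seed,
        "qc": {k: v for k, v in qc_report.items() if k != "dropped_barcodes"},
        "pseudocell_k": cfg.pseudocell_k,
        "train_fraction": cfg.train_fraction,
        "feature_selection": cfg.feature_selection,
        "bootstrap_b": cfg.bootstrap_b,
    }
    (d / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
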