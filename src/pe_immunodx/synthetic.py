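"""Synthetic cohort and single-cell count generator.

Emulates the statistical structure the downstream diagnostic pipeline
assumes: a small case/control pregnancy cohort (8 preeclampsia (PE) and
15 normal-pregnancy (NP) subjects by default), per-patient negative-binomial
expression counts with log-normal gene baselines, per-cell library-size
variation, a scalar per-patient random effect, planted group-differential
genes per cell type, and a configurable fraction of QC-violating cells
(high mitochondrial or hemoglobin content, too few detected genes).

The generator also emits a :class:`SyntheticTruth` record (which genes carry
effects, which cells violate QC).  The truth record exists for validation
only and is never consumed by the analysis pipeline itself.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "HEMOGLOBIN_GENES",
    "MITO_GENES",
    "generate_cohort",
    "generate_counts",
    "generate_dataset",
]

#: The ten hemoglobin genes screened by the cell QC filter.
HEMOGLOBIN_GENES = (
    "HBA1", "HBA2", "HBB", "HBD", "HBE1",
    "HBG1", "HBG2", "HBM", "HBQ1", "HBZ",
)

#: Mitochondrially encoded genes included in the synthetic panel.
MITO_GENES = (
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP8", "MT-ATP6",
    "MT-CO3", "MT-ND3", "MT-ND4L", "MT-ND4", "MT-ND5", "MT-ND6", "MT-CYB",
)


class ConfigurationError(ValueError):
    """Raised when a :class:`SyntheticConfig` field is invalid."""


def _default_covariate_params() -> dict:
    # Group means/SDs and binary rates chosen to resemble a third-trimester
    # PE/NP clinical table: PE carries higher blood pressure and BMI, lower
    # gestational age at delivery and fetal weight.
    return {
        "maternal_age": {"NP": (29.0, 2.2), "PE": (29.0, 2.6)},
        "bmi": {"NP": (25.5, 2.2), "PE": (27.7, 1.8)},
        "sbp": {"NP": (114.0, 10.0), "PE": (125.8, 20.2)},
        "dbp": {"NP": (68.1, 7.0), "PE": (79.6, 13.7)},
        "gestational_age_sampling": {"NP": (35.0, 2.4), "PE": (37.2, 1.6)},
        "gestational_age_delivery": {"NP": (39.6, 1.3), "PE": (37.3, 1.4)},
        "fetal_weight": {"NP": (3221.3, 312.4), "PE": (2730.0, 682.1)},
        "cesarean": {"NP": 1 / 15, "PE": 4 / 8},
        "preterm": {"NP": 0.02, "PE": 2 / 8},
        "fetal_sex": {"NP": 8 / 15, "PE": 4 / 8},
    }


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort and count generator.

    ``de_genes_per_type`` maps a cell type to ``[(gene, log2_effect), ...]``;
    the listed genes have their negative-binomial mean multiplied by
    ``2**log2_effect`` in PE cells of that type.
    """

    n_pe: int = 8
    n_np: int = 15
    cells_per_patient: int = 300
    n_genes: int = 2000
    cell_types: tuple = ("mono",)
    cell_type_proportions: tuple = (1.0,)
    de_genes_per_type: dict = field(default_factory=dict)
    nb_dispersion: float = 2.0
    baseline_logmean_mu: float = -1.0
    baseline_logmean_sigma: float = 1.3
    libsize_sigma: float = 0.3
    patient_effect_sigma: float = 0.15
    qc_violator_fraction: float = 0.05
    #: planted differential genes emulate diagnostic markers, which are
    #: expressed genes; their baselines are floored at this panel quantile
    de_min_baseline_quantile: float = 0.5
    covariate_params: dict = field(default_factory=_default_covariate_params)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_pe", "n_np", "cells_per_patient", "n_genes"):
            if int(getattr(self, name)) <= 0:
                raise ConfigurationError(f"{name} must be a positive count")
        if self.n_genes < 100:
            raise ConfigurationError(
                "n_genes must be >= 100 so the annotated gene categories "
                "(mito, hemoglobin, ribo, ...) can be represented"
            )
        if len(self.cell_types) != len(self.cell_type_proportions):
            raise ConfigurationError(
                "cell_types and cell_type_proportions must align"
            )
        if abs(sum(self.cell_type_proportions) - 1.0) > 1e-8:
            raise ConfigurationError("cell_type_proportions must sum to 1")
        if not 0.0 <= self.qc_violator_fraction <= 1.0:
            raise ConfigurationError("qc_violator_fraction must lie in [0, 1]")
        for name in ("nb_dispersion", "libsize_sigma", "patient_effect_sigma"):
            if getattr(self, name) < 0 or (
                name == "nb_dispersion" and getattr(self, name) <= 0
            ):
                raise ConfigurationError(f"{name} must be positive")
        panel = set(_gene_panel(self.n_genes)[0])
        for ctype, effects in self.de_genes_per_type.items():
            if ctype not in self.cell_types:
                raise ConfigurationError(
                    f"de_genes_per_type references unknown cell type {ctype!r}"
                )
            for gene, _ in effects:
                if gene not in panel:
                    raise ConfigurationError(
                        f"differential gene {gene!r} is not in the gene panel"
                    )


@dataclass
class SyntheticTruth:
    """Ground-truth record of the generator, for validation only."""

    de_genes_per_type: dict
    violator_barcodes: list
    violator_rule: dict  # barcode -> "mito" | "hemoglobin" | "low_genes"
    cells_per_patient_type: pd.DataFrame  # patient_id x cell_type counts


def _gene_panel(n_genes: int):
    """Gene names and category annotation for a panel of ``n_genes``."""
    names: list = list(HEMOGLOBIN_GENES) + list(MITO_GENES)
    cats: list = ["hemoglobin"] * 10 + ["mito"] * 13
    n_ribo, n_pseudo, n_linc = 30, 15, 20
    names += [f"RPS{i}" if i % 2 else f"RPL{i}" for i in range(1, n_ribo + 1)]
    cats += ["ribo"] * n_ribo
    names += [f"PSG{i}P" for i in range(1, n_pseudo + 1)]
    cats += ["pseudogene"] * n_pseudo
    names += [f"LINC{i:05d}" for i in range(1, n_linc + 1)]
    cats += ["lincRNA"] * n_linc
    n_rest = n_genes - len(names)
    names += [f"GENE{i:05d}" for i in range(1, n_rest + 1)]
    cats += ["protein_coding"] * n_rest
    return names, cats


def generate_cohort(config: SyntheticConfig) -> pd.DataFrame:
    """Draw subject-level clinical covariates for both groups.

    Continuous covariates are Normal(group mean, group SD); binary covariates
    are Bernoulli(group rate).  Output is one row per subject with
    ``patient_id`` and ``group`` columns, reproducible under ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows = []
    for group, n in (("PE", config.n_pe), ("NP", config.n_np)):
        for i in range(n):
            row = {"patient_id": f"{group}{i + 1:02d}", "group": group}
            for cov, per_group in config.covariate_params.items():
                spec = per_group[group]
                if isinstance(spec, tuple):
                    mu, sd = spec
                    row[cov] = float(rng.normal(mu, sd))
                else:
                    row[cov] = int(rng.random() < float(spec))
            rows.append(row)
    cohort = pd.DataFrame(rows)
    # gestational ages / weights cannot be negative even with generous SDs
    for col in cohort.columns:
        if cohort[col].dtype.kind == "f":
            cohort[col] = cohort[col].clip(lower=0.0)
    return cohort


def generate_counts(config: SyntheticConfig, cohort: pd.DataFrame):
    """Draw the annotated single-cell count matrix for a cohort.

    Counts for gene g in cell j of patient p follow
    ``NB(mean = baseline_g * libsize_j * patient_p * 2**effect, size = nb_dispersion)``
    where the log2 effect applies only in PE cells of the matching cell type.
    A ``qc_violator_fraction`` of cells is then perturbed post hoc to violate
    one QC rule each (mito fraction >= 10%, hemoglobin fraction >= 1%, or
    fewer than 200 detected genes).

    Returns ``(adata, truth)``: an :class:`anndata.AnnData` (cells x genes,
    integer counts in ``X`` and ``layers["counts"]``, gene ``category`` in
    ``var``) and the :class:`SyntheticTruth` record.
    """
    config.validate()
    if not {"patient_id", "group"}.issubset(cohort.columns):
        raise ConfigurationError("cohort needs patient_id and group columns")
    rng = np.random.default_rng(config.seed + 1)

    gene_names, gene_cats = _gene_panel(config.n_genes)
    gene_cats = np.asarray(gene_cats)
    baseline = np.exp(
        rng.normal(config.baseline_logmean_mu, config.baseline_logmean_sigma,
                   config.n_genes)
    )
    # rescale special categories to realistic fractions of total expression:
    # mito ~4%, hemoglobin ~0.05% (far from the 10%/1% QC thresholds)
    total = baseline.sum()
    for cat, frac in (("mito", 0.04), ("hemoglobin", 0.0005)):
        mask = gene_cats == cat
        baseline[mask] *= frac * total / baseline[mask].sum()

    name_to_idx = {g: i for i, g in enumerate(gene_names)}
    de_idx = sorted({
        name_to_idx[g]
        for pairs in config.de_genes_per_type.values() for g, _ in pairs
    })
    if de_idx and config.de_min_baseline_quantile > 0:
        floor = np.quantile(baseline, config.de_min_baseline_quantile)
        baseline[de_idx] = np.maximum(baseline[de_idx], floor)
    effect = {}  # cell type -> per-gene multiplier applied in PE
    for ctype, pairs in config.de_genes_per_type.items():
        mult = np.ones(config.n_genes)
        for gene, log2fc in pairs:
            mult[name_to_idx[gene]] = 2.0 ** float(log2fc)
        effect[ctype] = mult

    props = np.asarray(config.cell_type_proportions, dtype=float)
    r = float(config.nb_dispersion)

    blocks, barcodes, pat_col, grp_col, type_col = [], [], [], [], []
    counts_by_pt = {}
    cell_no = 0
    for _, subj in cohort.iterrows():
        pid, group = subj["patient_id"], subj["group"]
        pat_eff = float(np.exp(rng.normal(0.0, config.patient_effect_sigma)))
        n_cells = config.cells_per_patient
        types = rng.choice(len(props), size=n_cells, p=props)
        lib = np.exp(rng.normal(0.0, config.libsize_sigma, n_cells))
        mean = baseline[None, :] * (pat_eff * lib)[:, None]
        if group == "PE":
            for t_idx, ctype in enumerate(config.cell_types):
                if ctype in effect:
                    rows = types == t_idx
                    mean[rows] = mean[rows] * effect[ctype][None, :]
        counts = rng.negative_binomial(r, r / (r + mean))
        blocks.append(counts)
        for t_idx, ctype in enumerate(config.cell_types):
            counts_by_pt[(pid, ctype)] = int((types == t_idx).sum())
        for t in types:
            barcodes.append(f"CELL{cell_no:06d}")
            cell_no += 1
            pat_col.append(pid)
            grp_col.append(group)
            type_col.append(config.cell_types[t])

    counts = np.vstack(blocks).astype(np.int64)
    n_cells_total = counts.shape[0]

    # ---- inject QC violators -------------------------------------------
    mito_idx = np.where(gene_cats == "mito")[0]
    hb_idx = np.where(gene_cats == "hemoglobin")[0]
    is_violator = rng.random(n_cells_total) < config.qc_violator_fraction
    violator_rules = ("mito", "hemoglobin", "low_genes")
    violator_rule: dict = {}
    for k, j in enumerate(np.where(is_violator)[0]):
        rule = violator_rules[k % 3]
        row = counts[j]
        if rule == "mito":
            frac = rng.uniform(0.15, 0.35)
            other = row.sum() - row[mito_idx].sum()
            target = max(int(np.ceil(frac / (1 - frac) * other)), 20)
            row[mito_idx] = rng.multinomial(
                target, baseline[mito_idx] / baseline[mito_idx].sum()
            )
        elif rule == "hemoglobin":
            frac = rng.uniform(0.03, 0.08)
            other = row.sum() - row[hb_idx].sum()
            target = max(int(np.ceil(frac / (1 - frac) * other)), 20)
            row[hb_idx] = rng.multinomial(
                target, baseline[hb_idx] / baseline[hb_idx].sum()
            )
        else:  # low_genes: keep well under the 200-gene floor
            nonzero = np.where(row > 0)[0]
            keep = rng.choice(
                nonzero, size=min(rng.integers(50, 150), nonzero.size),
                replace=False,
            )
            mask = np.zeros(config.n_genes, dtype=bool)
            mask[keep] = True
            row[~mask] = 0
        counts[j] = row
        violator_rule[barcodes[j]] = rule

    obs = pd.DataFrame(
        {
            "patient_id": pd.Categorical(pat_col),
            "group": pd.Categorical(grp_col, categories=["NP", "PE"]),
            "cell_type": pd.Categorical(type_col),
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    var = pd.DataFrame(
        {"category": pd.Categorical(gene_cats)},
        index=pd.Index(gene_names, name="gene"),
    )
    X = sp.csr_matrix(counts)
    adata = ad.AnnData(X=X, obs=obs, var=var)
    adata.layers["counts"] = X.copy()
    adata.uns["layer_tag"] = "counts"

    per_pt = (
        pd.Series(counts_by_pt)
        .rename_axis(["patient_id", "cell_type"])
        .unstack(fill_value=0)
    )
    truth = SyntheticTruth(
        de_genes_per_type={
            k: list(v) for k, v in config.de_genes_per_type.items()
        },
        violator_barcodes=[barcodes[j] for j in np.where(is_violator)[0]],
        violator_rule=violator_rule,
        cells_per_patient_type=per_pt,
    )
    return adata, truth


def generate_dataset(config: SyntheticConfig):
    """Convenience wrapper: cohort + counts in one call.

    Returns ``(adata, cohort, truth)``.
    """
    cohort = generate_cohort(config)
    adata, truth = generate_counts(config, cohort)
    return adata, cohort, truth


def config_from_dict(d: dict) -> SyntheticConfig:
    """Build a config from a plain mapping (e.g. parsed YAML)."""
    known = {f.name for f in dataclasses.fields(SyntheticConfig)}
    unknown = set(d) - known
    if unknown:
        raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
    d = dict(d)
    for key in ("cell_types", "cell_type_proportions"):
        if key in d:
            d[key] = tuple(d[key])
    if "de_genes_per_type" in d:
        d["de_genes_per_type"] = {
            k: [(g, float(e)) for g, e in v]
            for k, v in d["de_genes_per_type"].items()
        }
    return SyntheticConfig(**d)
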