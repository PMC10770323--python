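"""Cell/gene quality control, normalization and highly-variable genes.

QC keeps cells with 200–6000 detected genes, mitochondrial count fraction
below 10% and hemoglobin count fraction (over ten hemoglobin genes) below
1%; genes are kept when expressed in more than 3 cells, and ribosomal,
mitochondrial, pseudogene and lincRNA genes are removed outright.
Expression is then depth-normalized to 10,000 counts per cell,
log1p-transformed, and the top 2,000 genes by binned normalized dispersion
are flagged as highly variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .synthetic import HEMOGLOBIN_GENES

__all__ = [
    "QCParams",
    "NormalizationParams",
    "AnnotationError",
    "filter_cells",
    "filter_genes",
    "normalize_log",
    "select_hvgs",
]


class AnnotationError(ValueError):
    pass


class StatisticsError(ValueError):
    pass


@dataclass
class QCParams:
    min_genes_per_cell: int = 200
    max_genes_per_cell: int = 6000
    max_mito_fraction: float = 0.10
    max_hemoglobin_fraction: float = 0.01
    hemoglobin_genes: tuple = HEMOGLOBIN_GENES
    min_cells_per_gene: int = 3  # gene kept iff expressed in MORE than this
    blacklist_categories: tuple = ("ribo", "mito", "pseudogene", "lincRNA")

    def __post_init__(self):
        if not 0 < self.min_genes_per_cell < self.max_genes_per_cell:
            raise ValueError("need 0 < min_genes_per_cell < max_genes_per_cell")
        for f in (self.max_mito_fraction, self.max_hemoglobin_fraction):
            if not 0 < f <= 1:
                raise ValueError("QC fractions must lie in (0, 1]")


@dataclass
class NormalizationParams:
    target_sum: float = 10_000.0
    n_hvgs: int = 2000

    def __post_init__(self):
        if self.target_sum <= 0:
            raise ValueError("target_sum must be positive")


def _counts(m: ad.AnnData) -> sp.csr_matrix:
    if "counts" not in m.layers:
        raise AnnotationError("counts layer is missing; run on raw count data")
    return sp.csr_matrix(m.layers["counts"])


def _mito_mask(m: ad.AnnData) -> np.ndarray:
    if "category" in m.var.columns:
        return (m.var["category"].astype(str) == "mito").to_numpy()
    # fallback for data without category annotation
    return m.var_names.str.upper().str.startswith("MT-").to_numpy()


def filter_cells(m: ad.AnnData, p: QCParams | None = None):
    """Drop cells violating the detected-gene, mito or hemoglobin rules.

    Returns ``(filtered, report)``; the report attributes each dropped cell
    to the first rule it violates, in the order gene-range, mito,
    hemoglobin, so per-rule counts sum to the total dropped.
    """
    p = p or QCParams()
    X = _counts(m)
    detected = np.asarray((X > 0).sum(axis=1)).ravel()
    total = np.asarray(X.sum(axis=1)).ravel().astype(float)
    safe_total = np.where(total > 0, total, 1.0)
    mito = _mito_mask(m)
    mito_frac = np.asarray(X[:, mito].sum(axis=1)).ravel() / safe_total
    hb = m.var_names.isin(p.hemoglobin_genes)
    hb_frac = np.asarray(X[:, hb].sum(axis=1)).ravel() / safe_total

    bad_range = (detected < p.min_genes_per_cell) | (detected > p.max_genes_per_cell)
    bad_mito = mito_frac >= p.max_mito_fraction
    bad_hb = hb_frac >= p.max_hemoglobin_fraction
    keep = ~(bad_range | bad_mito | bad_hb)

    report = {
        "n_input": int(m.n_obs),
        "n_kept": int(keep.sum()),
        "dropped_gene_range": int(bad_range.sum()),
        "dropped_mito": int((bad_mito & ~bad_range).sum()),
        "dropped_hemoglobin": int((bad_hb & ~bad_range & ~bad_mito).sum()),
        "dropped_barcodes": list(np.asarray(m.obs_names)[~keep]),
    }
    return m[keep].copy(), report


def filter_genes(m: ad.AnnData, p: QCParams | None = None) -> ad.AnnData:
    """Keep genes expressed in more than ``min_cells_per_gene`` cells and
    not in a blacklisted category (ribo/mito/pseudogene/lincRNA)."""
    p = p or QCParams()
    X = _counts(m)
    n_cells_expr = np.asarray((X > 0).sum(axis=0)).ravel()
    keep = n_cells_expr > p.min_cells_per_gene
    if "category" in m.var.columns:
        keep &= ~m.var["category"].astype(str).isin(p.blacklist_categories).to_numpy()
    else:
        keep &= ~_mito_mask(m)
    return m[:, keep].copy()


def normalize_log(m: ad.AnnData, p: NormalizationParams | None = None) -> ad.AnnData:
    """Add a ``lognorm`` layer: ``log1p(target_sum * c / total_c)`` per cell."""
    p = p or NormalizationParams()
    X = _counts(m).astype(float)
    total = np.asarray(X.sum(axis=1)).ravel()
    if np.any(total == 0):
        raise ZeroDivisionError(
            "all-zero cells present; apply cell QC before normalization"
        )
    out = m.copy()
    norm = sp.diags(p.target_sum / total) @ X
    norm.data = np.log1p(norm.data)
    out.layers["lognorm"] = sp.csr_matrix(norm)
    out.uns["layer_tag"] = "lognorm"
    return out


def select_hvgs(m: ad.AnnData, p: NormalizationParams | None = None,
                n_bins: int = 20) -> list:
    """Rank genes by binned normalized dispersion and return the top set.

    The community-default recipe for log-normalized data: de-log, compute
    per-gene mean and dispersion (variance/mean), take log dispersion, cut
    genes into ``n_bins`` equal-width bins of log1p mean, and z-score the
    log dispersions within each bin (a gene alone in its bin gets z = 1).
    Genes with zero variance never rank above genes with positive
    dispersion; ties break by gene name so the ranking is deterministic.
    """
    p = p or NormalizationParams()
    if "lognorm" not in m.layers:
        raise AnnotationError("lognorm layer missing; run normalize_log first")
    if m.n_obs < 2:
        raise StatisticsError("need at least 2 cells to estimate dispersion")
    X = sp.csr_matrix(m.layers["lognorm"]).copy()
    X.data = np.expm1(X.data)
    mean = np.asarray(X.mean(axis=0)).ravel()
    sq = X.copy()
    sq.data **= 2
    n = X.shape[0]
    var = (np.asarray(sq.sum(axis=0)).ravel() - n * mean**2) * (n / (n - 1)) / n
    var = np.maximum(var, 0.0)

    mean = np.where(mean == 0, 1e-12, mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = var / mean
        disp = np.where(disp == 0, np.nan, disp)
        disp = np.log(disp)
    logmean = np.log1p(mean)

    df = pd.DataFrame({"mean": logmean, "disp": disp}, index=m.var_names)
    df["bin"] = pd.cut(df["mean"], bins=n_bins)
    grouped = df.groupby("bin", observed=True)["disp"]
    bin_avg = grouped.transform("mean")
    bin_dev = grouped.transform(lambda s: s.std(ddof=1))
    one_gene = grouped.transform("size") == 1
    bin_avg = bin_avg.where(~one_gene, 0.0)
    bin_dev = bin_dev.where(~one_gene, grouped.transform("mean"))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (df["disp"] - bin_avg) / bin_dev
    z = z.fillna(-np.inf)  # zero-dispersion genes never win

    order = sorted(m.var_names, key=lambda g: (-z[g], g))
    return order[: min(p.n_hvgs, len(order))]
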