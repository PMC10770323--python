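"""Wilcoxon rank-sum differential expression between PE and NP cells.

Per gene, a two-sided rank-sum test on the log-normalized values of a cell
subset: exact enumeration of the rank-sum distribution when both groups
have at most 25 cells (dynamic program over doubled midranks, so ties are
handled exactly), a normal approximation with tie correction otherwise.
The average log2 fold change follows the convention for log-normalized
single-cell data:

    avg_log2fc = log2((mean(expm1 x | PE) + 1) / (mean(expm1 x | NP) + 1))

A gene is a significant DEG when Bonferroni-adjusted p < 0.05 AND
|avg_log2fc| > 0.15 (both gates strict).
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu, rankdata

__all__ = ["DEGRecord", "wilcoxon_de", "filter_significant",
           "exact_ranksum_pvalue"]

P_THRESHOLD = 0.05
LFC_THRESHOLD = 0.15
EXACT_MAX_GROUP = 25


class StatisticsError(ValueError):
    pass


@dataclass
class DEGRecord:
    gene: str
    avg_log2fc: float
    p_value: float
    p_adjusted: float
    direction: str  # up_in_PE | down_in_PE
    significant: bool


def exact_ranksum_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p-value by full enumeration.

    Counts, over all C(n1+n2, n1) assignments of the pooled midranks to
    group 1, the probability of a rank sum at least as far from its mean as
    observed.  Doubling the midranks makes every value an integer, so the
    distribution is built by an exact integer-weight dynamic program.
    """
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    ranks2 = np.round(2 * rankdata(pooled)).astype(int)  # doubled midranks
    w_obs = int(ranks2[:n1].sum())
    mu2 = n1 * ranks2.sum() / n

    # dp[k, s] = number of k-subsets of the doubled ranks with sum s
    smax = int(ranks2.sum())
    dp = np.zeros((n1 + 1, smax + 1))
    dp[0, 0] = 1.0
    for r in ranks2:
        for k in range(n1 - 1, -1, -1):
            dp[k + 1, r:] += dp[k, : smax + 1 - r]
    counts = dp[n1]
    total = counts.sum()
    d_obs = abs(w_obs - mu2)
    sums = np.arange(smax + 1)
    extreme = np.abs(sums - mu2) >= d_obs - 1e-9
    return float(counts[extreme].sum() / total)


def _ranksum_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) <= EXACT_MAX_GROUP and len(y) <= EXACT_MAX_GROUP:
        return exact_ranksum_pvalue(x, y)
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        return 1.0  # all values tied: no evidence either way
    return float(mannwhitneyu(x, y, alternative="two-sided",
                              method="asymptotic").pvalue)


def wilcoxon_de(m: ad.AnnData, cell_types=None, group_col: str = "group") -> list:
    """DEG records for PE vs NP within a cell-type subset (all cells if
    ``cell_types`` is None)."""
    if "lognorm" not in m.layers:
        raise ValueError("lognorm layer missing; run normalize_log first")
    mask = np.ones(m.n_obs, dtype=bool)
    if cell_types is not None:
        if isinstance(cell_types, str):
            cell_types = (cell_types,)
        mask = m.obs["cell_type"].astype(str).isin(cell_types).to_numpy()
    groups = m.obs[group_col].astype(str).to_numpy()
    pe = mask & (groups == "PE")
    np_ = mask & (groups == "NP")
    if pe.sum() < 3 or np_.sum() < 3:
        raise StatisticsError(
            f"need >= 3 cells per group in the subset (PE={pe.sum()}, "
            f"NP={np_.sum()})"
        )
    X = sp.csr_matrix(m.layers["lognorm"])
    Xpe = np.asarray(X[pe].todense())
    Xnp = np.asarray(X[np_].todense())

    n_genes = m.n_vars
    records = []
    mean_pe = np.expm1(Xpe).mean(axis=0)
    mean_np = np.expm1(Xnp).mean(axis=0)
    lfc = np.log2((mean_pe + 1.0) / (mean_np + 1.0))
    for j, gene in enumerate(m.var_names):
        p = _ranksum_pvalue(Xpe[:, j], Xnp[:, j])
        p_adj = min(1.0, p * n_genes)
        records.append(DEGRecord(
            gene=str(gene), avg_log2fc=float(lfc[j]), p_value=p,
            p_adjusted=p_adj,
            direction="up_in_PE" if lfc[j] >= 0 else "down_in_PE",
            significant=bool(p_adj < P_THRESHOLD and abs(lfc[j]) > LFC_THRESHOLD),
        ))
    return records


def filter_significant(records) -> list:
    """Significant DEGs sorted by |avg_log2fc| descending (ties by gene)."""
    sig = [r for r in records if r.significant]
    return sorted(sig, key=lambda r: (-abs(r.avg_log2fc), r.gene))


def de_table(records) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene, "avg_log2fc": r.avg_log2fc,
                "p_value": r.p_value, "p_adjusted": r.p_adjusted,
                "direction": r.direction, "significant": r.significant,
            }
            for r in records
        ]
    )
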