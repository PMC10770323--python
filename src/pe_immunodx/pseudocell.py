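"""Pseudo-cell construction.

A pseudo-cell is the mean log-normalized expression of a fixed-size block
(default 5) of cells sampled without replacement from one patient within one
annotated cell type (or a named union of types, e.g. all monocyte subsets).
Each pseudo-cell inherits its patient's PE/NP label; remainder cells that do
not fill a complete block are discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["PseudoCellParams", "PseudoCellDataset", "build_pseudocells",
           "summarize_dataset", "EmptySelectionError"]

log = logging.getLogger("pe_immunodx")


class EmptySelectionError(ValueError):
    pass


@dataclass
class PseudoCellParams:
    cell_types: tuple  # one annotated type or a union of types
    k: int = 5
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.cell_types, str):
            self.cell_types = (self.cell_types,)
        else:
            self.cell_types = tuple(self.cell_types)
        if self.k < 1:
            raise ValueError("pseudo-cell size k must be >= 1")


@dataclass
class PseudoCellDataset:
    """Pseudo-cell features with labels and full cell-level provenance."""

    features: pd.DataFrame          # pseudo-cells x genes
    labels: pd.Series               # 1 = PE (positive), 0 = NP
    patient_ids: pd.Series
    provenance: dict = field(repr=False)  # pseudo-cell id -> member barcodes

    def __len__(self) -> int:
        return len(self.features)

    def subset_genes(self, genes) -> "PseudoCellDataset":
        return PseudoCellDataset(
            self.features[list(genes)], self.labels, self.patient_ids,
            self.provenance,
        )

    def take(self, index) -> "PseudoCellDataset":
        return PseudoCellDataset(
            self.features.loc[index],
            self.labels.loc[index],
            self.patient_ids.loc[index],
            {i: self.provenance[i] for i in index},
        )


def build_pseudocells(m: ad.AnnData, p: PseudoCellParams,
                      genes=None) -> PseudoCellDataset:
    """Partition each patient's cells of the selected type(s) into disjoint
    blocks of ``k`` (seeded shuffle) and average the log-normalized layer.

    ``genes`` optionally restricts the feature space (e.g. to the HVG set).
    """
    if "lognorm" not in m.layers:
        raise ValueError("lognorm layer missing; run normalize_log first")
    sel = m.obs["cell_type"].astype(str).isin(p.cell_types).to_numpy()
    if not sel.any():
        raise EmptySelectionError(
            f"no cells match cell type(s) {p.cell_types!r}"
        )
    sub = m[sel]
    if genes is not None:
        sub = sub[:, list(genes)]
    X = sp.csr_matrix(sub.layers["lognorm"])
    barcodes = np.asarray(sub.obs_names)
    patients = sub.obs["patient_id"].astype(str).to_numpy()
    groups = sub.obs["group"].astype(str).to_numpy()

    rng = np.random.default_rng(p.seed)
    feats, labels, pids, prov, ids = [], [], [], {}, []
    n_pc = 0
    for pid in sorted(pd.unique(patients)):
        rows = np.where(patients == pid)[0]
        if rows.size < p.k:
            log.warning(
                "patient %s has %d cells of %s (< k=%d); contributes no "
                "pseudo-cells", pid, rows.size, p.cell_types, p.k,
            )
            continue
        perm = rng.permutation(rows)
        n_blocks = rows.size // p.k
        grp = groups[rows[0]]
        for b in range(n_blocks):
            block = perm[b * p.k : (b + 1) * p.k]
            vec = np.asarray(X[block].mean(axis=0)).ravel()
            pc_id = f"{pid}_pc{b:04d}"
            feats.append(vec)
            labels.append(1 if grp == "PE" else 0)
            pids.append(pid)
            prov[pc_id] = [str(x) for x in barcodes[block]]
            ids.append(pc_id)
            n_pc += 1
    if n_pc == 0:
        raise EmptySelectionError(
            "no patient had enough cells to form a single pseudo-cell"
        )
    index = pd.Index(ids, name="pseudo_cell")
    return PseudoCellDataset(
        features=pd.DataFrame(np.vstack(feats), index=index,
                              columns=sub.var_names),
        labels=pd.Series(labels, index=index, name="label"),
        patient_ids=pd.Series(pids, index=index, name="patient_id"),
        provenance=prov,
    )


def summarize_dataset(d: PseudoCellDataset) -> dict:
    """Class balance and per-patient pseudo-cell counts."""
    if len(d) == 0:
        raise ValueError("empty pseudo-cell dataset")
    n_pos = int((d.labels == 1).sum())
    n_neg = int((d.labels == 0).sum())
    summary = {
        "n_pseudocells": len(d),
        "n_positive": n_pos,
        "n_negative": n_neg,
        "fraction_positive": n_pos / len(d),
        "per_patient": d.patient_ids.value_counts().sort_index().to_dict(),
        "degenerate": "one class" if n_pos == 0 or n_neg == 0 else None,
    }
    return summary
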