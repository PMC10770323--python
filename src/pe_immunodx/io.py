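"""Reading and writing annotated expression matrices.

On disk a dataset is a directory in the CellRanger-like layout:

- ``matrix.mtx``   — genes x cells sparse counts, Matrix Market coordinate
- ``features.tsv`` — one gene per line: name <TAB> category
- ``barcodes.tsv`` — one cell barcode per line
- ``cells.csv``    — per-cell metadata (barcode, patient_id, group, cell_type)
- ``subjects.csv`` — optional subject-level covariate table

In memory the container is :class:`anndata.AnnData` (cells x genes).
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = ["FormatError", "write_dataset", "read_dataset"]

CELL_COLUMNS = ("patient_id", "group", "cell_type")


class FormatError(ValueError):
    """Mismatch between the matrix and its sidecar files."""


def write_dataset(adata: ad.AnnData, outdir, subjects: pd.DataFrame | None = None) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.layers.get("counts", adata.X)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), sp.coo_matrix(X.T))
    feat = pd.DataFrame(
        {
            "gene": adata.var_names,
            "category": adata.var.get(
                "category", pd.Series("other", index=adata.var_names)
            ).astype(str),
        }
    )
    feat.to_csv(outdir / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(
        outdir / "barcodes.tsv", sep="\t", header=False, index=False
    )
    cells = adata.obs.reset_index(names="barcode")
    cells.to_csv(outdir / "cells.csv", index=False)
    if subjects is not None:
        subjects.to_csv(outdir / "subjects.csv", index=False)
    return outdir


def read_dataset(indir) -> ad.AnnData:
    indir = Path(indir)
    mat = sp.csr_matrix(scipy.io.mmread(str(indir / "matrix.mtx"))).T
    features = pd.read_csv(
        indir / "features.tsv", sep="\t", header=None,
        names=["gene", "category"],
    )
    barcodes = pd.read_csv(
        indir / "barcodes.tsv", sep="\t", header=None, names=["barcode"]
    )["barcode"].astype(str)
    if len(features) != mat.shape[1]:
        raise FormatError(
            f"matrix has {mat.shape[1]} genes but features.tsv has "
            f"{len(features)} rows"
        )
    if len(barcodes) != mat.shape[0]:
        raise FormatError(
            f"matrix has {mat.shape[0]} cells but barcodes.tsv has "
            f"{len(barcodes)} rows"
        )
    obs = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    cells_path = indir / "cells.csv"
    if cells_path.exists():
        cells = pd.read_csv(cells_path, dtype=str).set_index("barcode")
        if not cells.index.equals(obs.index):
            cells = cells.reindex(obs.index)
            if cells.isna().all(axis=1).any():
                raise FormatError("cells.csv does not cover every barcode")
        for col in cells.columns:
            obs[col] = pd.Categorical(cells[col])
    var = pd.DataFrame(
        {"category": pd.Categorical(features["category"].fillna("other"))},
        index=pd.Index(features["gene"].astype(str), name="gene"),
    )
    if mat.shape[0] == 0:
        mat = sp.csr_matrix((0, len(var)))
    adata = ad.AnnData(X=mat, obs=obs, var=var)
    adata.layers["counts"] = adata.X.copy()
    adata.uns["layer_tag"] = "counts"
    adata.uns["degenerate"] = bool(adata.n_obs == 0 or adata.n_vars == 0)
    return adata


def read_subjects(indir) -> pd.DataFrame:
    return pd.read_csv(Path(indir) / "subjects.csv")
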