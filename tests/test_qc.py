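"""QC filters, normalization and HVG selection."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from pe_immunodx import qc
from pe_immunodx.qc import (NormalizationParams, QCParams, filter_cells,
                            filter_genes, normalize_log, select_hvgs)


def _make_adata(counts, categories=None, genes=None):
    counts = np.asarray(counts)
    n, p = counts.shape
    genes = genes or [f"G{j:04d}" for j in range(p)]
    obs = pd.DataFrame(
        {
            "patient_id": ["P1"] * n,
            "group": ["PE"] * n,
            "cell_type": ["t"] * n,
        },
        index=pd.Index([f"C{i:04d}" for i in range(n)], name="barcode"),
    )
    var = pd.DataFrame(
        {"category": pd.Categorical(categories or ["protein_coding"] * p)},
        index=pd.Index(genes, name="gene"),
    )
    a = ad.AnnData(X=sp.csr_matrix(counts.astype(float)), obs=obs, var=var)
    a.layers["counts"] = a.X.copy()
    return a


def test_detected_gene_boundaries():
    """199 detected genes -> dropped; 200 -> kept (inclusive range)."""
    p = 300
    rows = np.zeros((3, p))
    rows[0, :199] = 1
    rows[1, :200] = 1
    rows[2, :250] = 1
    a = _make_adata(rows)
    kept, report = filter_cells(a)
    assert list(kept.obs_names) == ["C0001", "C0002"]
    assert report["dropped_gene_range"] == 1


def test_all_zero_cell_dropped():
    rows = np.zeros((2, 300))
    rows[1, :220] = 1
    kept, report = filter_cells(_make_adata(rows))
    assert list(kept.obs_names) == ["C0001"]


def test_mito_hemoglobin_thresholds_strict():
    """Fractions exactly at threshold are dropped (< rule)."""
    p = 1000
    cats = ["protein_coding"] * p
    cats[0] = "mito"
    genes = [f"G{j:04d}" for j in range(p)]
    genes[1] = "HBB"
    # cell at exactly the thresholds: total 1000, mito 100 (10%), hb 10 (1%)
    c_mito = np.zeros(p)
    c_mito[2:892] = 1   # 890 ones
    c_mito[0] = 100     # mito
    c_mito[1] = 10      # hb
    assert c_mito.sum() == 1000
    c_ok = np.zeros(p)
    c_ok[2:992] = 1     # 990 ones
    c_ok[0] = 9         # mito 0.9%
    c_ok[1] = 1         # hb 0.1%
    a = _make_adata(np.vstack([c_mito, c_ok]), categories=cats, genes=genes)
    kept, report = filter_cells(a)
    assert list(kept.obs_names) == ["C0001"]
    assert report["dropped_mito"] == 1  # first-violated rule wins


def test_dropped_cells_equal_generator_truth(small_dataset):
    _, adata, _, truth = small_dataset
    _, report = filter_cells(adata)
    assert set(report["dropped_barcodes"]) == set(truth.violator_barcodes)
    assert (report["n_kept"] + report["dropped_gene_range"]
            + report["dropped_mito"] + report["dropped_hemoglobin"]
            == report["n_input"])


def test_gene_expression_boundary():
    """Expressed in exactly 4 cells -> kept; exactly 3 -> dropped."""
    counts = np.zeros((10, 3))
    counts[:3, 0] = 5   # 3 cells
    counts[:4, 1] = 5   # 4 cells
    counts[:, 2] = 1    # all cells
    a = _make_adata(counts)
    out = filter_genes(a)
    assert list(out.var_names) == ["G0001", "G0002"]


def test_blacklist_categories_removed():
    counts = np.ones((10, 4))
    a = _make_adata(counts, categories=["ribo", "mito", "lincRNA",
                                        "protein_coding"])
    out = filter_genes(a)
    assert list(out.var_names) == ["G0003"]


def test_filters_idempotent(small_dataset):
    _, adata, _, _ = small_dataset
    once, _ = filter_cells(adata)
    twice, rep2 = filter_cells(once)
    assert list(once.obs_names) == list(twice.obs_names)
    assert rep2["n_kept"] == rep2["n_input"]
    g1 = filter_genes(once)
    g2 = filter_genes(g1)
    assert list(g1.var_names) == list(g2.var_names)


def test_normalize_sums_and_values():
    counts = np.array([[5, 0, 0], [2, 3, 5]])
    a = _make_adata(counts)
    out = normalize_log(a)
    dense = np.asarray(out.layers["lognorm"].todense())
    # per-cell de-logged sums hit the target
    assert np.allclose(np.expm1(dense).sum(axis=1), 10_000, rtol=1e-9)
    # single nonzero gene with count 5 -> log(1 + 10000)
    assert dense[0, 0] == pytest.approx(np.log(1 + 10_000))
    assert dense[0, 1] == 0.0
    # counts layer preserved
    assert (out.layers["counts"] != a.layers["counts"]).nnz == 0


def test_normalize_rejects_zero_cells():
    counts = np.array([[0, 0], [1, 2]])
    with pytest.raises(ZeroDivisionError, match="QC"):
        normalize_log(_make_adata(counts))


def test_hvg_saturation_and_constant_gene():
    rng = np.random.default_rng(0)
    counts = rng.poisson(5, size=(30, 10)).astype(float)
    a = normalize_log(_make_adata(counts))
    # make gene 0 constant in the normalized layer (zero dispersion)
    dense = np.asarray(a.layers["lognorm"].todense())
    dense[:, 0] = 1.3
    a.layers["lognorm"] = sp.csr_matrix(dense)
    allg = select_hvgs(a, NormalizationParams(n_hvgs=10))
    assert len(allg) == 10  # saturation: everything returned
    top = select_hvgs(a, NormalizationParams(n_hvgs=9))
    assert "G0000" not in top  # constant gene never beats varying genes


def test_hvg_matches_scanpy_seurat_flavor():
    """Independent oracle: scanpy's binned-dispersion ranking."""
    sc = pytest.importorskip("scanpy")
    rng = np.random.default_rng(7)
    n, p = 120, 80
    counts = rng.negative_binomial(2, 2 / (2 + rng.lognormal(0, 1, p)),
                                   size=(n, p)).astype(float)
    counts[:, counts.sum(axis=0) == 0] = 1.0  # keep every gene expressed
    a = normalize_log(_make_adata(counts))
    mine = select_hvgs(a, NormalizationParams(n_hvgs=20))

    b = ad.AnnData(X=sp.csr_matrix(np.asarray(a.layers["lognorm"].todense())))
    b.var_names = a.var_names
    sc.pp.highly_variable_genes(b, flavor="seurat", n_top_genes=20,
                                n_bins=20)
    oracle = set(b.var_names[b.var["highly_variable"]])
    assert set(mine) == oracle
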