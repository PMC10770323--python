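import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pe_immunodx.synthetic import SyntheticConfig, generate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """A small but QC-realistic synthetic dataset shared by unit tests.

    2,000 genes keep non-violating cells comfortably inside the 200-6000
    detected-gene window, so the generator's violator truth record is the
    exact QC-dropped set.
    """
    cfg = SyntheticConfig(
        n_pe=2, n_np=3, cells_per_patient=150, n_genes=2000,
        qc_violator_fraction=0.08, seed=42,
    )
    adata, cohort, truth = generate_dataset(cfg)
    return cfg, adata, cohort, truth


@pytest.fixture()
def toy_pseudocells():
    """A tiny deterministic pseudo-cell dataset for split/scaler tests."""
    rng = np.random.default_rng(0)
    n_pos, n_neg, p = 30, 70, 8
    X = rng.normal(size=(n_pos + n_neg, p))
    idx = pd.Index([f"pc{i:03d}" for i in range(n_pos + n_neg)],
                   name="pseudo_cell")
    from pe_immunodx.pseudocell import PseudoCellDataset

    labels = pd.Series([1] * n_pos + [0] * n_neg, index=idx, name="label")
    pids = pd.Series(
        [f"PE{i % 3}" for i in range(n_pos)] + [f"NP{i % 5}" for i in range(n_neg)],
        index=idx, name="patient_id",
    )
    return PseudoCellDataset(
        features=pd.DataFrame(X, index=idx, columns=[f"g{j}" for j in range(p)]),
        labels=labels, patient_ids=pids,
        provenance={i: [] for i in idx},
    )
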