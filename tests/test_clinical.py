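"""Clinical statistics: matching, test gating, exact Fisher."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from pe_immunodx.clinical import (MatchingError, compare_categorical,
                                  compare_continuous, fisher_exact_two_sided,
                                  propensity_match, table_one)


def enumeration_fisher(table):
    """Symbolic enumeration oracle over all tables with fixed margins."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    probs = []
    for aa in range(max(0, c1 - r2), min(r1, c1) + 1):
        probs.append((aa, Fraction(math.comb(r1, aa) * math.comb(r2, c1 - aa),
                                   math.comb(n, c1))))
    p_obs = dict(probs)[a]
    tol = Fraction(10**7 + 1, 10**7)
    return float(sum(p for _, p in probs if p <= p_obs * tol))


def test_fisher_matches_enumeration_and_scipy():
    t = [[1, 14], [4, 4]]
    p = fisher_exact_two_sided(t)
    assert p == pytest.approx(enumeration_fisher(t), abs=1e-12)
    assert p == pytest.approx(stats.fisher_exact(t).pvalue, abs=1e-9)


@given(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40),
       st.integers(0, 40))
def test_fisher_exhaustive_small_tables(a, b, c, d):
    """Agreement with the enumeration oracle for all tables with N <= 40."""
    if a + b + c + d > 40 or a + b == 0 or c + d == 0:
        return
    if a + c == 0 or b + d == 0:
        return
    t = [[a, b], [c, d]]
    assert fisher_exact_two_sided(t) == pytest.approx(
        enumeration_fisher(t), abs=1e-12)
    # transpose symmetry
    assert fisher_exact_two_sided([[a, c], [b, d]]) == pytest.approx(
        fisher_exact_two_sided(t), abs=1e-12)


def test_fisher_degenerate_single_table():
    assert fisher_exact_two_sided([[0, 5], [0, 7]]) == 1.0


def test_categorical_branch_rule():
    """Expected-count gate recomputed independently."""
    small = [[1, 14], [4, 4]]
    r = compare_categorical(small, "x")
    exp = np.outer([15, 8], [5, 18]) / 23
    assert (exp < 5).any()
    assert r.test_used == "fisher_exact"
    big = [[40, 60], [55, 45]]
    r2 = compare_categorical(big, "y")
    exp2 = np.outer([100, 100], [95, 105]) / 200
    assert not (exp2 < 5).any()
    assert r2.test_used == "chi_square"
    assert r2.p_value == pytest.approx(
        stats.chi2_contingency(np.array(big), correction=True)[1])


def test_continuous_gate_and_power():
    rng = np.random.default_rng(0)
    a = rng.normal(0, 1, 50)
    b = rng.normal(1, 1, 50)  # 1-SD shift
    r = compare_continuous(a, b, variable="v")
    # gate oracle: both samples pass KS normality at 0.05
    for x in (a, b):
        assert stats.kstest(x, "norm",
                            args=(x.mean(), x.std(ddof=1))).pvalue > 0.05
    assert r.test_used == "t_test"
    assert r.p_value < 0.01
    # heavy skew routes to Mann-Whitney
    sk1 = np.exp(rng.normal(0, 1.5, 80))
    sk2 = np.exp(rng.normal(0.2, 1.5, 80))
    r2 = compare_continuous(sk1, sk2, variable="w")
    assert (stats.kstest(sk1, "norm",
                         args=(sk1.mean(), sk1.std(ddof=1))).pvalue <= 0.05
            or stats.kstest(sk2, "norm",
                            args=(sk2.mean(), sk2.std(ddof=1))).pvalue <= 0.05)
    assert r2.test_used == "mann_whitney"


def test_identical_samples_p_one():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    r = compare_continuous(x, x.copy())
    assert r.p_value == pytest.approx(1.0)


def _cohort_frames(seed=0, n_cases=8, n_pool=40, confounded=True):
    rng = np.random.default_rng(seed)
    cases = pd.DataFrame({
        "patient_id": [f"PE{i}" for i in range(n_cases)],
        "age": rng.normal(32, 2, n_cases),
        "ga": rng.normal(37, 1, n_cases),
    })
    shift = 3.0 if confounded else 0.0
    pool = pd.DataFrame({
        "patient_id": [f"NP{i}" for i in range(n_pool)],
        "age": rng.normal(32 - shift, 3, n_pool),
        "ga": rng.normal(36, 2, n_pool),
    })
    return cases, pool


def test_matching_counts_and_no_reuse():
    cases, pool = _cohort_frames()
    res = propensity_match(cases, pool, ["age", "ga"], ratio=2, seed=1)
    all_controls = [c for v in res.matches.values() for c in v]
    assert len(all_controls) == 16  # 8 cases x 2 controls
    assert len(set(all_controls)) == 16  # without replacement


def test_matching_selects_exact_duplicates():
    cases, _ = _cohort_frames(n_cases=4)
    dup = pd.concat([cases, cases], ignore_index=True)
    dup["patient_id"] = [f"NP{i}" for i in range(len(dup))]
    far = pd.DataFrame({
        "patient_id": [f"FAR{i}" for i in range(8)],
        "age": np.full(8, 90.0), "ga": np.full(8, 20.0),
    })
    pool = pd.concat([dup, far], ignore_index=True)
    res = propensity_match(cases, pool, ["age", "ga"], ratio=2, seed=0)
    chosen = {c for v in res.matches.values() for c in v}
    assert all(not c.startswith("FAR") for c in chosen)


def test_matching_improves_balance():
    cases, pool = _cohort_frames(seed=3, n_pool=60, confounded=True)
    res = propensity_match(cases, pool, ["age", "ga"], ratio=2, seed=0)
    assert abs(res.smd_after["age"]) < abs(res.smd_before["age"])


def test_matching_pool_exhausted():
    cases, pool = _cohort_frames(n_cases=8, n_pool=10)
    with pytest.raises(MatchingError):
        propensity_match(cases, pool, ["age", "ga"], ratio=2)


def test_table_one_structure():
    rng = np.random.default_rng(4)
    subjects = pd.DataFrame({
        "patient_id": [f"S{i}" for i in range(23)],
        "group": ["PE"] * 8 + ["NP"] * 15,
        "bmi": rng.normal(26, 2, 23),
        "cesarean": [1] * 4 + [0] * 4 + [1] + [0] * 14,
    })
    t = table_one(subjects)
    assert set(t["variable"]) == {"bmi", "cesarean"}
    ces = t[t["variable"] == "cesarean"].iloc[0]
    assert ces["test"] == "fisher_exact"
    assert ces["p_value"] == pytest.approx(
        fisher_exact_two_sided([[1, 14], [4, 4]]), abs=1e-12)
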