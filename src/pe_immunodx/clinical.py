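"""Propensity-score matching and the clinical "Table 1" test battery.

Controls are matched one-to-two to cases by greedy nearest neighbor on the
logit of a logistic-regression propensity score, without replacement.
Continuous covariates are compared with a pooled-variance t-test when both
groups pass a Kolmogorov–Smirnov normality check (estimated parameters,
alpha 0.05) and with a Mann–Whitney U test otherwise; 2x2 categorical
tables use Fisher's exact test when any expected count is below 5 and a
Yates-corrected chi-square otherwise.  The two-sided Fisher p-value follows
the probability-based convention (sum over tables no more likely than the
observed one, with the standard 1 + 1e-7 tolerance) computed in exact
integer arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

__all__ = [
    "MatchResult", "ComparisonResult", "propensity_match",
    "compare_continuous", "compare_categorical", "fisher_exact_two_sided",
    "table_one", "MatchingError",
]


class MatchingError(ValueError):
    pass


class DegenerateTableError(ValueError):
    pass


@dataclass
class MatchResult:
    matches: dict                     # case id -> list of control ids
    propensity_coef: dict             # covariate -> logistic coefficient
    smd_before: dict                  # covariate -> standardized mean diff
    smd_after: dict


@dataclass
class ComparisonResult:
    variable: str
    test_used: str  # t_test | mann_whitney | chi_square | fisher_exact
    statistic: float
    p_value: float
    summary_np: str
    summary_pe: str
    flags: list = field(default_factory=list)


def _smd(a: np.ndarray, b: np.ndarray) -> float:
    va, vb = a.var(ddof=1) if len(a) > 1 else 0.0, b.var(ddof=1) if len(b) > 1 else 0.0
    pooled = math.sqrt((va + vb) / 2)
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


def propensity_match(cases: pd.DataFrame, pool: pd.DataFrame, covariates,
                     ratio: int = 2, seed: int = 0,
                     caliper: float | None = None,
                     id_col: str = "patient_id") -> MatchResult:
    """Greedy 1:``ratio`` nearest-neighbor matching on the propensity logit.

    Cases are processed in seeded random order; controls are used at most
    once.  An optional caliper (max |logit| distance) rejects poor matches.
    """
    covariates = list(covariates)
    if len(pool) < ratio * len(cases):
        raise MatchingError(
            f"control pool of {len(pool)} cannot supply {ratio} matches for "
            f"each of {len(cases)} cases"
        )
    X = np.vstack([
        cases[covariates].to_numpy(float),
        pool[covariates].to_numpy(float),
    ])
    y = np.r_[np.ones(len(cases)), np.zeros(len(pool))]
    lr = LogisticRegression(C=np.inf, max_iter=5000).fit(X, y)
    logit = X @ lr.coef_.ravel() + lr.intercept_[0]
    case_logit, pool_logit = logit[: len(cases)], logit[len(cases):]

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cases))
    available = np.ones(len(pool), dtype=bool)
    matches: dict = {}
    for ci in order:
        cid = str(cases.iloc[ci][id_col])
        chosen = []
        for _ in range(ratio):
            dist = np.abs(pool_logit - case_logit[ci])
            dist[~available] = np.inf
            j = int(np.argmin(dist))
            if not np.isfinite(dist[j]) or (
                caliper is not None and dist[j] > caliper
            ):
                raise MatchingError(
                    f"control pool exhausted while matching case {cid}"
                )
            chosen.append(str(pool.iloc[j][id_col]))
            available[j] = False
        matches[cid] = chosen

    matched_ids = [c for ids in matches.values() for c in ids]
    matched_pool = pool[pool[id_col].astype(str).isin(matched_ids)]
    smd_before = {
        c: _smd(cases[c].to_numpy(float), pool[c].to_numpy(float))
        for c in covariates
    }
    smd_after = {
        c: _smd(cases[c].to_numpy(float), matched_pool[c].to_numpy(float))
        for c in covariates
    }
    return MatchResult(
        matches=matches,
        propensity_coef=dict(zip(covariates, lr.coef_.ravel().tolist())),
        smd_before=smd_before, smd_after=smd_after,
    )


def _iqr_summary(x: np.ndarray) -> str:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.1f} ({q1:.1f}, {q3:.1f})"


def compare_continuous(x_np, x_pe, alpha_normality: float = 0.05,
                       variable: str = "") -> ComparisonResult:
    """KS-gated comparison: t-test if both groups look normal, else
    Mann-Whitney U."""
    x_np = np.asarray(x_np, dtype=float)
    x_pe = np.asarray(x_pe, dtype=float)
    if len(x_np) < 3 or len(x_pe) < 3:
        raise ValueError("both groups need at least 3 values")
    flags = []
    if x_np.std() == 0 and x_pe.std() == 0:
        p = 1.0 if x_np.mean() == x_pe.mean() else 0.0
        flags.append("zero variance")
        return ComparisonResult(
            variable, "t_test", float("nan"), p,
            f"{x_np.mean():.1f} ({x_np.std(ddof=1):.1f})",
            f"{x_pe.mean():.1f} ({x_pe.std(ddof=1):.1f})", flags,
        )

    def _normal(x):
        if x.std(ddof=1) == 0:
            return False
        return stats.kstest(
            x, "norm", args=(x.mean(), x.std(ddof=1))
        ).pvalue > alpha_normality

    if _normal(x_np) and _normal(x_pe):
        res = stats.ttest_ind(x_np, x_pe, equal_var=True)
        return ComparisonResult(
            variable, "t_test", float(res.statistic), float(res.pvalue),
            f"{x_np.mean():.1f} ({x_np.std(ddof=1):.1f})",
            f"{x_pe.mean():.1f} ({x_pe.std(ddof=1):.1f})", flags,
        )
    res = stats.mannwhitneyu(x_np, x_pe, alternative="two-sided")
    return ComparisonResult(
        variable, "mann_whitney", float(res.statistic), float(res.pvalue),
        _iqr_summary(x_np), _iqr_summary(x_pe), flags,
    )


def fisher_exact_two_sided(table) -> float:
    """Probability-based two-sided Fisher exact p for a 2x2 table.

    Sums hypergeometric probabilities of all tables with the observed
    margins whose probability is at most the observed probability times
    (1 + 1e-7), in exact integer arithmetic.
    """
    (a, b), (c, d) = table
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        # one margin empty: only one table is possible
        if (r1 == 0 and r2 == 0) or n == 0:
            raise DegenerateTableError("empty table")
        return 1.0
    num_obs = math.comb(r1, a) * math.comb(r2, c)
    tol_num = num_obs * (10**7 + 1)
    num_sum = 0
    for aa in range(max(0, c1 - r2), min(r1, c1) + 1):
        num = math.comb(r1, aa) * math.comb(r2, c1 - aa)
        if num * 10**7 <= tol_num:
            num_sum += num
    return float(Fraction(num_sum, math.comb(n, c1)))


def compare_categorical(table, variable: str = "") -> ComparisonResult:
    """Fisher exact if any expected count < 5, else Yates chi-square."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if t.sum(axis=1).min() == 0 or t.sum(axis=0).min() == 0:
        raise DegenerateTableError("a table margin is empty")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()

    def _summary(row):
        return f"{int(row[0])} ({100 * row[0] / row.sum():.0f}%)"

    if (expected < 5).any():
        p = fisher_exact_two_sided(t.astype(int))
        return ComparisonResult(
            variable, "fisher_exact", float("nan"), p,
            _summary(t[0]), _summary(t[1]),
        )
    chi2, p, _, _ = stats.chi2_contingency(t, correction=True)
    return ComparisonResult(
        variable, "chi_square", float(chi2), float(p),
        _summary(t[0]), _summary(t[1]),
    )


CONTINUOUS_VARS = (
    "maternal_age", "bmi", "sbp", "dbp", "gestational_age_sampling",
    "gestational_age_delivery", "fetal_weight",
)
CATEGORICAL_VARS = ("cesarean", "preterm", "fetal_sex")


def table_one(subjects: pd.DataFrame) -> pd.DataFrame:
    """Build the group-comparison table from a subject covariate table."""
    np_rows = subjects[subjects["group"] == "NP"]
    pe_rows = subjects[subjects["group"] == "PE"]
    out = []
    for var in CONTINUOUS_VARS:
        if var not in subjects.columns:
            continue
        r = compare_continuous(np_rows[var], pe_rows[var], variable=var)
        out.append(r)
    for var in CATEGORICAL_VARS:
        if var not in subjects.columns:
            continue
        tab = [
            [int(np_rows[var].sum()), int((1 - np_rows[var]).sum())],
            [int(pe_rows[var].sum()), int((1 - pe_rows[var]).sum())],
        ]
        out.append(compare_categorical(tab, variable=var))
    return pd.DataFrame(
        [
            {
                "variable": r.variable, "NP": r.summary_np, "PE": r.summary_pe,
                "test": r.test_used, "p_value": r.p_value,
            }
            for r in out
        ]
    )
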