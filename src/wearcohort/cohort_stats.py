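"""Cross-sectional group comparisons and the missingness-mechanism check.

``compare_groups`` mirrors the applied convention "chi-squared, Student t or
Wilcoxon according to data type and normality": categorical outcomes go to a
chi-squared test on the contingency table (no continuity correction by
default), continuous outcomes are Shapiro-Wilk tested per group and routed
to Student's t when both groups look normal, otherwise to the Wilcoxon
rank-sum test.  ``two_way_anova`` adjusts a group difference for a second
factor with Type II sums of squares.

``hawkins_mcar_test`` implements the Hawkins (1981) k-sample procedure in the
Jamshidian-Jalal style for testing whether multivariate missingness is
consistent with MCAR: cases are grouped by missingness pattern and the
groups are compared for a common mean and covariance under EM-estimated
normal parameters.  The mean component is the classical sub-vector
chi-squared comparison of pattern-group means against the EM mean; the
covariance component completes the data with conditional-normal draws and
checks the uniformity of the per-case Hawkins F tail probabilities within
each group.  The two component p-values are Fisher-combined into the
overall p; p > alpha is consistent with MCAR.  No installed package offers
this test, so it is implemented here from the primary sources.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ComparisonResult",
    "compare_groups",
    "chi_squared_counts",
    "two_way_anova",
    "hawkins_mcar_test",
    "HawkinsResult",
]


@dataclass(frozen=True)
class ComparisonResult:
    measure: str
    test_used: str  # "t" | "wilcoxon" | "chi2" | "anova2"
    statistic: float
    p_value: float
    group_summaries: dict = field(default_factory=dict)
    notes: str = ""


def _normal_enough(x: np.ndarray, alpha: float) -> bool:
    return stats.shapiro(x).pvalue > alpha


def compare_groups(
    group_a: Sequence,
    group_b: Sequence,
    data_type: str = "continuous",
    normality_alpha: float = 0.05,
    measure: str = "",
    yates: bool = False,
) -> ComparisonResult:
    """Two-group comparison with data-type- and normality-adaptive test choice.

    Continuous data: Shapiro-Wilk per group at ``normality_alpha``; both
    normal -> two-tailed Student t (equal variances), otherwise Wilcoxon
    rank-sum (exact p when both groups are smaller than 25 and untied, else
    the normal approximation with tie correction).  Groups with fewer than 3
    observations cannot be normality-tested and fall back to Wilcoxon with a
    warning.  Categorical data: chi-squared on the contingency table.
    """
    if data_type == "categorical":
        a = pd.Series(list(group_a), dtype=object)
        b = pd.Series(list(group_b), dtype=object)
        cats = sorted(set(a) | set(b), key=str)
        table = np.array(
            [[int((a == c).sum()) for c in cats], [int((b == c).sum()) for c in cats]]
        )
        return chi_squared_counts(table, measure=measure, yates=yates)
    if data_type != "continuous":
        raise ValueError(f"unknown data_type {data_type!r}")

    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    notes = ""
    if min(len(a), len(b)) < 3:
        warnings.warn("a group has <3 observations; falling back to Wilcoxon", stacklevel=2)
        normal = False
        notes = "normality untestable (n<3)"
    else:
        normal = _normal_enough(a, normality_alpha) and _normal_enough(b, normality_alpha)
    summaries = {
        "a": {"n": len(a), "mean": float(np.mean(a)) if len(a) else np.nan,
              "sd": float(np.std(a, ddof=1)) if len(a) > 1 else np.nan},
        "b": {"n": len(b), "mean": float(np.mean(b)) if len(b) else np.nan,
              "sd": float(np.std(b, ddof=1)) if len(b) > 1 else np.nan},
    }
    if normal:
        res = stats.ttest_ind(a, b, equal_var=True)
        return ComparisonResult(measure, "t", float(res.statistic), float(res.pvalue), summaries, notes)
    tied = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (max(len(a), len(b)) < 25 and not tied) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return ComparisonResult(measure, "wilcoxon", float(res.statistic), float(res.pvalue), summaries, notes)


def chi_squared_counts(table: np.ndarray, measure: str = "", yates: bool = False) -> ComparisonResult:
    """Chi-squared test on an r x c contingency table of counts.

    Continuity correction off by default (toggle with ``yates``).
    """
    table = np.asarray(table)
    res = stats.chi2_contingency(table, correction=yates)
    summaries = {"table": table.tolist()}
    return ComparisonResult(measure, "chi2", float(res.statistic), float(res.pvalue), summaries)


def two_way_anova(
    values: Sequence[float],
    factor_a: Sequence,
    factor_b: Sequence,
    typ: int = 2,
) -> pd.DataFrame:
    """Two-way ANOVA (main effects, Type II SS) for adjusting a group
    difference for a second factor.

    Returns the ANOVA table with one row per factor (F and p).  A factor
    with a single level is a contract error.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"y": np.asarray(values, dtype=float),
                       "a": list(factor_a), "b": list(factor_b)})
    for name in ("a", "b"):
        if df[name].nunique() < 2:
            raise ValueError(f"factor {name!r} has a single level")
    if np.var(df["y"].to_numpy()) == 0.0:
        # constant outcome: no effect of either factor, by construction
        return pd.DataFrame(
            {"sum_sq": [0.0, 0.0, 0.0], "df": [np.nan, np.nan, np.nan],
             "F": [0.0, 0.0, np.nan], "PR(>F)": [1.0, 1.0, np.nan]},
            index=["C(a)", "C(b)", "Residual"],
        )
    model = smf.ols("y ~ C(a) + C(b)", data=df).fit()
    return sm.stats.anova_lm(model, typ=typ)


# ---------------------------------------------------------------------------
# Hawkins test of MCAR (Jamshidian-Jalal formulation)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HawkinsResult:
    statistic: float
    p_value: float
    n_patterns: int
    n_cases: int
    pattern_sizes: tuple[int, ...]
    p_mean: float = float("nan")
    p_covariance: float = float("nan")


def _em_mvn(X: np.ndarray, max_iter: int = 200, tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """EM estimates of (mu, Sigma) for multivariate normal data with NaNs."""
    n, p = X.shape
    mu = np.nanmean(X, axis=0)
    var = np.nanvar(X, axis=0)
    var[var <= 0] = 1.0
    sigma = np.diag(var)
    miss = np.isnan(X)
    patterns: dict[bytes, np.ndarray] = {}
    for key in np.unique(miss, axis=0):
        rows = np.flatnonzero((miss == key).all(axis=1))
        patterns[key.tobytes()] = rows
    for _ in range(max_iter):
        sum_x = np.zeros(p)
        sum_xx = np.zeros((p, p))
        for key, rows in patterns.items():
            m = np.frombuffer(key, dtype=bool)
            o = ~m
            Xr = X[rows]
            if not m.any():
                comp = Xr
                cov_add = np.zeros((p, p))
            else:
                Soo = sigma[np.ix_(o, o)]
                Smo = sigma[np.ix_(m, o)]
                Smm = sigma[np.ix_(m, m)]
                B = np.linalg.solve(Soo, Smo.T).T  # regression of missing on observed
                cond_cov = Smm - B @ Smo.T
                comp = Xr.copy()
                comp[:, m] = mu[m] + (Xr[:, o] - mu[o]) @ B.T
                cov_add = np.zeros((p, p))
                cov_add[np.ix_(m, m)] = cond_cov * len(rows)
            sum_x += comp.sum(axis=0)
            sum_xx += comp.T @ comp + cov_add
        new_mu = sum_x / n
        new_sigma = sum_xx / n - np.outer(new_mu, new_mu)
        new_sigma += np.eye(p) * 1e-10
        if np.max(np.abs(new_mu - mu)) < tol and np.max(np.abs(new_sigma - sigma)) < tol:
            mu, sigma = new_mu, new_sigma
            break
        mu, sigma = new_mu, new_sigma
    return mu, sigma


def _impute_conditional_draws(
    X: np.ndarray, mu: np.ndarray, sigma: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Complete the data by drawing missing entries from their conditional
    normal distribution given the observed entries (proper single
    imputation, preserving covariance structure in expectation)."""
    out = X.copy()
    miss = np.isnan(X)
    for i in np.flatnonzero(miss.any(axis=1)):
        m = miss[i]
        o = ~m
        if not o.any():
            out[i] = rng.multivariate_normal(mu, sigma)
            continue
        Soo = sigma[np.ix_(o, o)]
        Smo = sigma[np.ix_(m, o)]
        Smm = sigma[np.ix_(m, m)]
        B = np.linalg.solve(Soo, Smo.T).T
        cond_mu = mu[m] + B @ (X[i, o] - mu[o])
        cond_cov = Smm - B @ Smo.T
        cond_cov = (cond_cov + cond_cov.T) / 2
        out[i, m] = rng.multivariate_normal(cond_mu, cond_cov + np.eye(m.sum()) * 1e-12)
    return out


def _pattern_groups(X: np.ndarray) -> dict[bytes, np.ndarray]:
    miss = np.isnan(X)
    groups: dict[bytes, list[int]] = {}
    for i, row in enumerate(miss):
        groups.setdefault(row.tobytes(), []).append(i)
    return {k: np.array(v) for k, v in groups.items()}


def _mean_component(X: np.ndarray, mu: np.ndarray, sigma: np.ndarray,
                    groups: dict[bytes, np.ndarray]) -> float:
    """Sub-vector chi-squared comparison of pattern-group means vs the EM mean
    (the classical mean-equality component of MCAR testing)."""
    p = X.shape[1]
    d2 = 0.0
    df = 0
    for key, rows in groups.items():
        m = np.frombuffer(key, dtype=bool)
        o = ~m
        if not o.any() or len(rows) < 2:
            continue
        Xo = X[np.ix_(rows, np.flatnonzero(o))]
        diff = Xo.mean(axis=0) - mu[o]
        Soo = sigma[np.ix_(o, o)]
        d2 += len(rows) * float(diff @ np.linalg.solve(Soo, diff))
        df += int(o.sum())
    df -= p
    if df <= 0:
        return 1.0
    return float(stats.chi2.sf(d2, df))


def _covariance_component(
    comp: np.ndarray, groups: dict[bytes, np.ndarray], min_cases: int
) -> float:
    """Hawkins homoscedasticity component on completed data.

    Within each pattern group of size >= ``min_cases`` the per-case
    Mahalanobis distances to the group mean (pooled covariance) map to F
    tail probabilities that are Uniform(0,1) when all groups share one
    normal distribution; each group's uniformity is scored with a
    Cramer-von Mises test and the group p-values are Fisher-combined.
    """
    p = comp.shape[1]
    kept = {k: v for k, v in groups.items() if len(v) >= min_cases}
    if len(kept) < 2:
        raise ValueError(
            f"fewer than 2 missingness patterns with >= {min_cases} cases; "
            "lower min_cases or supply more data"
        )
    n_kept = sum(len(v) for v in kept.values())
    k = len(kept)
    dof2 = n_kept - k - p
    if dof2 <= 0:
        raise ValueError("too few cases for the Hawkins F statistic")
    S = np.zeros((p, p))
    for rows in kept.values():
        d = comp[rows] - comp[rows].mean(axis=0)
        S += d.T @ d
    S /= n_kept - k
    Sinv = np.linalg.inv(S)
    pvals = []
    for rows in kept.values():
        ni = len(rows)
        d = comp[rows] - comp[rows].mean(axis=0)
        dist = np.einsum("ij,jk,ik->i", d, Sinv, d)
        denom = (ni - 1) * (n_kept - k) - ni * dist
        F = np.where(denom > 0, (dof2 * ni * dist) / (p * np.maximum(denom, 1e-300)), np.inf)
        a = np.clip(stats.f.sf(F, p, dof2), 1e-300, 1.0)
        res = stats.cramervonmises(a, "uniform")
        pvals.append(max(min(float(res.pvalue), 1.0), 1e-300))
    T = -2.0 * float(np.sum(np.log(pvals)))
    return float(stats.chi2.sf(T, 2 * len(pvals)))


def hawkins_mcar_test(
    data: pd.DataFrame | np.ndarray,
    min_cases: int = 6,
    seed: int | np.random.Generator = 0,
    method: str = "combined",
) -> HawkinsResult:
    """Hawkins k-sample test of MCAR on a multivariate matrix with NaNs.

    Cases are grouped by missingness pattern and compared for equal means
    and covariances under an EM-estimated multivariate normal model:

    * mean component — chi-squared comparison of each pattern's observed
      sub-vector mean against the EM mean;
    * covariance component — the data are completed with conditional-normal
      draws (covariance-preserving in expectation; groups with fewer than
      ``min_cases`` cases are dropped from this component) and each group's
      Hawkins F tail probabilities are checked for uniformity.

    ``method``: ``"combined"`` (default) Fisher-combines the two component
    p-values; ``"mean"`` or ``"covariance"`` report a single component.  A
    small p is evidence against MCAR.  Complete data (a single missingness
    pattern) leave the test undefined.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("data must be 2-dimensional")
    X = X[~np.isnan(X).all(axis=1)]
    groups = _pattern_groups(X)
    if len(groups) < 2:
        raise ValueError("Hawkins test undefined: a single missingness pattern")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mu, sigma = _em_mvn(X)
    p_mean = _mean_component(X, mu, sigma, groups)
    comp = _impute_conditional_draws(X, mu, sigma, rng)
    p_cov = _covariance_component(comp, groups, min_cases)
    kept_sizes = tuple(sorted(len(v) for v in groups.values() if len(v) >= min_cases))

    if method == "combined":
        T = -2.0 * (np.log(max(p_mean, 1e-300)) + np.log(max(p_cov, 1e-300)))
        p_value = float(stats.chi2.sf(T, 4))
        statistic = float(T)
    elif method == "mean":
        statistic, p_value = float("nan"), p_mean
    elif method == "covariance":
        statistic, p_value = float("nan"), p_cov
    else:
        raise ValueError(f"unknown method {method!r}")
    return HawkinsResult(
        statistic, p_value, len(groups), sum(kept_sizes), kept_sizes,
        p_mean=p_mean, p_covariance=p_cov,
    )
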