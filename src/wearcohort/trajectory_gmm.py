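"""Growth mixture modelling of day-level wearable time series.

A finite mixture of latent-class linear growth trajectories: patient i in
class k follows ``y_it = a_k + b_k * t + u_i + e_it`` with a shared
patient random-intercept variance tau^2 and shared residual variance
sigma^2 across classes, class-specific intercept/slope, and Gaussian noise.
The time axis is days since each patient's own device deployment (day 0).

Fitting is by EM on the marginal patient-level likelihood (compound-symmetry
covariance, evaluated in closed form), with multiple seeded restarts and a
generalized M-step for the variance components (accepted only when it does
not decrease the expected complete-data log-likelihood, preserving the EM
monotonicity guarantee, which is asserted every iteration).  Classes are
canonicalized by ascending intercept so labels are stable; BIC uses the
number of patients as the sample size, the convention for subject-level
mixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp

__all__ = ["GmmSpec", "GmmFit", "fit_gmm", "select_classes", "classify_posterior", "series_from_days"]


@dataclass(frozen=True)
class GmmSpec:
    n_classes: int = 1
    n_restarts: int = 3
    max_iter: int = 200
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class GmmFit:
    spec: GmmSpec
    weights: np.ndarray  # (K,)
    intercepts: np.ndarray  # (K,)
    slopes: np.ndarray  # (K,)
    intercept_se: np.ndarray
    slope_se: np.ndarray
    intercept_p: np.ndarray
    slope_p: np.ndarray
    tau2: float  # patient random-intercept variance
    sigma2: float  # residual variance
    loglike: float
    bic: float
    posterior: np.ndarray  # (n_patients, K)
    patient_ids: list
    converged: bool
    n_iter: int

    @property
    def modal_classes(self) -> np.ndarray:
        return np.argmax(self.posterior, axis=1)

    @property
    def modal_sizes(self) -> np.ndarray:
        return np.bincount(self.modal_classes, minlength=self.spec.n_classes)


def series_from_days(summaries: pd.DataFrame, measure: str) -> tuple[list, list[np.ndarray], list[np.ndarray]]:
    """Patient series (time in days since own first day, values) from day
    summaries; patients contributing < 2 days are dropped."""
    ids, times, values = [], [], []
    for pid, grp in summaries.groupby("patient_id", sort=True):
        g = grp.dropna(subset=[measure])
        if len(g) < 2:
            continue
        dates = pd.to_datetime(g["date"])
        t = (dates - dates.min()).dt.days.to_numpy(dtype=float)
        ids.append(pid)
        times.append(t)
        values.append(g[measure].to_numpy(dtype=float))
    return ids, times, values


def _patient_loglik(t: np.ndarray, y: np.ndarray, a: float, b: float, tau2: float, sigma2: float) -> float:
    """Gaussian log-density of one patient's series under compound symmetry."""
    n = len(y)
    r = y - (a + b * t)
    s = sigma2 + n * tau2
    logdet = (n - 1) * np.log(sigma2) + np.log(s)
    quad = (r @ r - (tau2 / s) * r.sum() ** 2) / sigma2
    return -0.5 * (n * np.log(2 * np.pi) + logdet + quad)


def _loglik_matrix(times, values, a, b, tau2, sigma2) -> np.ndarray:
    K = len(a)
    out = np.empty((len(times), K))
    for i, (t, y) in enumerate(zip(times, values)):
        for k in range(K):
            out[i, k] = _patient_loglik(t, y, a[k], b[k], tau2, sigma2)
    return out


def _gls_update(times, values, resp_k, tau2, sigma2) -> tuple[np.ndarray, np.ndarray]:
    """Responsibility-weighted GLS for one class's (intercept, slope).

    Returns (theta, covariance of theta)."""
    XtX = np.zeros((2, 2))
    Xty = np.zeros(2)
    for (t, y), w in zip(zip(times, values), resp_k):
        if w < 1e-12:
            continue
        n = len(y)
        s = sigma2 + n * tau2
        X = np.column_stack([np.ones(n), t])
        # Sigma^{-1} X and Sigma^{-1} y via Woodbury for compound symmetry
        SX = (X - (tau2 / s) * X.sum(axis=0)) / sigma2
        XtX += w * X.T @ SX
        Xty += w * SX.T @ y
    cov = np.linalg.inv(XtX)
    return cov @ Xty, cov


def _fit_once(times, values, K, rng, max_iter, tol) -> dict | None:
    n_pat = len(times)
    pat_means = np.array([y.mean() for y in values])
    order = np.sort(pat_means)
    # class intercept init at spread quantiles, jittered per restart
    qs = (np.arange(K) + 0.5) / K
    a = np.quantile(order, qs) + rng.normal(0, max(pat_means.std(), 1e-3) * 0.1, K)
    b = np.zeros(K)
    resid0 = np.concatenate([y - y.mean() for y in values])
    sigma2 = max(float(np.var(resid0)), 1e-6)
    tau2 = max(float(np.var(pat_means)) / max(K, 1), 1e-6)
    weights = np.full(K, 1.0 / K)

    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        llmat = _loglik_matrix(times, values, a, b, tau2, sigma2)
        joint = llmat + np.log(weights)
        norm = logsumexp(joint, axis=1)
        ll = float(norm.sum())
        if ll + 1e-8 * max(1.0, abs(ll)) < ll_old:
            raise AssertionError(f"EM log-likelihood decreased: {ll_old} -> {ll}")
        resp = np.exp(joint - norm[:, None])
        if ll - ll_old < tol * max(1.0, abs(ll)) and it > 1:
            converged = True
            ll_old = ll
            break
        ll_old = ll
        # M-step
        weights = resp.mean(axis=0)
        if weights.min() < 1.0 / (10.0 * n_pat):
            return None  # empty class -> trigger restart
        covs = []
        for k in range(K):
            theta, cov = _gls_update(times, values, resp[:, k], tau2, sigma2)
            a[k], b[k] = theta
            covs.append(cov)

        def neg_q(logv, a=a, b=b, resp=resp):
            t2, s2 = np.exp(logv)
            ml = _loglik_matrix(times, values, a, b, t2, s2)
            return -float((resp * ml).sum())

        x0 = np.log([tau2, sigma2])
        res = optimize.minimize(neg_q, x0, method="Nelder-Mead",
                                options={"maxiter": 60, "xatol": 1e-4, "fatol": 1e-6})
        if res.fun < neg_q(x0):  # generalized M-step: accept only improvements
            tau2, sigma2 = np.exp(res.x)
            tau2 = max(tau2, 1e-10)
            sigma2 = max(sigma2, 1e-10)

    # final responsibilities and per-class GLS covariance at the optimum
    llmat = _loglik_matrix(times, values, a, b, tau2, sigma2)
    joint = llmat + np.log(weights)
    norm = logsumexp(joint, axis=1)
    resp = np.exp(joint - norm[:, None])
    ses = np.empty((K, 2))
    for k in range(K):
        _, cov = _gls_update(times, values, resp[:, k], tau2, sigma2)
        ses[k] = np.sqrt(np.diag(cov))
    return {
        "a": a, "b": b, "weights": weights, "tau2": tau2, "sigma2": sigma2,
        "loglike": float(norm.sum()), "posterior": resp, "converged": converged,
        "n_iter": it, "se": ses,
    }


def fit_gmm(
    summaries_or_series,
    spec: GmmSpec | None = None,
    measure: str = "mvpa_minutes",
) -> GmmFit:
    """Fit a K-class linear growth mixture to day-level patient series.

    Accepts either a day-summaries frame (with ``patient_id``, ``date`` and
    the measure column) or a prebuilt ``(ids, times, values)`` triple from
    :func:`series_from_days`.  The best of ``n_restarts`` seeded runs by
    log-likelihood is returned; a restart whose mixture collapses (a class
    proportion below 1/(10 n)) is discarded.  Non-convergence within
    ``max_iter`` is flagged, returning the best fit so far.
    """
    spec = spec or GmmSpec()
    if isinstance(summaries_or_series, tuple):
        ids, times, values = summaries_or_series
    else:
        ids, times, values = series_from_days(summaries_or_series, measure)
    if not ids:
        raise ValueError("no patient contributes >= 2 days")
    K = spec.n_classes
    rng = np.random.default_rng(spec.seed)
    best = None
    for _ in range(max(spec.n_restarts, 1)):
        run = _fit_once(times, values, K, rng, spec.max_iter, spec.tol)
        if run is None:
            continue
        if best is None or run["loglike"] > best["loglike"]:
            best = run
    if best is None:
        raise RuntimeError("all restarts collapsed to an empty class")

    order = np.argsort(best["a"])  # canonical: ascending intercept
    a, b = best["a"][order], best["b"][order]
    w = best["weights"][order]
    ses = best["se"][order]
    post = best["posterior"][:, order]
    n_pat = len(ids)
    n_params = (K - 1) + 2 * K + 2
    bic = -2.0 * best["loglike"] + n_params * np.log(n_pat)
    z_a = a / ses[:, 0]
    z_b = np.divide(b, ses[:, 1], out=np.zeros(K), where=ses[:, 1] > 0)
    return GmmFit(
        spec=spec,
        weights=w,
        intercepts=a,
        slopes=b,
        intercept_se=ses[:, 0],
        slope_se=ses[:, 1],
        intercept_p=2 * stats.norm.sf(np.abs(z_a)),
        slope_p=2 * stats.norm.sf(np.abs(z_b)),
        tau2=float(best["tau2"]),
        sigma2=float(best["sigma2"]),
        loglike=best["loglike"],
        bic=float(bic),
        posterior=post,
        patient_ids=list(ids),
        converged=best["converged"],
        n_iter=best["n_iter"],
    )


def select_classes(
    summaries_or_series,
    k_max: int,
    spec: GmmSpec | None = None,
    measure: str = "mvpa_minutes",
) -> tuple[pd.DataFrame, int, dict[int, GmmFit]]:
    """Fit K = 1..k_max with common seeds and choose the lowest BIC.

    Ties break toward the smaller K.  A K whose restarts all collapse is
    skipped with a warning row.  Returns (table, chosen K, fits by K).
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    spec = spec or GmmSpec()
    rows = []
    fits: dict[int, GmmFit] = {}
    for K in range(1, k_max + 1):
        try:
            fit = fit_gmm(summaries_or_series, GmmSpec(
                n_classes=K, n_restarts=spec.n_restarts, max_iter=spec.max_iter,
                tol=spec.tol, seed=spec.seed), measure=measure)
        except RuntimeError as exc:
            rows.append({"K": K, "bic": np.nan, "loglike": np.nan, "converged": False,
                         "note": str(exc)})
            continue
        fits[K] = fit
        rows.append({"K": K, "bic": fit.bic, "loglike": fit.loglike,
                     "converged": fit.converged, "note": ""})
    table = pd.DataFrame(rows)
    feasible = table.dropna(subset=["bic"])
    if feasible.empty:
        raise RuntimeError("no class count could be fitted")
    chosen = int(feasible.sort_values(["bic", "K"], kind="mergesort").iloc[0]["K"])
    return table, chosen, fits


def classify_posterior(fit: GmmFit) -> pd.DataFrame:
    """Modal class per patient plus the fit's relative entropy.

    Relative entropy is 1 - sum(-p log p) / (n log K), in [0, 1]; 1 means
    perfectly separated classes.  For K=1 it is defined as 1.
    """
    post = fit.posterior
    n, K = post.shape
    if K == 1:
        rel_entropy = 1.0
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(post > 0, post * np.log(post), 0.0)
        rel_entropy = 1.0 + plogp.sum() / (n * np.log(K))
    out = pd.DataFrame({
        "patient_id": fit.patient_ids,
        "modal_class": fit.modal_classes,
        "max_posterior": post.max(axis=1),
    })
    out.attrs["relative_entropy"] = float(rel_entropy)
    return out
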