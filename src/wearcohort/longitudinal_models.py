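"""Baseline-adjusted linear mixed-effects models of PRO trajectories.

The core model regresses a PRO score on time (0/1/2 in 3-month units, or
categorical wave labels), MVPA group (active vs inactive), their
interaction, and optionally the patient's baseline score, with a random
intercept per patient, fitted by REML.  The time-by-group interaction is the
quantity of interest: with linear time coding its coefficient is the extra
change per 3 months associated with being MVPA-active.

Two baseline-handling variants are shipped: the covariate-plus-baseline-rows
form, and the ANCOVA-style form that keeps the baseline score as a covariate
but models only the follow-up waves as outcomes (avoiding the outcome-equals-
covariate degeneracy at wave 0).  Model comparison across fixed-effect sets
uses ML (not REML) AIC; diagnostics are the Shapiro-Wilk test on conditional
residuals and a White-type Lagrange-multiplier test of residual variance
homogeneity against the fitted values.

Inference uses Wald statistics on a t reference with within/between
degrees of freedom (within-patient terms: observations minus patients minus
within-term count; between-patient terms: patients minus between-term
count), a standard close approximation to Satterthwaite df for
random-intercept designs of this shape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_wearable import WAVES

__all__ = [
    "LmeSpec",
    "LmeFit",
    "fit_lme",
    "select_model",
    "diagnose",
    "sensitivity_grid",
    "MEANINGFUL_CHANGE_T",
]

#: General meaningful-change threshold for group comparisons on T-score scales.
MEANINGFUL_CHANGE_T = 3.0

_WAVE_TIME = {w: float(i) for i, w in enumerate(WAVES)}  # 3-month units


@dataclass(frozen=True)
class LmeSpec:
    """Specification of one mixed-model variant."""

    outcome: str = "value"
    time_coding: str = "linear"  # "linear" | "categorical"
    baseline_covariate: bool = True
    include_baseline_rows: bool = True
    interaction: bool = True
    reml: bool = True

    def __post_init__(self) -> None:
        if self.time_coding not in ("linear", "categorical"):
            raise ValueError(f"unknown time_coding {self.time_coding!r}")


@dataclass
class LmeFit:
    spec: LmeSpec
    params: pd.DataFrame  # index term; columns estimate, se, df, ci_lo, ci_hi, p
    aic: float
    loglike: float
    n_obs: int
    n_patients: int
    converged: bool
    singular: bool
    degenerate: bool
    resid: np.ndarray
    fitted: np.ndarray
    marginal_resid: np.ndarray
    marginal_fitted: np.ndarray
    re_var: float
    resid_var: float
    obs_index: pd.MultiIndex  # (patient_id, wave) of modelled rows
    meaningful_change: bool | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def interaction_term(self) -> str | None:
        cands = [t for t in self.params.index if ":" in t]
        if not cands:
            return None
        return cands[-1]  # linear: time:group; categorical: time_m6:group last


def _prepare(data: pd.DataFrame, spec: LmeSpec) -> pd.DataFrame:
    """Long input -> modelling frame with time, group indicator, baseline."""
    df = data.copy()
    required = {"patient_id", "wave", "group", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"long table missing columns {sorted(missing)}")
    if not set(df["wave"]) <= set(WAVES):
        raise ValueError(f"waves must be within {WAVES}")
    df["time"] = df["wave"].map(_WAVE_TIME)
    df["g"] = (df["group"] == "active").astype(float)
    base = df[df["wave"] == "baseline"].set_index("patient_id")["value"]
    df["baseline_score"] = df["patient_id"].map(base)
    df = df.dropna(subset=["value"])
    if spec.baseline_covariate:
        df = df.dropna(subset=["baseline_score"])
    if not spec.include_baseline_rows:
        df = df[df["wave"] != "baseline"]
    if df.empty:
        raise ValueError("no usable observations for this outcome")
    if df["wave"].nunique() < 2:
        raise ValueError("need at least 2 waves represented")
    return df.reset_index(drop=True)


def _design(df: pd.DataFrame, spec: LmeSpec) -> tuple[np.ndarray, list[str], list[bool]]:
    """Design matrix, term names, and a per-term within-patient flag."""
    cols: list[np.ndarray] = [np.ones(len(df))]
    names = ["const"]
    within = [False]
    if spec.time_coding == "linear":
        cols.append(df["time"].to_numpy())
        names.append("time")
        within.append(True)
        time_terms = [("time", df["time"].to_numpy())]
    else:
        time_terms = []
        for w in WAVES[1:]:
            ind = (df["wave"] == w).astype(float).to_numpy()
            cols.append(ind)
            names.append(f"time_{w}")
            within.append(True)
            time_terms.append((f"time_{w}", ind))
    cols.append(df["g"].to_numpy())
    names.append("group")
    within.append(False)
    if spec.interaction:
        for tname, tcol in time_terms:
            cols.append(tcol * df["g"].to_numpy())
            names.append(f"{tname}:group")
            within.append(True)
    if spec.baseline_covariate:
        cols.append(df["baseline_score"].to_numpy())
        names.append("baseline_score")
        within.append(False)
    return np.column_stack(cols), names, within


def fit_lme(data: pd.DataFrame, spec: LmeSpec | None = None) -> LmeFit:
    """Fit one mixed-model variant on a long PRO table.

    ``data`` columns: ``patient_id, wave, group, value`` (one row per
    patient-wave observation of one outcome; missing outcomes simply have no
    row or a NaN value).  Non-convergence is reported on the fit, never
    silently swallowed; a singular (zero) random-intercept variance is
    flagged but the fit is still returned.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    spec = spec or LmeSpec()
    df = _prepare(data, spec)
    exog, names, within = _design(df, spec)
    endog = df["value"].to_numpy(dtype=float)
    groups = df["patient_id"].to_numpy()
    n_obs = len(endog)
    n_pat = df["patient_id"].nunique()
    degenerate = bool(np.var(endog) < 1e-12)

    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = sm.MixedLM(endog, exog, groups=groups)
        try:
            res = model.fit(reml=spec.reml)
            converged = bool(res.converged)
        except Exception:
            # fall back to a more robust optimizer before giving up
            try:
                res = model.fit(reml=spec.reml, method="powell", maxiter=500)
                converged = bool(res.converged)
            except Exception as exc:  # pragma: no cover - pathological input
                raise RuntimeError(f"mixed model failed to fit: {exc}") from exc

    params = np.asarray(res.fe_params, dtype=float)
    se = np.asarray(res.bse_fe, dtype=float)
    re_var = float(np.squeeze(res.cov_re)) if res.cov_re.size else 0.0
    resid_var = float(res.scale)
    singular = re_var < 1e-8 * max(resid_var, 1e-12)

    n_within = sum(within)
    n_between = len(within) - n_within
    df_within = max(n_obs - n_pat - n_within, 1)
    df_between = max(n_pat - n_between, 1)
    dfs = np.where(within, df_within, df_between).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = params / se
        pvals = 2.0 * stats.t.sf(np.abs(tvals), dfs)
        crit = stats.t.ppf(0.975, dfs)
    table = pd.DataFrame(
        {
            "estimate": params,
            "se": se,
            "df": dfs,
            "ci_lo": params - crit * se,
            "ci_hi": params + crit * se,
            "p": pvals,
        },
        index=names,
    )
    fitted = exog @ params  # marginal fit (fixed effects only)
    # conditional residuals: subtract predicted random effects as well
    re_pred = np.zeros(n_obs)
    try:
        re_dict = res.random_effects
        for i, g in enumerate(groups):
            re_pred[i] = float(np.squeeze(re_dict[g].iloc[0])) if len(re_dict[g]) else 0.0
    except (ValueError, np.linalg.LinAlgError):
        pass  # singular random-effect covariance: BLUPs undefined, use zeros
    cond_fitted = fitted + re_pred
    resid = endog - cond_fitted

    llf = float(res.llf)
    k = len(params) + 2  # fixed effects + random-intercept var + residual var
    aic = 2 * k - 2 * llf

    fit = LmeFit(
        spec=spec,
        params=table,
        aic=aic,
        loglike=llf,
        n_obs=n_obs,
        n_patients=n_pat,
        converged=converged,
        singular=singular,
        degenerate=degenerate,
        resid=resid,
        fitted=cond_fitted,
        marginal_resid=endog - fitted,
        marginal_fitted=fitted,
        re_var=re_var,
        resid_var=resid_var,
        obs_index=pd.MultiIndex.from_arrays([df["patient_id"], df["wave"]]),
    )
    term = fit.interaction_term
    if term is not None and spec.outcome.endswith("_t"):
        fit.meaningful_change = bool(abs(table.loc[term, "estimate"]) >= MEANINGFUL_CHANGE_T)
    return fit


def select_model(candidates: Sequence[LmeSpec], data: pd.DataFrame) -> pd.DataFrame:
    """Rank candidate fixed-effect structures by ML AIC on a common
    observation set.

    All candidates are refitted with ML (REML log-likelihoods are not
    comparable across fixed-effect sets).  Candidates whose NA handling
    yields different observation sets are a contract error.
    """
    fits = []
    obs_sets = []
    for spec in candidates:
        fit = fit_lme(data, replace(spec, reml=False))
        fits.append(fit)
        obs_sets.append(frozenset(fit.obs_index))
    if len(set(obs_sets)) > 1:
        raise ValueError("candidate models use non-nested observation sets; AIC not comparable")
    rows = []
    best = min(f.aic for f in fits)
    for spec, fit in zip(candidates, fits):
        rows.append(
            {
                "time_coding": spec.time_coding,
                "interaction": spec.interaction,
                "baseline_covariate": spec.baseline_covariate,
                "include_baseline_rows": spec.include_baseline_rows,
                "aic": fit.aic,
                "delta_aic": fit.aic - best,
                "loglike": fit.loglike,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows).sort_values("aic", kind="mergesort").reset_index(drop=True)


def diagnose(fit: LmeFit) -> dict:
    """Residual diagnostics: Shapiro-Wilk normality and a White-type LM test.

    Shapiro-Wilk runs on the conditional residuals (the standard mixed-model
    practice).  The LM test regresses squared marginal residuals
    (y - X beta-hat) on the marginal fitted values and their squares;
    n R^2 is chi-squared with 2 df under homoscedasticity.  Marginal
    residuals are used because predicted-random-effect shrinkage couples
    conditional residuals to the fitted values even under a correct model;
    within-patient correlation makes the test mildly conservative.  Neither
    test triggers refitting.
    """
    e = np.asarray(fit.resid, dtype=float)
    if len(e) < 3:
        raise ValueError("need at least 3 residuals to diagnose")
    if np.var(e) < 1e-14 or np.var(fit.marginal_resid) < 1e-14:
        return {"shapiro_p": np.nan, "white_lm_p": np.nan, "degenerate": True}
    sw = stats.shapiro(e)
    e = np.asarray(fit.marginal_resid, dtype=float)
    f = np.asarray(fit.marginal_fitted, dtype=float)
    Z = np.column_stack([np.ones_like(f), f, f**2])
    y = e**2
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    yhat = Z @ beta
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    lm = len(e) * r2
    out = {
        "shapiro_w": float(sw.statistic),
        "shapiro_p": float(sw.pvalue),
        "white_lm": float(lm),
        "white_lm_p": float(stats.chi2.sf(lm, 2)),
        "degenerate": False,
    }
    fit.diagnostics = out
    return out


def sensitivity_grid(
    data: pd.DataFrame,
    base_spec: LmeSpec,
    label_variants: dict[str, pd.DataFrame] | None = None,
    extra_variants: Sequence[str] = ("categorical_time", "drop_single_wave_patients",
                                     "toggle_baseline_covariate"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Refit the interaction model across perturbed analysis choices.

    ``data`` is the base long table; ``label_variants`` maps variant name ->
    a labels frame (``patient_id, label``) that re-assigns groups (from
    :func:`wearcohort.phenotyping.perturb_labels`).  ``extra_variants`` are
    structural: categorical time labels, dropping patients observed at a
    single wave, and excluding baseline rows.  Each row reports the
    interaction estimate, CI, p and whether sign and significance match the
    base fit; a variant that empties a group is marked infeasible.
    """
    base_fit = fit_lme(data, base_spec)
    term = base_fit.interaction_term
    base_est = float(base_fit.params.loc[term, "estimate"])
    base_sig = bool(base_fit.params.loc[term, "p"] < alpha)

    def row_for(name: str, d: pd.DataFrame, spec: LmeSpec) -> dict:
        try:
            if d[d["group"] == "active"]["patient_id"].nunique() == 0 or \
               d[d["group"] == "inactive"]["patient_id"].nunique() == 0:
                raise ValueError("a group is empty")
            fit = fit_lme(d, spec)
        except (ValueError, RuntimeError) as exc:
            return {"variant": name, "feasible": False, "note": str(exc)}
        t = fit.interaction_term
        est = float(fit.params.loc[t, "estimate"])
        p = float(fit.params.loc[t, "p"])
        return {
            "variant": name,
            "feasible": True,
            "term": t,
            "estimate": est,
            "ci_lo": float(fit.params.loc[t, "ci_lo"]),
            "ci_hi": float(fit.params.loc[t, "ci_hi"]),
            "p": p,
            "n_patients": fit.n_patients,
            "sign_stable": bool(np.sign(est) == np.sign(base_est) and (p < alpha) == base_sig),
            "note": "",
        }

    rows = [
        {
            "variant": "base",
            "feasible": True,
            "term": term,
            "estimate": base_est,
            "ci_lo": float(base_fit.params.loc[term, "ci_lo"]),
            "ci_hi": float(base_fit.params.loc[term, "ci_hi"]),
            "p": float(base_fit.params.loc[term, "p"]),
            "n_patients": base_fit.n_patients,
            "sign_stable": True,
            "note": "",
        }
    ]
    for name, labels in (label_variants or {}).items():
        d = data.drop(columns=["group"]).merge(
            labels[labels["label"].isin(["active", "inactive"])][["patient_id", "label"]],
            on="patient_id",
        ).rename(columns={"label": "group"})
        rows.append(row_for(name, d, base_spec))
    for name in extra_variants:
        if name == "categorical_time":
            rows.append(row_for(name, data, replace(base_spec, time_coding="categorical")))
        elif name == "drop_single_wave_patients":
            counts = data.dropna(subset=["value"]).groupby("patient_id")["wave"].nunique()
            keep = counts[counts >= 2].index
            rows.append(row_for(name, data[data["patient_id"].isin(keep)], base_spec))
        elif name == "exclude_baseline_rows":
            rows.append(row_for(name, data, replace(base_spec, include_baseline_rows=False)))
        elif name == "toggle_baseline_covariate":
            rows.append(row_for(
                name, data,
                replace(base_spec, baseline_covariate=not base_spec.baseline_covariate)))
        else:
            raise ValueError(f"unknown sensitivity variant {name!r}")
    return pd.DataFrame(rows)
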