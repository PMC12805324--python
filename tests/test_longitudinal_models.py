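"""Mixed-effects PRO trajectory models: estimation, selection, diagnostics."""

from __future__ import annotations

import subprocess
import textwrap
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from wearcohort.longitudinal_models import LmeSpec, diagnose, fit_lme, select_model, sensitivity_grid
from wearcohort.synthetic_data import CohortConfig, generate_profiles, generate_pro_long


def _simulated_long(seed=0, interaction=-4.21, dropout=(0.0, 0.3, 0.3), n_active=41, n_inactive=41):
    from wearcohort.synthetic_data import DEFAULT_PRO_MEASURES, ProMeasureConfig

    rng = np.random.default_rng(seed)
    config = CohortConfig(n_active=n_active, n_inactive=n_inactive, dropout=dropout)
    profiles = generate_profiles(config, rng)
    base = DEFAULT_PRO_MEASURES["social_roles_t"]
    params = replace(base, interaction=interaction)
    long, truth = generate_pro_long(profiles, config, rng, "social_roles_t", params)
    return long, truth


class TestFitLme:
    def test_recovers_interaction_direction_and_scale(self):
        long, truth = _simulated_long(seed=3)
        fit = fit_lme(long, LmeSpec(outcome="social_roles_t"))
        est = fit.params.loc[fit.interaction_term, "estimate"]
        assert est == pytest.approx(-4.21, abs=3.0)  # single replicate, wide band
        assert fit.converged
        assert fit.n_patients == 82

    def test_constant_outcome_flagged_degenerate(self):
        rows = []
        for pid in ("P1", "P2", "P3", "P4"):
            for w in ("baseline", "m3", "m6"):
                rows.append({"patient_id": pid, "wave": w,
                             "group": "active" if pid in ("P1", "P2") else "inactive",
                             "value": 50.0})
        fit = fit_lme(pd.DataFrame(rows), LmeSpec(baseline_covariate=False))
        assert fit.degenerate
        assert fit.params.loc["time", "estimate"] == pytest.approx(0.0, abs=1e-8)
        assert fit.params.loc["time:group", "estimate"] == pytest.approx(0.0, abs=1e-8)

    def test_interaction_invariant_to_outcome_shift(self):
        long, _ = _simulated_long(seed=4)
        fit1 = fit_lme(long, LmeSpec())
        shifted = long.copy()
        shifted["value"] += 100.0
        fit2 = fit_lme(shifted, LmeSpec())
        assert fit1.params.loc["time:group", "estimate"] == pytest.approx(
            fit2.params.loc["time:group", "estimate"], abs=1e-6)

    def test_affine_outcome_gives_affine_coefficients(self):
        """A T-score outcome that is an affine map of the raw score yields
        proportionally scaled slope coefficients."""
        long, _ = _simulated_long(seed=5)
        raw = long.copy()
        raw["value"] = (long["value"] - 10.0) / 2.0
        fit_t = fit_lme(long, LmeSpec(baseline_covariate=False))
        fit_raw = fit_lme(raw, LmeSpec(baseline_covariate=False))
        assert fit_raw.params.loc["time:group", "estimate"] == pytest.approx(
            fit_t.params.loc["time:group", "estimate"] / 2.0, rel=1e-4)

    def test_zero_random_variance_matches_ols(self):
        """With no patient effect in the data the LME fixed effects match OLS."""
        import statsmodels.api as sm

        rng = np.random.default_rng(6)
        rows = []
        for i in range(60):
            g = "active" if i < 30 else "inactive"
            for t, w in enumerate(("baseline", "m3", "m6")):
                rows.append({"patient_id": f"P{i:03d}", "wave": w, "group": g,
                             "value": 50 + 2 * t + (3 * t if g == "active" else 0)
                             + rng.normal(0, 1)})
        long = pd.DataFrame(rows)
        fit = fit_lme(long, LmeSpec(baseline_covariate=False))
        g = (long["group"] == "active").astype(float)
        t = long["wave"].map({"baseline": 0, "m3": 1, "m6": 2}).astype(float)
        X = sm.add_constant(np.column_stack([t, g, t * g]))
        ols = sm.OLS(long["value"], X).fit()
        np.testing.assert_allclose(fit.params["estimate"].to_numpy(), ols.params, atol=0.05)

    def test_all_missing_outcome_is_error(self):
        long = pd.DataFrame({"patient_id": ["P1"] * 3, "wave": ["baseline", "m3", "m6"],
                             "group": ["active"] * 3, "value": [np.nan] * 3})
        with pytest.raises(ValueError):
            fit_lme(long, LmeSpec())

    def test_meaningful_change_annotation(self):
        long, _ = _simulated_long(seed=7, interaction=-6.0)
        fit = fit_lme(long, LmeSpec(outcome="social_roles_t"))
        assert fit.meaningful_change is True


class TestAgainstLmerTest:
    def test_fixed_effects_match_lmertest(self, tmp_path):
        """Independent oracle: the same REML model fitted by lmerTest in R
        agrees on fixed effects and their standard errors."""
        long, _ = _simulated_long(seed=10)
        fit = fit_lme(long, LmeSpec(baseline_covariate=False))
        csv = tmp_path / "long.csv"
        long.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(lmerTest))
            d <- read.csv("{csv}")
            d$time <- ifelse(d$wave == "baseline", 0, ifelse(d$wave == "m3", 1, 2))
            d$g <- as.numeric(d$group == "active")
            m <- lmer(value ~ time * g + (1 | patient_id), data = d, REML = TRUE)
            co <- summary(m)$coefficients
            write.csv(co, "{tmp_path}/coef.csv")
        """))
        proc = subprocess.run(["Rscript", str(script)], capture_output=True, text=True, timeout=300)
        assert proc.returncode == 0, proc.stderr
        ref = pd.read_csv(tmp_path / "coef.csv", index_col=0)
        ours = fit.params
        mapping = {"(Intercept)": "const", "time": "time", "g": "group", "time:g": "time:group"}
        for rname, oname in mapping.items():
            assert ours.loc[oname, "estimate"] == pytest.approx(ref.loc[rname, "Estimate"], abs=1e-3)
            assert ours.loc[oname, "se"] == pytest.approx(ref.loc[rname, "Std. Error"], rel=0.02)


class TestModelSelection:
    def test_duplicated_spec_identical_aic(self):
        long, _ = _simulated_long(seed=8)
        spec = LmeSpec()
        table = select_model([spec, spec], long)
        assert table["aic"].iloc[0] == pytest.approx(table["aic"].iloc[1], abs=1e-8)

    def test_interaction_model_wins_when_true(self):
        wins = 0
        reps = 12
        for i in range(reps):
            long, _ = _simulated_long(seed=200 + i, interaction=-6.0,
                                      n_active=120, n_inactive=120, dropout=(0, 0, 0))
            table = select_model(
                [LmeSpec(interaction=True), LmeSpec(interaction=False)], long)
            if bool(table.iloc[0]["interaction"]):
                wins += 1
        assert wins >= reps - 1

    def test_non_nested_observation_sets_rejected(self):
        long, _ = _simulated_long(seed=9)
        specs = [LmeSpec(include_baseline_rows=True), LmeSpec(include_baseline_rows=False)]
        with pytest.raises(ValueError, match="observation sets"):
            select_model(specs, long)


class TestDiagnostics:
    def test_gaussian_fit_passes_both_tests(self):
        long, _ = _simulated_long(seed=11)
        fit = fit_lme(long, LmeSpec(baseline_covariate=False))
        diag = diagnose(fit)
        assert diag["shapiro_p"] > 0.001
        assert diag["white_lm_p"] > 0.001

    def test_heteroscedastic_residuals_detected(self):
        """White LM flags variance growing with the fitted values."""
        rng = np.random.default_rng(12)
        detected = 0
        for i in range(5):
            rows = []
            for j in range(82):
                g = "active" if j < 41 else "inactive"
                mu = 30 if g == "active" else 60
                for t, w in enumerate(("baseline", "m3", "m6")):
                    m = mu + 5 * t
                    rows.append({"patient_id": f"P{j:03d}", "wave": w, "group": g,
                                 "value": m + rng.normal(0, 0.08 * m)})
            fit = fit_lme(pd.DataFrame(rows), LmeSpec(baseline_covariate=False))
            if diagnose(fit)["white_lm_p"] < 0.05:
                detected += 1
        assert detected >= 3

    def test_too_few_residuals_is_error(self):
        long, _ = _simulated_long(seed=13)
        fit = fit_lme(long, LmeSpec())
        fit.resid = fit.resid[:2]
        with pytest.raises(ValueError):
            diagnose(fit)


class TestSensitivityGrid:
    def test_identity_variant_equals_base(self):
        long, _ = _simulated_long(seed=14)
        labels = (long[["patient_id", "group"]].drop_duplicates()
                  .rename(columns={"group": "label"}))
        grid = sensitivity_grid(long, LmeSpec(), label_variants={"identity": labels},
                                extra_variants=())
        base = grid[grid["variant"] == "base"].iloc[0]
        ident = grid[grid["variant"] == "identity"].iloc[0]
        assert ident["estimate"] == pytest.approx(base["estimate"], abs=1e-8)

    def test_sign_stability_under_strong_effect(self):
        long, _ = _simulated_long(seed=15, interaction=-8.0)
        labels = (long[["patient_id", "group"]].drop_duplicates()
                  .rename(columns={"group": "label"}))
        flipped = labels.copy()
        near = flipped.sample(2, random_state=0).index
        flipped.loc[near, "label"] = flipped.loc[near, "label"].map(
            {"active": "inactive", "inactive": "active"})
        grid = sensitivity_grid(long, LmeSpec(), label_variants={"swap2": flipped})
        assert grid[grid["feasible"]]["sign_stable"].all()

    def test_drop_single_wave_patients_reduces_n(self):
        long, _ = _simulated_long(seed=16, dropout=(0.0, 0.0, 0.0))
        # force 9 patients down to a single wave
        singles = long["patient_id"].drop_duplicates().iloc[:9]
        long = long[~(long["patient_id"].isin(singles) & long["wave"].isin(["m3", "m6"]))]
        grid = sensitivity_grid(long, LmeSpec(), extra_variants=("drop_single_wave_patients",))
        base_n = grid[grid["variant"] == "base"].iloc[0]["n_patients"]
        drop_n = grid[grid["variant"] == "drop_single_wave_patients"].iloc[0]["n_patients"]
        assert base_n - drop_n == 9

    def test_emptied_group_marked_infeasible(self):
        long, _ = _simulated_long(seed=17)
        labels = (long[["patient_id", "group"]].drop_duplicates()
                  .rename(columns={"group": "label"}))
        labels["label"] = "inactive"
        grid = sensitivity_grid(long, LmeSpec(), label_variants={"allsame": labels},
                                extra_variants=())
        row = grid[grid["variant"] == "allsame"].iloc[0]
        assert not row["feasible"]
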