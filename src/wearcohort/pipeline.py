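"""End-to-end pipeline: simulate -> validate -> features -> phenotype ->
score -> compare -> lme -> gmm, with a manifest of every threshold used.

Each stage writes its outputs under the run directory and registers them in
the manifest (config snapshot, package version, seed, per-stage output
hashes, exclusion tallies).  Reruns with the same config and seed produce
byte-identical outputs; any stage failure halts the run with a stage-named
error.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .config import PhenotypeConfig, ValidationConfig
from .cohort_stats import compare_groups, hawkins_mcar_test
from .daily_features import cohort_daily_table, summarize_cohort_days
from .io_wearable import write_day_summaries, write_minute_csv, write_pro_table, write_sleep_csv
from .longitudinal_models import LmeSpec, diagnose, fit_lme
from .phenotyping import classify_cohort
from .pro_scoring import score_records
from .synthetic_data import (
    CohortConfig,
    generate_cohort_minutes,
    generate_profiles,
    generate_pro_waves,
    generate_sleep_records,
)
from .trajectory_gmm import GmmSpec, select_classes
from .wear_validation import exclusion_tally, validate_cohort

__all__ = ["PipelineError", "run_pipeline", "STAGES"]

STAGES = ("simulate", "validate", "features", "phenotype", "score", "compare", "lme", "gmm")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _cohort_config(overrides: dict[str, Any] | None) -> CohortConfig:
    cfg = CohortConfig()
    if overrides:
        known = set(CohortConfig.__dataclass_fields__)
        unknown = set(overrides) - known
        if unknown:
            raise ValueError(f"unknown cohort config keys: {sorted(unknown)}")
        cfg = replace(cfg, **{k: tuple(v) if isinstance(v, list) else v for k, v in overrides.items()})
    return cfg


def run_pipeline(
    out_dir: str | Path,
    seed: int,
    cohort: dict[str, Any] | None = None,
    validation: dict[str, Any] | None = None,
    lme_outcome: str = "social_roles_t",
    gmm_measure: str = "mvpa_minutes",
    gmm_k_max: int = 2,
) -> dict[str, Any]:
    """Run the full synthetic-cohort analysis and return the manifest.

    Config errors (e.g. an inverted HR plausibility window) surface before
    any stage runs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vconfig = ValidationConfig(**(validation or {}))  # validates thresholds up front
    cconfig = _cohort_config(cohort)
    pconfig = PhenotypeConfig(min_valid_days=vconfig.valid_patient_days)
    rng = np.random.default_rng(seed)
    manifest: dict[str, Any] = {
        "package_version": __version__,
        "seed": seed,
        "config": {
            "validation": vconfig.to_dict(),
            "phenotype": asdict(pconfig),
            "cohort": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(cconfig).items()
                       if k not in ("pro_measures", "artifacts", "start_date")},
        },
        "stages": {},
    }

    def record(stage: str, files: dict[str, Path], extra: dict | None = None) -> None:
        manifest["stages"][stage] = {
            "outputs": {k: {"path": str(p.relative_to(out)), "sha256": _sha256(p)} for k, p in files.items()},
            **(extra or {}),
        }

    # 1. simulate
    try:
        profiles = generate_profiles(cconfig, rng)
        minutes, ledger = generate_cohort_minutes(cconfig, rng, profiles)
        sleep = generate_sleep_records(profiles, cconfig, rng)
        pro_records, pro_truth = generate_pro_waves(profiles, cconfig, rng)
        files = {
            "minutes": out / "minutes.csv",
            "sleep": out / "sleep.csv",
            "pro": out / "pro.csv",
            "profiles": out / "profiles_truth.csv",
        }
        write_minute_csv(minutes, files["minutes"])
        write_sleep_csv(sleep, files["sleep"])
        write_pro_table(pro_records, files["pro"])
        profiles.to_csv(files["profiles"], index=False)
        record("simulate", files, {"n_patients": len(profiles)})
    except Exception as exc:
        raise PipelineError("simulate", str(exc)) from exc

    # 2. validate
    try:
        flags, days, patient_verdicts = validate_cohort(minutes, vconfig)
        files = {"day_verdicts": out / "day_verdicts.csv", "patient_verdicts": out / "patient_verdicts.csv"}
        days.to_csv(files["day_verdicts"], index=False)
        patient_verdicts.to_csv(files["patient_verdicts"], index=False)
        tally = exclusion_tally(flags)
        (out / "exclusion_tally.json").write_text(json.dumps(tally, indent=2, sort_keys=True))
        files["exclusion_tally"] = out / "exclusion_tally.json"
        record("validate", files, {"exclusion_tally": tally})
    except Exception as exc:
        raise PipelineError("validate", str(exc)) from exc

    # 3. features
    try:
        summaries = summarize_cohort_days(flags, sleep)
        files = {"day_summaries": out / "day_summaries.csv"}
        write_day_summaries(summaries, files["day_summaries"])
        record("features", files, {"n_days": len(summaries)})
    except Exception as exc:
        raise PipelineError("features", str(exc)) from exc

    # 4. phenotype
    try:
        valid_ids = patient_verdicts.loc[patient_verdicts["is_valid_wear_patient"], "patient_id"]
        labels = classify_cohort(summaries[summaries["patient_id"].isin(valid_ids)],
                                 config=pconfig, validation=vconfig)
        files = {"labels": out / "labels.csv"}
        labels.to_csv(files["labels"], index=False)
        counts = labels["label"].value_counts().to_dict()
        record("phenotype", files, {"label_counts": {k: int(v) for k, v in counts.items()}})
    except Exception as exc:
        raise PipelineError("phenotype", str(exc)) from exc

    # 5. score
    try:
        scored = score_records(pro_records)
        files = {"scored": out / "pro_scored.csv"}
        scored.to_csv(files["scored"], index=False, float_format="%.6f")
        record("score", files, {"n_rows": len(scored)})
    except Exception as exc:
        raise PipelineError("score", str(exc)) from exc

    # 6. compare (baseline group comparisons + Hawkins MCAR check)
    try:
        merged = scored.merge(labels[labels["label"].isin(["active", "inactive"])][["patient_id", "label"]],
                              on="patient_id")
        base = merged[merged["wave"] == "baseline"]
        rows = []
        for measure, grp in base.groupby("measure", sort=True):
            a = grp.loc[grp["label"] == "active", "value"]
            b = grp.loc[grp["label"] == "inactive", "value"]
            if a.nunique() <= 2 and b.nunique() <= 2:
                continue  # binary flags handled as counts elsewhere
            if len(a) < 3 or len(b) < 3:
                continue
            res = compare_groups(a, b, "continuous", measure=measure)
            rows.append({"measure": measure, "test": res.test_used,
                         "statistic": res.statistic, "p": res.p_value,
                         "active_mean": res.group_summaries["a"]["mean"],
                         "inactive_mean": res.group_summaries["b"]["mean"]})
        table = pd.DataFrame(rows)
        fit_table = cohort_daily_table(summaries, labels, vconfig)
        # Hawkins on the primary outcome's wave matrix
        waves_mat = (scored[scored["measure"] == lme_outcome]
                     .pivot_table(index="patient_id", columns="wave", values="value", aggfunc="first"))
        for w in ("baseline", "m3", "m6"):
            if w not in waves_mat.columns:
                waves_mat[w] = np.nan
        waves_mat = waves_mat[["baseline", "m3", "m6"]]
        try:
            hawkins = hawkins_mcar_test(waves_mat.to_numpy(), seed=int(rng.integers(2**31)))
            hawkins_out = {"p_value": hawkins.p_value, "n_patterns": hawkins.n_patterns}
        except ValueError as exc:
            hawkins_out = {"error": str(exc)}
        files = {"baseline_comparisons": out / "baseline_comparisons.csv",
                 "fitbit_table": out / "fitbit_group_table.csv"}
        table.to_csv(files["baseline_comparisons"], index=False, float_format="%.6f")
        fit_table.to_csv(files["fitbit_table"], index=False, float_format="%.6f")
        record("compare", files, {"hawkins": hawkins_out})
    except Exception as exc:
        raise PipelineError("compare", str(exc)) from exc

    # 7. lme
    try:
        long = (scored[scored["measure"] == lme_outcome]
                .merge(labels[labels["label"].isin(["active", "inactive"])][["patient_id", "label"]],
                       on="patient_id")
                .rename(columns={"label": "group"}))[["patient_id", "wave", "group", "value"]]
        fit = fit_lme(long, LmeSpec(outcome=lme_outcome, baseline_covariate=False))
        diag = diagnose(fit)
        term = fit.interaction_term
        lme_out = {
            "outcome": lme_outcome,
            "interaction": {
                "term": term,
                "estimate": float(fit.params.loc[term, "estimate"]),
                "ci": [float(fit.params.loc[term, "ci_lo"]), float(fit.params.loc[term, "ci_hi"])],
                "p": float(fit.params.loc[term, "p"]),
            },
            "aic": fit.aic,
            "n_obs": fit.n_obs,
            "n_patients": fit.n_patients,
            "converged": fit.converged,
            "diagnostics": {k: (None if isinstance(v, float) and np.isnan(v) else v) for k, v in diag.items()},
            "meaningful_change": fit.meaningful_change,
        }
        files = {"lme": out / "lme_fit.json"}
        files["lme"].write_text(json.dumps(lme_out, indent=2, sort_keys=True))
        record("lme", files, {"interaction_estimate": lme_out["interaction"]["estimate"]})
    except Exception as exc:
        raise PipelineError("lme", str(exc)) from exc

    # 8. gmm
    try:
        table_k, chosen, fits = select_classes(summaries, gmm_k_max,
                                               GmmSpec(seed=int(rng.integers(2**31))),
                                               measure=gmm_measure)
        best = fits[chosen]
        gmm_out = {
            "measure": gmm_measure,
            "chosen_k": chosen,
            "bic": {str(int(r["K"])): (None if pd.isna(r["bic"]) else float(r["bic"]))
                    for _, r in table_k.iterrows()},
            "intercepts": [float(x) for x in best.intercepts],
            "slopes": [float(x) for x in best.slopes],
            "modal_sizes": [int(x) for x in best.modal_sizes],
        }
        files = {"gmm": out / "gmm_fit.json"}
        files["gmm"].write_text(json.dumps(gmm_out, indent=2, sort_keys=True))
        record("gmm", files, {"chosen_k": chosen})
    except Exception as exc:
        raise PipelineError("gmm", str(exc)) from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
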