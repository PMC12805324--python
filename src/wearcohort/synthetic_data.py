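"""Synthetic cohort generator with a ground-truth ledger.

Generates the inputs the pipeline consumes — minute-level wearable streams,
daily sleep sessions and three-wave PRO tables — with the statistical
structure the analyses assume, so every stage can be scored against known
truth.  Defaults emulate a long-COVID remote-monitoring cohort: 41 + 41
patients split into two activity phenotypes (daily MVPA means near 46.9 and
8.2 minutes, steps near 8966 and 5744, resting HR near 70.7), a lognormal
valid-day distribution matched to a median of 42 days (IQR 20-70.75), sensor
artifacts (missing-HR runs, flat-line runs straddling the 11-minute
exclusion threshold, out-of-range spikes) and MCAR PRO dropout across the
baseline / 3-month / 6-month waves, with configurable group-by-time effects
(the social-roles T-score interaction defaults to -4.21 per 3 months).

Every injected artifact is registered in the ledger; generated intensity,
METs and steps never contradict each other (an intensity>=2 minute always
has METs > 3 and elevated steps).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date as Date, datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .io_wearable import ProRecord

__all__ = [
    "ArtifactConfig",
    "ProMeasureConfig",
    "CohortConfig",
    "GroundTruthLedger",
    "generate_profiles",
    "generate_minute_day",
    "generate_patient_minutes",
    "generate_cohort_minutes",
    "generate_sleep_records",
    "generate_day_summaries",
    "generate_pro_long",
    "generate_pro_waves",
    "generate_gmm_series",
    "mvn_with_missing",
    "make_fixture_suite",
]


@dataclass(frozen=True)
class ArtifactConfig:
    """Sensor artifact injection rates (per day unless noted)."""

    gap_runs_per_day: float = 1.0       # Poisson mean of missing-HR runs
    gap_run_mean_len: float = 8.0       # geometric mean run length (minutes)
    active_gap_fraction: float = 0.4    # fraction of gap runs placed on active minutes
    flatline_runs_per_day: float = 0.4  # Poisson mean of flat-line runs
    flatline_lengths: tuple[int, ...] = (8, 15)  # straddle the 11-minute rule
    spikes_per_day: float = 0.2         # Poisson mean of out-of-range spikes
    spike_values: tuple[int, int] = (30, 215)

    @classmethod
    def none(cls) -> "ArtifactConfig":
        return cls(gap_runs_per_day=0.0, flatline_runs_per_day=0.0, spikes_per_day=0.0)


@dataclass(frozen=True)
class ProMeasureConfig:
    """Generating parameters for one PRO measure.

    Scores follow ``group baseline mean + patient intercept (SD tau) +
    slope_g * wave + residual (SD sigma)``; the active-group slope is
    ``inactive_slope + interaction`` per 3-month wave unit.
    """

    active_mean: float
    inactive_mean: float
    tau: float       # between-patient SD
    sigma: float     # within-patient residual SD
    inactive_slope: float = 0.0
    interaction: float = 0.0
    lo: float | None = None
    hi: float | None = None
    integer: bool = False


#: Default PRO measures, calibrated to the cohort's printed baseline means /
#: SDs and follow-up trends; the social-roles interaction is the headline
#: -4.21 T points per 3 months of being MVPA-active.
DEFAULT_PRO_MEASURES: dict[str, ProMeasureConfig] = {
    "social_roles_t": ProMeasureConfig(47.0, 40.0, 7.0, 7.0, inactive_slope=4.21, interaction=-4.21),
    "physical_function_t": ProMeasureConfig(38.0, 34.0, 5.0, 5.0, inactive_slope=1.35, interaction=-1.35),
    "fatigue_t": ProMeasureConfig(59.0, 66.0, 7.0, 6.0, inactive_slope=-1.5, interaction=2.5),
    "dyspnea_t": ProMeasureConfig(56.0, 63.0, 8.0, 7.0, inactive_slope=-1.0, interaction=0.0),
    "gad7": ProMeasureConfig(6.1, 8.2, 4.0, 3.2, inactive_slope=-0.8, interaction=1.5, lo=0, hi=21, integer=True),
    "phq2": ProMeasureConfig(1.8, 2.4, 1.2, 1.1, inactive_slope=-0.4, interaction=0.5, lo=0, hi=6, integer=True),
}

#: Screener symptoms with baseline presence rates and severity-score targets
#: per group (active, inactive); ratings are drawn to match the target mean.
DEFAULT_SYMPTOMS: dict[str, dict] = {
    "fatigue": {"present": (0.88, 0.95), "severity": (9.2, 12.3)},
    "muscle_pain": {"present": (0.80, 0.78), "severity": (7.0, 8.1)},
    "joint_pain": {"present": (0.61, 0.71), "severity": (5.6, 7.5)},
    "unrefreshing_sleep": {"present": (0.71, 0.83), "severity": (7.1, 9.8)},
    "sleep_problems": {"present": (0.83, 0.90), "severity": (7.1, 10.4)},
    "forgetfulness": {"present": (0.59, 0.76), "severity": (5.2, 8.1)},
    "concentration": {"present": (0.63, 0.85), "severity": (5.3, 8.7)},
    "dizziness": {"present": (0.71, 0.80), "severity": (4.8, 4.4)},
}


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters of the synthetic cohort."""

    n_active: int = 41
    n_inactive: int = 41
    followup_log_median: float = 42.0   # median valid days
    followup_log_sigma: float = 0.93    # lognormal sigma matching IQR 20-70.75
    followup_min_days: int = 7
    followup_max_days: int = 180
    mvpa_means: tuple[float, float] = (46.9, 8.2)       # (active, inactive) min/day
    mvpa_between_sd: tuple[float, float] = (18.0, 4.0)  # between-patient SD
    mvpa_day_sd: float = 10.0                           # day-to-day SD
    steps_means: tuple[float, float] = (8966.0, 5744.0)
    steps_between_sd: tuple[float, float] = (2500.0, 1800.0)
    resting_hr_means: tuple[float, float] = (70.7, 70.6)
    resting_hr_sd: float = 8.8
    sedentary_frac: tuple[float, float] = (66.8, 74.0)
    light_minutes: tuple[float, float] = (283.2, 242.1)
    bedtime_h: tuple[float, float] = (23.99, 24.11)
    getup_h: tuple[float, float] = (7.60, 8.01)
    hours_asleep: tuple[float, float] = (6.83, 6.96)
    sleep_efficiency: tuple[float, float] = (87.4, 87.1)
    pem_rate: tuple[float, float] = (0.78, 0.73)
    artifacts: ArtifactConfig = field(default_factory=ArtifactConfig)
    pro_measures: dict[str, ProMeasureConfig] = field(default_factory=lambda: dict(DEFAULT_PRO_MEASURES))
    dropout: tuple[float, float, float] = (0.0, 0.3, 0.3)  # MCAR per wave
    start_date: Date = Date(2022, 6, 1)

    @property
    def n_patients(self) -> int:
        return self.n_active + self.n_inactive


@dataclass
class GroundTruthLedger:
    """Everything needed to score any pipeline stage against truth."""

    profiles: pd.DataFrame                      # per-patient true phenotype & means
    artifacts: pd.DataFrame                     # injected artifact registry
    day_truth: pd.DataFrame                     # per-day true (pre-artifact) features
    pro_truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Patient profiles
# ---------------------------------------------------------------------------

def generate_profiles(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-patient latent profiles (phenotype, activity means, HR, sleep)."""
    rows = []
    for gi, (group, n) in enumerate([("active", config.n_active), ("inactive", config.n_inactive)]):
        for j in range(n):
            pid = f"P{len(rows) + 1:03d}"
            n_days = int(np.clip(
                np.round(rng.lognormal(np.log(config.followup_log_median), config.followup_log_sigma)),
                config.followup_min_days, config.followup_max_days))
            mvpa = max(rng.normal(config.mvpa_means[gi], config.mvpa_between_sd[gi]), 0.5)
            rows.append({
                "patient_id": pid,
                "group": group,
                "n_days": n_days,
                "mvpa_mean": mvpa,
                "steps_mean": max(rng.normal(config.steps_means[gi], config.steps_between_sd[gi]), 500.0),
                "resting_hr": float(np.clip(rng.normal(config.resting_hr_means[gi], config.resting_hr_sd), 50, 95)),
                "sedentary_frac": float(np.clip(rng.normal(config.sedentary_frac[gi], 6.0), 40, 95)),
                "light_mean": max(rng.normal(config.light_minutes[gi], 60.0), 30.0),
                "bedtime_h": rng.normal(config.bedtime_h[gi], 1.2),
                "getup_h": float(np.clip(rng.normal(config.getup_h[gi], 1.2), 4.5, 11.5)),
                "hours_asleep": float(np.clip(rng.normal(config.hours_asleep[gi], 1.0), 3.5, 11.0)),
                "sleep_efficiency": float(np.clip(rng.normal(config.sleep_efficiency[gi], 3.0), 60, 99)),
                "pem": bool(rng.random() < config.pem_rate[gi]),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Minute streams
# ---------------------------------------------------------------------------

def _ar1(n: int, sd: float, phi: float, rng: np.random.Generator) -> np.ndarray:
    e = rng.normal(0, sd * np.sqrt(1 - phi**2), n)
    out = np.empty(n)
    out[0] = rng.normal(0, sd)
    for i in range(1, n):
        out[i] = phi * out[i - 1] + e[i]
    return out


def _sample_disjoint_runs(
    eligible: np.ndarray, n_runs: int, lengths: np.ndarray, rng: np.random.Generator, margin: int = 2
) -> list[tuple[int, int]]:
    """Place runs of given lengths on eligible minutes without overlap."""
    taken = np.zeros(len(eligible), dtype=bool)
    out = []
    cand = np.flatnonzero(eligible)
    for L in lengths[:n_runs]:
        ok_starts = [s for s in cand if s + L <= len(eligible)
                     and eligible[s:s + L].all()
                     and not taken[max(s - margin, 0):s + L + margin].any()]
        if not ok_starts:
            continue
        s = int(rng.choice(ok_starts))
        taken[max(s - margin, 0):s + int(L) + margin] = True
        out.append((s, int(L)))
    return out


def generate_minute_day(
    profile: pd.Series | dict,
    day: Date,
    config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict, list[dict]]:
    """Generate one patient-day of 1440 minute records plus ledger entries.

    Returns ``(minutes, day_truth, artifact_entries)``.  The stream carries a
    circadian HR baseline (sinusoid + AR(1) noise around the patient's
    resting level), jointly consistent activity bouts (intensity 2-3 <=>
    METs > 3 and elevated steps), a sleep window with low HR and zero steps,
    and then injected artifacts per ``config.artifacts``.
    """
    p = profile
    art = config.artifacts
    n = 1440
    minute_of_day = np.arange(n)
    getup_min = int(p["getup_h"] * 60) % n
    bed_h = p["bedtime_h"]
    asleep = minute_of_day < getup_min
    if bed_h < 24:
        asleep |= minute_of_day >= int(bed_h * 60)
    wake = ~asleep
    n_wake = int(wake.sum())

    # activity classes on wake minutes, hitting expected daily targets
    mvpa_target = max(rng.normal(p["mvpa_mean"], config.mvpa_day_sd), 0.0)
    light_target = max(rng.normal(p["light_mean"], 40.0), 0.0)
    p_mvpa = min(mvpa_target / max(n_wake, 1), 0.9)
    p_light = min(light_target / max(n_wake, 1), 0.9 - p_mvpa)
    u = rng.random(n_wake)
    klass = np.zeros(n, dtype=int)  # 0 sedentary/sleep
    wake_idx = np.flatnonzero(wake)
    klass[wake_idx[u < p_mvpa]] = 2
    klass[wake_idx[(u >= p_mvpa) & (u < p_mvpa + p_light)]] = 1

    mets = np.full(n, 1.0)
    mets[klass == 1] = rng.uniform(1.6, 2.9, int((klass == 1).sum()))
    mets[klass == 2] = rng.uniform(3.5, 7.5, int((klass == 2).sum()))
    intensity = klass.copy()
    intensity[(klass == 2) & (mets > 6.0)] = 3

    steps = np.zeros(n, dtype=int)
    n_mvpa = int((klass >= 2).sum())
    n_light = int((klass == 1).sum())
    mvpa_rate = 100.0
    sed_steps_total = 0.10 * (wake & (klass == 0)).sum() * 8.0
    light_rate = (p["steps_mean"] - mvpa_rate * n_mvpa - sed_steps_total) / max(n_light, 1)
    light_rate = float(np.clip(light_rate, 5.0, 80.0))
    steps[klass >= 2] = rng.poisson(mvpa_rate, n_mvpa) + 1
    steps[klass == 1] = rng.poisson(light_rate, n_light) + 1
    sed_wake = wake & (klass == 0)
    sed_step_mask = sed_wake & (rng.random(n) < 0.10)
    steps[sed_step_mask] = rng.poisson(8.0, int(sed_step_mask.sum())) + 1

    circadian = 6.0 * np.sin(2 * np.pi * (minute_of_day / 60.0 - 15.0) / 24.0)
    hr = p["resting_hr"] + 4.0 + circadian + _ar1(n, 3.0, 0.8, rng)
    hr[asleep] -= 6.0
    hr += np.where(klass == 1, 15.0, 0.0) + np.where(klass >= 2, 42.0, 0.0)
    hr += np.where(intensity == 3, 12.0, 0.0)
    hr = np.clip(np.round(hr), 46, 200)

    truth = {
        "patient_id": p["patient_id"],
        "date": day,
        "true_mvpa_minutes": n_mvpa,
        "true_light_minutes": n_light,
        "true_steps": int(steps.sum()),
        "true_max_hr": float(hr.max()),
    }

    # ---- artifact injection -------------------------------------------------
    entries: list[dict] = []
    observed = np.ones(n, dtype=bool)
    blocked = np.zeros(n, dtype=bool)  # minutes already touched by an artifact

    n_gaps = rng.poisson(art.gap_runs_per_day)
    if n_gaps:
        lens = rng.geometric(1.0 / art.gap_run_mean_len, n_gaps).clip(1, 90)
        active_mask = (klass >= 1) & ~blocked
        rest_mask = sed_wake & (steps == 0) & ~blocked
        for i, L in enumerate(lens):
            on_active = rng.random() < art.active_gap_fraction
            mask = active_mask if on_active else rest_mask
            runs = _sample_disjoint_runs(mask & ~blocked, 1, np.array([L]), rng)
            for s, ln in runs:
                observed[s:s + ln] = False
                blocked[s:s + ln] = True
                entries.append({"patient_id": p["patient_id"], "date": day, "type": "hr_gap",
                                "start_minute": s, "length": ln,
                                "subtype": "active" if on_active else "rest"})

    n_flat = rng.poisson(art.flatline_runs_per_day)
    if n_flat:
        lens = np.array([rng.choice(art.flatline_lengths) for _ in range(n_flat)])
        runs = _sample_disjoint_runs(sed_wake & ~blocked, n_flat, lens, rng)
        for s, ln in runs:
            const = float(np.clip(hr[s], 50, 200))
            hr[s:s + ln] = const
            # ensure the run is maximal: neighbours must differ
            if s > 0 and hr[s - 1] == const and observed[s - 1]:
                hr[s - 1] = const + 2
            e = s + ln
            if e < n and hr[e] == const and observed[e]:
                hr[e] = const + 2
            blocked[s:s + ln] = True
            entries.append({"patient_id": p["patient_id"], "date": day, "type": "flatline",
                            "start_minute": s, "length": ln, "subtype": str(ln)})

    n_spikes = rng.poisson(art.spikes_per_day)
    if n_spikes:
        free = np.flatnonzero(~blocked & observed)
        # keep spikes off run boundaries so they never merge with a flat-line
        if len(free):
            pick = rng.choice(free, size=min(n_spikes, len(free)), replace=False)
            for s in pick:
                if blocked[max(s - 1, 0):min(s + 2, n)].any():
                    continue
                v = int(rng.choice(art.spike_values))
                hr[s] = v
                blocked[s] = True
                entries.append({"patient_id": p["patient_id"], "date": day, "type": "spike",
                                "start_minute": int(s), "length": 1,
                                "subtype": "low" if v < 100 else "high"})

    timestamps = pd.date_range(datetime.combine(day, datetime.min.time()), periods=n, freq="min")
    minutes = pd.DataFrame({
        "patient_id": p["patient_id"],
        "timestamp": timestamps,
        "hr": np.where(observed, hr, np.nan),
        "steps": steps,
        "mets": mets,
        "intensity": intensity.astype(float),
    })
    return minutes, truth, entries


def generate_patient_minutes(
    profile: pd.Series | dict,
    config: CohortConfig,
    rng: np.random.Generator,
    n_days: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """All minute records for one patient: ``(minutes, day_truth, artifacts)``."""
    n_days = int(n_days if n_days is not None else profile["n_days"])
    frames, truths, arts = [], [], []
    for d in range(n_days):
        day = config.start_date + timedelta(days=d)
        m, t, a = generate_minute_day(profile, day, config, rng)
        frames.append(m)
        truths.append(t)
        arts.extend(a)
    return (
        pd.concat(frames, ignore_index=True),
        pd.DataFrame(truths),
        pd.DataFrame(arts, columns=["patient_id", "date", "type", "start_minute", "length", "subtype"]),
    )


def generate_cohort_minutes(
    config: CohortConfig, rng: np.random.Generator, profiles: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, GroundTruthLedger]:
    """Minute streams for the whole cohort plus the ground-truth ledger."""
    profiles = profiles if profiles is not None else generate_profiles(config, rng)
    frames, truths, arts = [], [], []
    for _, prof in profiles.iterrows():
        m, t, a = generate_patient_minutes(prof, config, rng)
        frames.append(m)
        truths.append(t)
        arts.append(a)
    minutes = pd.concat(frames, ignore_index=True)
    ledger = GroundTruthLedger(
        profiles=profiles,
        artifacts=pd.concat(arts, ignore_index=True),
        day_truth=pd.concat(truths, ignore_index=True),
    )
    return minutes, ledger


def generate_sleep_records(
    profiles: pd.DataFrame, config: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Nightly sleep sessions consistent with each profile's sleep timing."""
    rows = []
    for _, p in profiles.iterrows():
        for d in range(int(p["n_days"])):
            day = config.start_date + timedelta(days=d)
            bed_h = rng.normal(p["bedtime_h"], 0.5)
            in_bed_h = max(rng.normal(p["hours_asleep"] / (p["sleep_efficiency"] / 100.0), 0.5), 2.0)
            eff = float(np.clip(rng.normal(p["sleep_efficiency"], 2.0), 55, 99.5))
            start = datetime.combine(day, datetime.min.time()) + timedelta(hours=float(bed_h))
            end = start + timedelta(hours=in_bed_h)
            in_bed_min = int(in_bed_h * 60)
            rows.append({
                "patient_id": p["patient_id"],
                "bed_start": start,
                "bed_end": end,
                "minutes_asleep": int(in_bed_min * eff / 100.0),
                "minutes_in_bed": in_bed_min,
            })
    return pd.DataFrame(rows)


def generate_day_summaries(
    config: CohortConfig, rng: np.random.Generator, profiles: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Direct day-level feature generation (fast path, no minute streams).

    Produces the same DaySummary columns the pipeline derives, for
    simulations that only need day-level structure (group-table recovery,
    growth-mixture experiments).  Returns ``(summaries, profiles)``.
    """
    profiles = profiles if profiles is not None else generate_profiles(config, rng)
    rows = []
    for _, p in profiles.iterrows():
        n_days = int(p["n_days"])
        mvpa = np.clip(rng.normal(p["mvpa_mean"], config.mvpa_day_sd, n_days), 0, None)
        light = np.clip(rng.normal(p["light_mean"], 40.0, n_days), 0, None)
        steps = np.clip(rng.normal(p["steps_mean"], 1500.0, n_days), 0, None)
        rhr = rng.normal(p["resting_hr"], 2.0, n_days)
        for d in range(n_days):
            rows.append({
                "patient_id": p["patient_id"],
                "date": config.start_date + timedelta(days=d),
                "valid_minutes": 1440,
                "sedentary_frac": float(np.clip(rng.normal(p["sedentary_frac"], 4.0), 0, 100)),
                "light_minutes": int(light[d]),
                "mvpa_minutes": int(round(mvpa[d])),
                "steps": int(steps[d]),
                "resting_hr": float(rhr[d]),
                "max_hr": float(rhr[d] + rng.normal(52, 6)),
                "bedtime_h": rng.normal(p["bedtime_h"], 0.5),
                "getup_h": rng.normal(p["getup_h"], 0.5),
                "hours_asleep": float(np.clip(rng.normal(p["hours_asleep"], 0.7), 2, 13)),
                "sleep_efficiency": float(np.clip(rng.normal(p["sleep_efficiency"], 2.0), 55, 100)),
            })
    return pd.DataFrame(rows), profiles


# ---------------------------------------------------------------------------
# PRO waves
# ---------------------------------------------------------------------------

def generate_pro_long(
    profiles: pd.DataFrame,
    config: CohortConfig,
    rng: np.random.Generator,
    measure: str = "social_roles_t",
    params: ProMeasureConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Three-wave scores for one measure, in the long modelling layout.

    Score = group baseline mean + patient intercept + group slope x wave +
    residual; MCAR dropout per wave per ``config.dropout``.  Returns the
    long frame (``patient_id, wave, group, value``) and the truth record.
    """
    params = params or config.pro_measures[measure]
    waves = ("baseline", "m3", "m6")
    n = len(profiles)
    active = (profiles["group"] == "active").to_numpy()
    base_mean = np.where(active, params.active_mean, params.inactive_mean)
    slope = np.where(active, params.inactive_slope + params.interaction, params.inactive_slope)
    intercepts = rng.normal(0.0, params.tau, n)
    rows = []
    for t, wave in enumerate(waves):
        vals = base_mean + intercepts + slope * t + rng.normal(0.0, params.sigma, n)
        if params.lo is not None or params.hi is not None:
            vals = np.clip(vals, params.lo, params.hi)
        if params.integer:
            vals = np.round(vals)
        drop = rng.random(n) < config.dropout[t]
        for i in range(n):
            if drop[i]:
                continue
            rows.append({
                "patient_id": profiles["patient_id"].iloc[i],
                "wave": wave,
                "group": "active" if active[i] else "inactive",
                "value": float(vals[i]),
            })
    truth = {
        "measure": measure,
        "interaction": params.interaction,
        "inactive_slope": params.inactive_slope,
        "active_mean": params.active_mean,
        "inactive_mean": params.inactive_mean,
    }
    return pd.DataFrame(rows), truth


def _ratings_for_severity(target: float, rng: np.random.Generator) -> tuple[int, int]:
    """Draw (frequency, intensity) in 1-4 whose product centres on target."""
    r = np.sqrt(max(target, 1.0))
    f = int(np.clip(np.round(rng.normal(r, 0.8)), 1, 4))
    i = int(np.clip(np.round(rng.normal(r, 0.8)), 1, 4))
    return f, i


def generate_pro_waves(
    profiles: pd.DataFrame, config: CohortConfig, rng: np.random.Generator
) -> tuple[list[ProRecord], dict]:
    """Full PRO records: instrument scores, symptom reports, PEM and dropout.

    Follow-up symptom gating is honoured: a symptom absent at baseline
    yields no follow-up report.  Whole waves go missing completely at
    random per ``config.dropout``.
    """
    waves = ("baseline", "m3", "m6")
    n = len(profiles)
    active = (profiles["group"] == "active").to_numpy()
    truth: dict = {"measures": {}, "symptom_baseline": {}}
    scores_by_measure: dict[str, np.ndarray] = {}
    for name, mp in config.pro_measures.items():
        base_mean = np.where(active, mp.active_mean, mp.inactive_mean)
        slope = np.where(active, mp.inactive_slope + mp.interaction, mp.inactive_slope)
        b = rng.normal(0, mp.tau, n)
        vals = np.stack([
            base_mean + b + slope * t + rng.normal(0, mp.sigma, n) for t in range(3)
        ])
        if mp.lo is not None or mp.hi is not None:
            vals = np.clip(vals, mp.lo, mp.hi)
        if mp.integer:
            vals = np.round(vals)
        scores_by_measure[name] = vals
        truth["measures"][name] = {"interaction": mp.interaction}

    present0: dict[str, np.ndarray] = {}
    for sym, sp in DEFAULT_SYMPTOMS.items():
        rate = np.where(active, sp["present"][0], sp["present"][1])
        present0[sym] = rng.random(n) < rate
        truth["symptom_baseline"][sym] = present0[sym].copy()

    dropped = np.stack([rng.random(n) < config.dropout[t] for t in range(3)])
    records: list[ProRecord] = []
    for i in range(n):
        pid = profiles["patient_id"].iloc[i]
        for t, wave in enumerate(waves):
            if dropped[t, i]:
                continue
            rec = ProRecord(patient_id=pid, wave=wave,
                            pem_flag="yes" if profiles["pem"].iloc[i] else "no")
            for name, vals in scores_by_measure.items():
                rec.scores[name] = float(vals[t, i])
            for sym, sp in DEFAULT_SYMPTOMS.items():
                if not present0[sym][i]:
                    if t == 0:
                        rec.symptoms[sym] = {"present": "no", "frequency": 0, "intensity": 0}
                    continue  # baseline-gated: no follow-up item
                target = sp["severity"][0] if active[i] else sp["severity"][1]
                f, s = _ratings_for_severity(target + rng.normal(0, 2.0), rng)
                rec.symptoms[sym] = {"present": "yes", "frequency": f, "intensity": s}
            records.append(rec)
    truth["dropped"] = dropped
    return records, truth


# ---------------------------------------------------------------------------
# Trajectory and missingness helpers for simulation studies
# ---------------------------------------------------------------------------

def generate_gmm_series(
    class_sizes: tuple[int, ...] = (70, 12),
    intercepts: tuple[float, ...] = (18.4, 68.2),
    slopes: tuple[float, ...] = (-0.029, 0.20),
    tau: float = 4.0,
    sigma: float = 12.0,
    n_days_mean: float = 50.0,
    rng: np.random.Generator | None = None,
) -> tuple[tuple[list, list, list], np.ndarray]:
    """Latent-class day-level series for growth-mixture experiments.

    Defaults match the exploratory MVPA clustering conditions: classes of 70
    and 12 patients with intercepts 18.4 and 68.2 minutes and near-zero
    slopes, about 50 days per patient.  Returns ``((ids, times, values),
    true_class)`` with classes ordered by ascending intercept.
    """
    rng = rng or np.random.default_rng(0)
    order = np.argsort(intercepts)
    ids, times, values, classes = [], [], [], []
    pid = 0
    for rank, k in enumerate(order):
        for _ in range(class_sizes[k]):
            pid += 1
            n_days = max(int(rng.normal(n_days_mean, n_days_mean / 5)), 10)
            t = np.sort(rng.choice(np.arange(int(n_days_mean * 3.5)), size=n_days, replace=False)).astype(float)
            u = rng.normal(0, tau)
            y = intercepts[k] + u + slopes[k] * t + rng.normal(0, sigma, n_days)
            ids.append(f"P{pid:03d}")
            times.append(t)
            values.append(np.clip(y, 0, None))
            classes.append(rank)
    return (ids, times, values), np.array(classes)


def mvn_with_missing(
    n: int = 200,
    p: int = 3,
    rate: float = 0.3,
    mechanism: str = "mcar",
    strength: float = 2.0,
    rho: float = 0.4,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Correlated multivariate normal data with injected missingness.

    ``mcar``: each entry of columns 1..p-1 missing independently with
    probability ``rate``.  ``mnar``: an entry's missingness probability is
    logistic in its own standardized value scaled by ``strength``, with the
    offset calibrated so the marginal rate equals ``rate``.  The first
    column is always observed as a fully observed anchor.
    """
    rng = rng or np.random.default_rng(0)
    cov = np.full((p, p), rho) + (1 - rho) * np.eye(p)
    X = rng.multivariate_normal(np.zeros(p), cov, size=n)
    out = X.copy()
    miss = np.zeros((n, p), dtype=bool)
    if mechanism == "mcar":
        miss[:, 1:] = rng.random((n, p - 1)) < rate
    elif mechanism == "mnar":
        from scipy.optimize import brentq
        from scipy.special import expit

        offset = brentq(lambda c: expit(c + strength * X[:, 1:]).mean() - rate, -50, 50)
        miss[:, 1:] = rng.random((n, p - 1)) < expit(offset + strength * X[:, 1:])
    else:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    out[miss] = np.nan
    return out


# ---------------------------------------------------------------------------
# Fixture suite
# ---------------------------------------------------------------------------

def make_fixture_suite(out_dir: str | Path, seed: int = 20220601, n_patients: int = 3, n_days: int = 10) -> dict[str, Path]:
    """Write a deterministic mini-cohort (default 3 patients x 10 days).

    Regeneration with the same seed is bit-identical.  Returns the paths of
    the written files.
    """
    from .io_wearable import write_minute_csv, write_pro_table, write_sleep_csv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    config = replace(
        CohortConfig(),
        n_active=(n_patients + 1) // 2,
        n_inactive=n_patients // 2,
        followup_min_days=n_days,
        followup_max_days=n_days,
    )
    profiles = generate_profiles(config, rng)
    profiles["n_days"] = n_days
    minutes, ledger = generate_cohort_minutes(config, rng, profiles)
    sleep = generate_sleep_records(profiles, config, rng)
    pro, _ = generate_pro_waves(profiles, config, rng)
    paths = {
        "minutes": out / "minutes.csv",
        "sleep": out / "sleep.csv",
        "pro": out / "pro.csv",
        "profiles": out / "profiles_truth.csv",
        "artifacts": out / "artifacts_truth.csv",
    }
    write_minute_csv(minutes, paths["minutes"])
    write_sleep_csv(sleep, paths["sleep"])
    write_pro_table(pro, paths["pro"])
    profiles.to_csv(paths["profiles"], index=False)
    ledger.artifacts.to_csv(paths["artifacts"], index=False)
    return paths
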