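"""Daily behavioural features from validated minutes and sleep sessions.

Each valid wear day is reduced to the cohort-table features: the fraction of
valid wear time spent sedentary, light-activity minutes, MVPA minutes
(moderate-to-vigorous physical activity, device intensity codes 2-3 with a
METs > 3 fallback), step total, resting and maximum heart rate, and sleep
timing (go-to-bed / get-up clock hours, hours asleep, sleep efficiency).

Group summaries use two-stage averaging — patient-level means first, then
group mean (SD) — so patients contributing more days are not over-weighted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ValidationConfig
from .io_wearable import DAY_SUMMARY_COLUMNS

__all__ = [
    "minute_activity_class",
    "summarize_day",
    "summarize_cohort_days",
    "sleep_features",
    "cohort_daily_table",
    "FEATURES",
]

#: Features included in the cohort table, in display order.
FEATURES = [
    "sedentary_frac",
    "light_minutes",
    "mvpa_minutes",
    "steps",
    "resting_hr",
    "max_hr",
    "bedtime_h",
    "getup_h",
    "hours_asleep",
    "sleep_efficiency",
]

_VALID = ("valid_observed", "valid_filled")


def minute_activity_class(intensity: np.ndarray, mets: np.ndarray) -> np.ndarray:
    """Classify minutes as 'sedentary' / 'light' / 'mvpa' / 'unclassified'.

    MVPA = intensity 2 or 3; when the intensity code is absent, METs > 3.0
    (the absolute-scale definition of moderate-to-vigorous activity) serves
    as the fallback.  Sedentary and light require the intensity code.
    """
    out = np.full(len(intensity), "unclassified", dtype=object)
    has_int = ~np.isnan(intensity)
    out[has_int & (intensity == 0)] = "sedentary"
    out[has_int & (intensity == 1)] = "light"
    out[has_int & (intensity >= 2)] = "mvpa"
    with np.errstate(invalid="ignore"):
        out[~has_int & (np.nan_to_num(mets, nan=-np.inf) > 3.0)] = "mvpa"
    return out


def _rolling_min_mean(hr: np.ndarray, window: int = 30) -> float:
    """Minimum of the rolling mean of HR — the computed resting-HR path."""
    if len(hr) == 0:
        return np.nan
    if len(hr) < window:
        return float(np.mean(hr))
    s = pd.Series(hr).rolling(window).mean()
    return float(s.min())


def summarize_day(
    day_flags: pd.DataFrame,
    sleep_day: pd.DataFrame | None = None,
    resting_hr: float | None = None,
) -> dict | None:
    """Summarise one patient-day of validated minutes into a DaySummary row.

    ``day_flags`` is this day's flagged minute frame; only valid minutes
    (observed or filled, not excluded) contribute.  Returns None when the
    day has zero valid minutes.  ``resting_hr`` comes from a daily-summary
    file when supplied; otherwise the minimum 30-minute rolling mean of the
    day's effective HR is used.
    """
    valid = day_flags[day_flags["status"].isin(_VALID)]
    if valid.empty:
        return None
    intensity = valid["intensity"].to_numpy(dtype=float)
    mets = valid["mets"].to_numpy(dtype=float)
    klass = minute_activity_class(intensity, mets)
    n_valid = len(valid)
    hr_eff = valid["hr_effective"].to_numpy(dtype=float)
    row = {
        "patient_id": day_flags["patient_id"].iloc[0],
        "date": day_flags["timestamp"].dt.date.iloc[0],
        "valid_minutes": n_valid,
        "sedentary_frac": 100.0 * np.count_nonzero(klass == "sedentary") / n_valid,
        "light_minutes": int(np.count_nonzero(klass == "light")),
        "mvpa_minutes": int(np.count_nonzero(klass == "mvpa")),
        "steps": int(valid["steps"].sum()),
        "resting_hr": resting_hr if resting_hr is not None else _rolling_min_mean(hr_eff),
        "max_hr": float(np.nanmax(hr_eff)),
        "bedtime_h": np.nan,
        "getup_h": np.nan,
        "hours_asleep": np.nan,
        "sleep_efficiency": np.nan,
    }
    if sleep_day is not None and len(sleep_day):
        row.update(sleep_features(sleep_day))
    return row


def sleep_features(sessions: pd.DataFrame) -> dict:
    """Sleep-timing features from a day's sessions (the longest is main sleep).

    Go-to-bed time is reported in hours since the prior midnight so a
    bedtime just after midnight averages sensibly with one just before
    (00:06 -> 24.1); bed starts before noon are read as crossing midnight.
    """
    main = sessions.loc[sessions["minutes_in_bed"].idxmax()]
    start, end = pd.Timestamp(main["bed_start"]), pd.Timestamp(main["bed_end"])
    bedtime_h = start.hour + start.minute / 60.0
    if start.hour < 12:
        bedtime_h += 24.0
    return {
        "bedtime_h": bedtime_h,
        "getup_h": end.hour + end.minute / 60.0,
        "hours_asleep": float(main["minutes_asleep"]) / 60.0,
        "sleep_efficiency": 100.0 * float(main["minutes_asleep"]) / float(main["minutes_in_bed"]),
    }


def summarize_cohort_days(
    flags: pd.DataFrame,
    sleep: pd.DataFrame | None = None,
    daily_resting_hr: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Build day summaries for every patient-day with valid wear minutes.

    ``daily_resting_hr``, when given, maps (patient_id, date) -> resting_hr
    from the device's daily export; otherwise resting HR is computed from
    minutes.  Sleep sessions are joined on the date of bed_start.
    """
    if flags.empty:
        return pd.DataFrame(columns=DAY_SUMMARY_COLUMNS)
    flags = flags.copy()
    flags["date"] = flags["timestamp"].dt.date
    sleep_by_day: dict[tuple, pd.DataFrame] = {}
    if sleep is not None and len(sleep):
        s = sleep.copy()
        s["date"] = pd.to_datetime(s["bed_start"]).dt.date
        sleep_by_day = {k: g for k, g in s.groupby(["patient_id", "date"])}
    rhr_lookup: dict[tuple, float] = {}
    if daily_resting_hr is not None and len(daily_resting_hr):
        d = daily_resting_hr.copy()
        d["date"] = pd.to_datetime(d["date"]).dt.date
        rhr_lookup = dict(zip(zip(d["patient_id"], d["date"]), d["resting_hr"]))
    rows = []
    for (pid, date), grp in flags.groupby(["patient_id", "date"], sort=True):
        row = summarize_day(
            grp,
            sleep_day=sleep_by_day.get((pid, date)),
            resting_hr=rhr_lookup.get((pid, date)),
        )
        if row is not None:
            rows.append(row)
    return pd.DataFrame(rows, columns=DAY_SUMMARY_COLUMNS)


def patient_feature_means(
    summaries: pd.DataFrame,
    config: ValidationConfig | None = None,
    valid_days_only: bool = True,
) -> pd.DataFrame:
    """Stage one of two-stage averaging: per-patient feature means.

    Restricted to valid wear days (>= ``valid_day_minutes`` valid minutes)
    unless ``valid_days_only`` is False.
    """
    config = config or ValidationConfig()
    df = summaries
    if valid_days_only:
        df = df[df["valid_minutes"].astype(float) >= config.valid_day_minutes]
    means = df.groupby("patient_id")[FEATURES].mean()
    means["n_valid_days"] = df.groupby("patient_id").size()
    return means.reset_index()


def cohort_daily_table(
    summaries: pd.DataFrame,
    labels: pd.DataFrame,
    config: ValidationConfig | None = None,
) -> pd.DataFrame:
    """Per-group mean (SD) of each daily feature, patient-averaged first.

    ``labels`` needs columns ``patient_id`` and ``label`` (active/inactive).
    Raises ValueError when a group is empty.
    """
    per_patient = patient_feature_means(summaries, config)
    merged = per_patient.merge(labels[["patient_id", "label"]], on="patient_id", how="inner")
    rows = []
    groups = {g: d for g, d in merged.groupby("label")}
    for g in ("active", "inactive"):
        if g not in groups or groups[g].empty:
            raise ValueError(f"group {g!r} has no patients")
    for feat in FEATURES:
        row = {"feature": feat}
        for g, d in groups.items():
            vals = d[feat].dropna()
            row[f"{g}_mean"] = float(vals.mean()) if len(vals) else np.nan
            row[f"{g}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            row[f"{g}_n"] = int(len(vals))
        rows.append(row)
    return pd.DataFrame(rows)
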