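"""Minute-level wear validation for heart-rate-bearing wearable streams.

A minute with an observed heart rate counts as device wear.  Minutes with
missing HR but concurrent activity evidence (steps > 0, METs > 1.0 or a
raised intensity code) are gap-filled with the arithmetic mean of the nearest
observed-HR minute on each side; minutes without activity evidence, or
without a close-enough observed neighbour, are nonwear.  Implausible values
(HR strictly below ``hr_min`` or strictly above ``hr_max``) and flat-line
runs (>= ``flatline_min_run`` consecutive identical observed values) are then
excluded as non-physiological.  What survives is tallied into valid wear
days (>= ``valid_day_minutes`` valid minutes) and valid wear patients
(>= ``valid_patient_days`` valid days).

Pipeline order is wear detection -> gap fill -> plausibility exclusion ->
flat-line exclusion -> day tally; plausibility exclusion therefore applies to
filled values too (switchable via ``ValidationConfig.exclude_filled``).

Statuses partition the minutes: ``valid_observed``, ``valid_filled``,
``excluded`` (reason ``hr_below_min`` / ``hr_above_max`` / ``flatline_run``)
and ``nonwear`` (reason ``no_signal``).

Precedence details that the simple narrative leaves open, fixed here:

* "Adjacent" observed neighbours for gap filling must lie in the same
  calendar day and within ``max_fill_gap`` minutes on each side; filled
  values never seed further fills.
* Flat-line runs are detected over observed minutes only; a missing or
  filled minute, or a timestamp gap, breaks a run.  A minute already
  excluded by the plausibility window keeps that reason (a run is
  value-uniform, so this only matters for runs that are themselves
  implausible).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ValidationConfig

__all__ = [
    "ContractError",
    "STATUSES",
    "REASONS",
    "activity_gate",
    "fill_hr_gaps",
    "exclude_implausible",
    "exclude_flatlines",
    "day_verdicts",
    "validate_patient",
    "validate_cohort",
]

STATUSES = ("valid_observed", "valid_filled", "excluded", "nonwear")
REASONS = ("none", "hr_below_min", "hr_above_max", "flatline_run", "no_signal")

_MINUTE = np.timedelta64(1, "m")


class ContractError(ValueError):
    """Input violates a stage precondition (unsorted, duplicated, etc.)."""


def _check_stream(df: pd.DataFrame) -> None:
    if df.empty:
        return
    ts = df["timestamp"].to_numpy()
    if df["patient_id"].nunique() > 1:
        raise ContractError("validation stages operate on a single patient's stream")
    if not (ts[1:] > ts[:-1]).all():
        raise ContractError("minute stream must be sorted by timestamp with unique minutes")


def activity_gate(df: pd.DataFrame, config: ValidationConfig) -> np.ndarray:
    """Boolean mask of minutes with activity evidence despite missing HR.

    A minute passes when steps > ``steps_gate`` OR mets > ``met_gate`` OR
    intensity > ``intensity_gate``.  Missing METs/intensity never pass.
    """
    steps = df["steps"].to_numpy(dtype=float)
    mets = df["mets"].to_numpy(dtype=float)
    intensity = df["intensity"].to_numpy(dtype=float)
    gate = steps > config.steps_gate
    with np.errstate(invalid="ignore"):
        gate |= np.nan_to_num(mets, nan=-np.inf) > config.met_gate
        gate |= np.nan_to_num(intensity, nan=-np.inf) > config.intensity_gate
    return gate


def fill_hr_gaps(df: pd.DataFrame, config: ValidationConfig) -> pd.DataFrame:
    """Stage 1+2: wear detection and activity-gated HR gap filling.

    Returns the frame with ``status``, ``reason``, ``filled_hr`` and
    ``hr_effective`` columns added.  Observed-HR minutes become
    ``valid_observed``; gated missing-HR minutes with an observed neighbour
    on each side (same day, within ``max_fill_gap`` minutes) become
    ``valid_filled`` with the neighbour mean; everything else is nonwear.
    """
    _check_stream(df)
    out = df.copy()
    n = len(out)
    hr = out["hr"].to_numpy(dtype=float)
    observed = ~np.isnan(hr)
    status = np.where(observed, "valid_observed", "nonwear").astype(object)
    reason = np.where(observed, "none", "no_signal").astype(object)
    filled_hr = np.full(n, np.nan)

    if n and (~observed).any():
        gate = activity_gate(out, config)
        t = out["timestamp"].to_numpy().astype("datetime64[m]").astype(np.int64)
        day = out["timestamp"].to_numpy().astype("datetime64[D]").astype(np.int64)
        idx = np.arange(n, dtype=float)
        prev_obs = pd.Series(np.where(observed, idx, np.nan)).ffill().to_numpy()
        next_obs = pd.Series(np.where(observed, idx, np.nan)).bfill().to_numpy()
        cand = ~observed & gate & ~np.isnan(prev_obs) & ~np.isnan(next_obs)
        pi = np.where(np.isnan(prev_obs), 0, prev_obs).astype(int)
        ni = np.where(np.isnan(next_obs), 0, next_obs).astype(int)
        ok = (
            cand
            & (day[pi] == day)
            & (day[ni] == day)
            & (t - t[pi] <= config.max_fill_gap)
            & (t[ni] - t <= config.max_fill_gap)
        )
        filled_hr[ok] = (hr[pi[ok]] + hr[ni[ok]]) / 2.0
        status[ok] = "valid_filled"
        reason[ok] = "none"

    out["status"] = status
    out["reason"] = reason
    out["filled_hr"] = filled_hr
    out["hr_effective"] = np.where(np.isnan(hr), filled_hr, hr)
    return out


def exclude_implausible(df: pd.DataFrame, config: ValidationConfig) -> pd.DataFrame:
    """Stage 3: exclude minutes whose effective HR falls outside the window.

    Exclusion is strict: HR < ``hr_min`` or HR > ``hr_max``; the bounds
    themselves are retained.  Applies to observed minutes always and to
    filled minutes when ``config.exclude_filled`` is set.
    """
    out = df.copy()
    hr_eff = out["hr_effective"].to_numpy(dtype=float)
    status = out["status"].to_numpy(dtype=object)
    eligible = status == "valid_observed"
    if config.exclude_filled:
        eligible |= status == "valid_filled"
    with np.errstate(invalid="ignore"):
        low = eligible & (hr_eff < config.hr_min)
        high = eligible & (hr_eff > config.hr_max)
    status[low] = "excluded"
    status[high] = "excluded"
    reason = out["reason"].to_numpy(dtype=object)
    reason[low] = "hr_below_min"
    reason[high] = "hr_above_max"
    out["status"] = status
    out["reason"] = reason
    return out


def exclude_flatlines(df: pd.DataFrame, config: ValidationConfig) -> pd.DataFrame:
    """Stage 4: exclude maximal runs of identical consecutive observed HR.

    A run is a maximal sequence of observed-HR minutes that are timestamp
    adjacent (exactly 1 minute apart) with identical values; runs of length
    >= ``flatline_min_run`` are excluded.  Filled minutes and timestamp gaps
    break runs.  Minutes already excluded keep their earlier reason.
    """
    out = df.copy()
    hr = out["hr"].to_numpy(dtype=float)
    observed = ~np.isnan(hr)
    if not observed.any():
        return out
    t = out["timestamp"].to_numpy().astype("datetime64[m]").astype(np.int64)
    oi = np.flatnonzero(observed)
    ot, ohr = t[oi], hr[oi]
    # run break: non-adjacent timestamps or a value change
    new_run = np.ones(len(oi), dtype=bool)
    new_run[1:] = (np.diff(ot) != 1) | (ohr[1:] != ohr[:-1])
    run_id = np.cumsum(new_run)
    run_len = np.bincount(run_id)[run_id]
    flat = oi[run_len >= config.flatline_min_run]
    status = out["status"].to_numpy(dtype=object)
    reason = out["reason"].to_numpy(dtype=object)
    mark = flat[status[flat] == "valid_observed"]
    status[mark] = "excluded"
    reason[mark] = "flatline_run"
    out["status"] = status
    out["reason"] = reason
    return out


@dataclass(frozen=True)
class PatientVerdict:
    patient_id: str
    n_days: int
    n_valid_days: int
    is_valid_wear_patient: bool


def day_verdicts(flags: pd.DataFrame, config: ValidationConfig) -> pd.DataFrame:
    """Stage 5: tally flagged minutes into per-day wear verdicts."""
    if flags.empty:
        return pd.DataFrame(
            columns=[
                "patient_id", "date", "n_minutes", "valid_minutes",
                "excluded_hr_below_min", "excluded_hr_above_max",
                "excluded_flatline_run", "nonwear_minutes", "is_valid_day",
            ]
        )
    df = flags.copy()
    df["date"] = df["timestamp"].dt.date
    rows = []
    for (pid, date), grp in df.groupby(["patient_id", "date"], sort=True):
        reason = grp["reason"]
        status = grp["status"]
        valid = int(status.isin(["valid_observed", "valid_filled"]).sum())
        rows.append(
            {
                "patient_id": pid,
                "date": date,
                "n_minutes": len(grp),
                "valid_minutes": valid,
                "excluded_hr_below_min": int((reason == "hr_below_min").sum()),
                "excluded_hr_above_max": int((reason == "hr_above_max").sum()),
                "excluded_flatline_run": int((reason == "flatline_run").sum()),
                "nonwear_minutes": int((reason == "no_signal").sum()),
                "is_valid_day": valid >= config.valid_day_minutes,
            }
        )
    return pd.DataFrame(rows)


def validate_patient(
    df: pd.DataFrame, config: ValidationConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, bool]:
    """Run the full validation pipeline on one patient's minute stream.

    Returns ``(flags, day_verdicts, is_valid_wear_patient)``.  An empty
    stream yields zero days and an invalid patient.
    """
    config = config or ValidationConfig()
    _check_stream(df)
    flags = fill_hr_gaps(df, config)
    flags = exclude_implausible(flags, config)
    flags = exclude_flatlines(flags, config)
    days = day_verdicts(flags, config)
    n_valid = int(days["is_valid_day"].sum()) if len(days) else 0
    return flags, days, n_valid >= config.valid_patient_days


def validate_cohort(
    minutes: pd.DataFrame, config: ValidationConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Validate every patient in a combined minute frame.

    Returns ``(flags, day_verdicts, patient_verdicts)`` where
    ``patient_verdicts`` has one row per patient with the valid-day count and
    the >= ``valid_patient_days`` decision.
    """
    config = config or ValidationConfig()
    all_flags, all_days, verdicts = [], [], []
    for pid, grp in minutes.groupby("patient_id", sort=True):
        flags, days, ok = validate_patient(grp.reset_index(drop=True), config)
        all_flags.append(flags)
        all_days.append(days)
        verdicts.append(
            {
                "patient_id": pid,
                "n_days": len(days),
                "n_valid_days": int(days["is_valid_day"].sum()) if len(days) else 0,
                "is_valid_wear_patient": ok,
            }
        )
    flags = pd.concat(all_flags, ignore_index=True) if all_flags else pd.DataFrame()
    days = pd.concat(all_days, ignore_index=True) if all_days else day_verdicts(pd.DataFrame(), config)
    return flags, days, pd.DataFrame(verdicts, columns=["patient_id", "n_days", "n_valid_days", "is_valid_wear_patient"])


def exclusion_tally(flags: pd.DataFrame) -> dict[str, float]:
    """Cohort-level exclusion percentages, for the run report.

    Percentages are of all observed minutes (the denominator the field's
    preprocessing reports use); data-dependent, logged but never asserted.
    """
    if flags.empty:
        return {"observed_minutes": 0}
    observed = flags["hr"].notna()
    n_obs = int(observed.sum())
    out: dict[str, float] = {"observed_minutes": n_obs}
    for key in ("hr_below_min", "hr_above_max", "flatline_run"):
        n = int((flags["reason"] == key).sum())
        out[f"pct_{key}"] = 100.0 * n / n_obs if n_obs else 0.0
    return out
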