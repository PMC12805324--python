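"""MVPA phenotyping: classify valid-wear patients as active or inactive.

The WHO guideline of 150 MVPA minutes per week translates to a daily
threshold of 150/7 = 21.4 minutes (rounded half-up to one decimal).  A
patient's average daily MVPA over valid wear days in the baseline-to-6-month
window is compared against the threshold; "reached" is read inclusively
(>= threshold).  Deterministic label perturbations support the sensitivity
analysis: shifted thresholds, swapping the k patients nearest the cutoff,
stricter minimum-valid-day rules and shortened windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from datetime import date as Date
from typing import Any

import numpy as np
import pandas as pd

from .config import PhenotypeConfig, ValidationConfig

__all__ = [
    "PhenotypeLabel",
    "weekly_to_daily_threshold",
    "classify_patient",
    "classify_cohort",
    "perturb_labels",
]


@dataclass(frozen=True)
class PhenotypeLabel:
    patient_id: str
    mean_daily_mvpa: float
    label: str  # "active" | "inactive"
    window: tuple[Date | None, Date | None]
    threshold_used: float
    n_valid_days: int


def weekly_to_daily_threshold(weekly_minutes: float) -> float:
    """Convert a weekly MVPA guideline to a daily threshold.

    Divides by 7 and rounds half-up to one decimal (150 -> 21.4).
    """
    if weekly_minutes <= 0:
        raise ValueError("weekly_minutes must be positive")
    daily = Decimal(str(weekly_minutes)) / Decimal(7)
    return float(daily.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _window_mask(summaries: pd.DataFrame, window: tuple[Date | None, Date | None]) -> pd.Series:
    dates = pd.to_datetime(summaries["date"]).dt.date
    mask = pd.Series(True, index=summaries.index)
    start, end = window
    if start is not None:
        mask &= dates >= start
    if end is not None:
        mask &= dates <= end
    return mask


def classify_patient(
    day_summaries: pd.DataFrame,
    window: tuple[Date | None, Date | None] = (None, None),
    config: PhenotypeConfig | None = None,
    validation: ValidationConfig | None = None,
) -> PhenotypeLabel | None:
    """Label one patient from their day summaries.

    The mean is over valid wear days inside the window only.  Returns None
    (patient excluded) when fewer than ``config.min_valid_days`` valid days
    fall in the window.
    """
    config = config or PhenotypeConfig()
    validation = validation or ValidationConfig()
    df = day_summaries[_window_mask(day_summaries, window)]
    df = df[df["valid_minutes"].astype(float) >= validation.valid_day_minutes]
    if len(df) < config.min_valid_days:
        return None
    mean_mvpa = float(df["mvpa_minutes"].astype(float).mean())
    threshold = weekly_to_daily_threshold(config.weekly_mvpa_minutes)
    if config.inclusive_threshold:
        active = mean_mvpa >= threshold
    else:
        active = mean_mvpa > threshold
    return PhenotypeLabel(
        patient_id=str(day_summaries["patient_id"].iloc[0]),
        mean_daily_mvpa=mean_mvpa,
        label="active" if active else "inactive",
        window=window,
        threshold_used=threshold,
        n_valid_days=len(df),
    )


def classify_cohort(
    summaries: pd.DataFrame,
    pro_dates: pd.DataFrame | None = None,
    config: PhenotypeConfig | None = None,
    validation: ValidationConfig | None = None,
) -> pd.DataFrame:
    """Label every classifiable patient; returns a labels frame.

    ``pro_dates`` (optional) supplies per-patient windows via columns
    ``patient_id, baseline_date, m6_date``; without it the whole record is
    used.  Excluded patients (too few valid days) are listed with label
    ``excluded`` and the reason.
    """
    windows: dict[str, tuple[Date | None, Date | None]] = {}
    if pro_dates is not None and len(pro_dates):
        for row in pro_dates.itertuples(index=False):
            windows[str(row.patient_id)] = (
                pd.to_datetime(row.baseline_date).date(),
                pd.to_datetime(row.m6_date).date(),
            )
    rows = []
    for pid, grp in summaries.groupby("patient_id", sort=True):
        label = classify_patient(grp, windows.get(str(pid), (None, None)), config, validation)
        if label is None:
            rows.append(
                {
                    "patient_id": str(pid),
                    "mean_daily_mvpa": np.nan,
                    "label": "excluded",
                    "threshold_used": np.nan,
                    "n_valid_days": 0,
                    "reason": "insufficient_valid_days",
                }
            )
        else:
            rows.append(
                {
                    "patient_id": label.patient_id,
                    "mean_daily_mvpa": label.mean_daily_mvpa,
                    "label": label.label,
                    "threshold_used": label.threshold_used,
                    "n_valid_days": label.n_valid_days,
                    "reason": "",
                }
            )
    return pd.DataFrame(rows)


def perturb_labels(
    labels: pd.DataFrame,
    mode: str,
    summaries: pd.DataFrame | None = None,
    config: PhenotypeConfig | None = None,
    validation: ValidationConfig | None = None,
    **params: Any,
) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Produce a deterministic alternative labelling for sensitivity analysis.

    Modes
    -----
    ``threshold_delta`` (``pct``: signed percent change of the daily
        threshold): relabel classified patients against the shifted cutoff.
    ``swap_near_cutoff`` (``k``): flip the k classified patients whose mean
        daily MVPA lies nearest the cutoff.
    ``min_days`` (``m``): require at least m valid days; reclassify.
    ``window`` (``days``): truncate each patient's record to their first
        ``days`` calendar days before reclassifying (requires summaries).

    Returns the perturbed labels plus a provenance record.
    """
    config = config or PhenotypeConfig()
    provenance: dict[str, Any] = {"mode": mode, **params}
    classified = labels[labels["label"].isin(["active", "inactive"])].copy()

    if mode == "threshold_delta":
        pct = float(params.get("pct", 0.0))
        base = weekly_to_daily_threshold(config.weekly_mvpa_minutes)
        new_thr = base * (1.0 + pct / 100.0)
        out = labels.copy()
        mask = out["label"].isin(["active", "inactive"])
        mvpa = out.loc[mask, "mean_daily_mvpa"].astype(float)
        active = mvpa >= new_thr if config.inclusive_threshold else mvpa > new_thr
        out.loc[mask, "label"] = np.where(active, "active", "inactive")
        out.loc[mask, "threshold_used"] = new_thr
        provenance["threshold"] = new_thr
        return out, provenance

    if mode == "swap_near_cutoff":
        k = int(params.get("k", 2))
        thr = classified["threshold_used"].astype(float)
        dist = (classified["mean_daily_mvpa"].astype(float) - thr).abs()
        flip_ids = set(classified.assign(_d=dist).nsmallest(k, "_d")["patient_id"])
        out = labels.copy()
        flip = out["patient_id"].isin(flip_ids) & out["label"].isin(["active", "inactive"])
        out.loc[flip, "label"] = out.loc[flip, "label"].map({"active": "inactive", "inactive": "active"})
        provenance["flipped"] = sorted(flip_ids)
        return out, provenance

    if mode == "min_days":
        m = int(params.get("m", config.min_valid_days))
        out = labels.copy()
        demote = out["n_valid_days"].astype(float) < m
        out.loc[demote, "label"] = "excluded"
        out.loc[demote, "reason"] = f"fewer_than_{m}_valid_days"
        provenance["min_days"] = m
        return out, provenance

    if mode == "window":
        if summaries is None:
            raise ValueError("window perturbation needs day summaries")
        days = int(params["days"])
        trimmed = []
        for pid, grp in summaries.groupby("patient_id", sort=True):
            dates = pd.to_datetime(grp["date"]).dt.date
            start = dates.min()
            keep = (pd.to_datetime(grp["date"]).dt.date - start).map(lambda d: d.days) < days
            trimmed.append(grp[keep.to_numpy()])
        trimmed_df = pd.concat(trimmed, ignore_index=True) if trimmed else summaries.iloc[:0]
        out = classify_cohort(trimmed_df, config=config, validation=validation)
        provenance["window_days"] = days
        return out, provenance

    raise ValueError(f"unknown perturbation mode {mode!r}")
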