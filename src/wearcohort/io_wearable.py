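"""Readers and writers for the file dialects the pipeline touches.

Minute-level wearable exports arrive in a Fitabase-style CSV dialect: one row
per device minute with heart rate, step count, METs and an ordinal intensity
code (0=sedentary, 1=light, 2=fairly active, 3=very active).  Fitabase METs
exports are scaled by 10 (a stored value of 12 means 1.2 METs), so the dialect
carries a configurable divisor.  Patient-reported outcomes (PRO) travel in a
long CSV ``patient_id,wave,measure,value``; day summaries round-trip through
:func:`write_day_summaries` / :func:`read_day_summaries`.

Timestamps are local civil time at minute resolution; days are
midnight-to-midnight.  Missing heart rate is encoded as absent (NaN), never 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd

__all__ = [
    "MinuteDialect",
    "ProRecord",
    "FormatError",
    "WAVES",
    "INSTRUMENT_RANGES",
    "read_minute_csv",
    "write_minute_csv",
    "read_pro_table",
    "write_pro_table",
    "pro_records_to_frame",
    "read_day_summaries",
    "write_day_summaries",
    "read_sleep_csv",
    "write_sleep_csv",
]

#: Canonical PRO wave labels, in temporal order.
WAVES = ("baseline", "m3", "m6")

#: Documented score ranges for the instruments the pipeline validates on read.
#: PROMIS T-scores typically fall in 20-80 but are not hard-bounded, so they
#: are checked loosely (0-100); raw instrument totals are hard-bounded.
INSTRUMENT_RANGES: dict[str, tuple[float, float]] = {
    "phq2": (0, 6),
    "gad7": (0, 21),
}

_SYMPTOM_RATING_RANGE = (0, 4)


class FormatError(ValueError):
    """A file does not conform to the declared dialect."""


@dataclass(frozen=True)
class MinuteDialect:
    """Column mapping and conventions of a minute-level CSV export."""

    id_col: str = "Id"
    time_col: str = "ActivityMinute"
    hr_col: str = "HeartRate"
    steps_col: str = "Steps"
    mets_col: str = "METs"
    intensity_col: str = "Intensity"
    datetime_format: str | None = None  # None -> pandas inference
    mets_divisor: float = 10.0  # Fitabase stores METs x10

    @property
    def columns(self) -> dict[str, str]:
        return {
            self.id_col: "patient_id",
            self.time_col: "timestamp",
            self.hr_col: "hr",
            self.steps_col: "steps",
            self.mets_col: "mets",
            self.intensity_col: "intensity",
        }


@dataclass
class ProRecord:
    """One patient-wave set of PRO scores and symptom reports.

    ``scores`` maps measure name -> value (e.g. ``phq2``, ``gad7``,
    ``promis_fatigue_t``); ``symptoms`` maps symptom name -> a dict with keys
    ``present`` (yes/no/unknown), ``frequency`` and ``intensity`` (ordinal
    0-4).  An absent symptom carries frequency = intensity = 0.
    """

    patient_id: str
    wave: str
    scores: dict[str, float] = field(default_factory=dict)
    symptoms: dict[str, dict[str, Any]] = field(default_factory=dict)
    pem_flag: str = "unknown"

    def __post_init__(self) -> None:
        if self.wave not in WAVES:
            raise FormatError(f"unknown wave {self.wave!r}; expected one of {WAVES}")


def _require_columns(df: pd.DataFrame, required: Iterable[str], path: Any) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def read_minute_csv(path: str | Path, dialect: MinuteDialect | None = None) -> pd.DataFrame:
    """Read a minute-level wearable CSV into the canonical frame.

    Returns a DataFrame with columns ``patient_id, timestamp, hr, steps,
    mets, intensity`` sorted by (patient_id, timestamp).  METs are rescaled
    by the dialect divisor; missing HR becomes NaN.  Duplicate timestamps
    within a patient are rejected.
    """
    dialect = dialect or MinuteDialect()
    df = pd.read_csv(path, dtype={dialect.id_col: str})
    _require_columns(df, dialect.columns, path)
    df = df.rename(columns=dialect.columns)[list(dialect.columns.values())]
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], format=dialect.datetime_format)
    except (ValueError, TypeError) as exc:
        bad = _first_bad_datetime(df["timestamp"], dialect.datetime_format)
        raise FormatError(f"{path}: unparseable datetime at data row {bad}") from exc
    if (df["timestamp"].dt.second != 0).any():
        raise FormatError(f"{path}: timestamps must be minute-aligned (seconds == 0)")
    df["hr"] = pd.to_numeric(df["hr"], errors="coerce")
    df.loc[df["hr"] == 0, "hr"] = np.nan  # 0 bpm is an encoding of absence
    df["steps"] = pd.to_numeric(df["steps"]).fillna(0).astype(int)
    if (df["steps"] < 0).any():
        raise FormatError(f"{path}: negative step counts")
    df["mets"] = pd.to_numeric(df["mets"], errors="coerce") / dialect.mets_divisor
    df["intensity"] = pd.to_numeric(df["intensity"], errors="coerce")
    bad_int = df["intensity"].dropna()
    if not bad_int.isin([0, 1, 2, 3]).all():
        raise FormatError(f"{path}: intensity codes must be in 0..3")
    df = df.sort_values(["patient_id", "timestamp"], kind="mergesort").reset_index(drop=True)
    dup = df.duplicated(subset=["patient_id", "timestamp"])
    if dup.any():
        first = df.loc[dup.idxmax()]
        raise FormatError(
            f"{path}: duplicate timestamp {first['timestamp']} for patient {first['patient_id']}"
        )
    return df


def _first_bad_datetime(series: pd.Series, fmt: str | None) -> int:
    parsed = pd.to_datetime(series, format=fmt, errors="coerce")
    bad = parsed.isna() & series.notna()
    return int(np.argmax(bad.to_numpy())) + 1 if bad.any() else -1


def write_minute_csv(df: pd.DataFrame, path: str | Path, dialect: MinuteDialect | None = None) -> None:
    """Write the canonical minute frame back to the dialect's CSV layout."""
    dialect = dialect or MinuteDialect()
    out = pd.DataFrame(
        {
            dialect.id_col: df["patient_id"],
            dialect.time_col: df["timestamp"].dt.strftime("%Y-%m-%d %H:%M:%S"),
            dialect.hr_col: df["hr"],
            dialect.steps_col: df["steps"],
            dialect.mets_col: (df["mets"] * dialect.mets_divisor).round(0).astype("Int64"),
            dialect.intensity_col: df["intensity"],
        }
    )
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# PRO tables
# ---------------------------------------------------------------------------

def _validate_measure(measure: str, value: float) -> None:
    if measure in INSTRUMENT_RANGES:
        lo, hi = INSTRUMENT_RANGES[measure]
        if not (lo <= value <= hi):
            raise FormatError(f"{measure} value {value} outside documented range {lo}-{hi}")
    elif measure.endswith(("_freq", "_int")):
        lo, hi = _SYMPTOM_RATING_RANGE
        if not (lo <= value <= hi):
            raise FormatError(f"{measure} rating {value} outside {lo}-{hi}")
    elif measure.endswith("_t"):
        if not (0 <= value <= 100):
            raise FormatError(f"T-score {measure}={value} outside plausible 0-100 band")


def read_pro_table(path: str | Path) -> list[ProRecord]:
    """Read a long-format PRO CSV (``patient_id,wave,measure,value``).

    One :class:`ProRecord` per patient-wave.  Out-of-range instrument scores
    raise :class:`FormatError` rather than being silently clamped.  Symptom
    measures use the naming convention ``symptom_<name>_present`` (0/1),
    ``symptom_<name>_freq`` and ``symptom_<name>_int``.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "wave": str, "measure": str})
    _require_columns(df, ["patient_id", "wave", "measure", "value"], path)
    records: dict[tuple[str, str], ProRecord] = {}
    for row in df.itertuples(index=False):
        key = (row.patient_id, row.wave)
        if key not in records:
            records[key] = ProRecord(patient_id=row.patient_id, wave=row.wave)
        rec = records[key]
        measure, value = row.measure, float(row.value)
        if measure == "pem":
            rec.pem_flag = {1.0: "yes", 0.0: "no"}.get(value, "unknown")
            continue
        if measure.startswith("symptom_"):
            stem, _, kind = measure.rpartition("_")
            name = stem[len("symptom_"):]
            entry = rec.symptoms.setdefault(name, {"present": "unknown", "frequency": 0, "intensity": 0})
            if kind == "present":
                entry["present"] = {1.0: "yes", 0.0: "no"}.get(value, "unknown")
            else:
                _validate_measure(measure, value)
                entry["frequency" if kind == "freq" else "intensity"] = int(value)
            continue
        _validate_measure(measure, value)
        rec.scores[measure] = value
    out = sorted(records.values(), key=lambda r: (r.patient_id, WAVES.index(r.wave)))
    for rec in out:
        for name, entry in rec.symptoms.items():
            if entry["present"] == "no" and (entry["frequency"] or entry["intensity"]):
                raise FormatError(
                    f"{path}: symptom {name} absent but rated for patient {rec.patient_id}"
                )
    return out


def write_pro_table(records: Iterable[ProRecord], path: str | Path) -> None:
    """Write ProRecords to the long CSV dialect (inverse of read_pro_table)."""
    rows: list[tuple[str, str, str, float]] = []
    for rec in records:
        for measure in sorted(rec.scores):
            rows.append((rec.patient_id, rec.wave, measure, rec.scores[measure]))
        for name in sorted(rec.symptoms):
            entry = rec.symptoms[name]
            present = {"yes": 1.0, "no": 0.0}.get(entry["present"], np.nan)
            rows.append((rec.patient_id, rec.wave, f"symptom_{name}_present", present))
            rows.append((rec.patient_id, rec.wave, f"symptom_{name}_freq", float(entry["frequency"])))
            rows.append((rec.patient_id, rec.wave, f"symptom_{name}_int", float(entry["intensity"])))
        if rec.pem_flag != "unknown":
            rows.append((rec.patient_id, rec.wave, "pem", 1.0 if rec.pem_flag == "yes" else 0.0))
    pd.DataFrame(rows, columns=["patient_id", "wave", "measure", "value"]).to_csv(path, index=False)


def pro_records_to_frame(records: Iterable[ProRecord]) -> pd.DataFrame:
    """Flatten ProRecords into a wide frame (one row per patient-wave)."""
    rows = []
    for rec in records:
        row: dict[str, Any] = {"patient_id": rec.patient_id, "wave": rec.wave, "pem": rec.pem_flag}
        row.update(rec.scores)
        for name, entry in rec.symptoms.items():
            row[f"symptom_{name}_present"] = entry["present"]
            row[f"symptom_{name}_freq"] = entry["frequency"]
            row[f"symptom_{name}_int"] = entry["intensity"]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Day summaries and sleep
# ---------------------------------------------------------------------------

DAY_SUMMARY_COLUMNS = [
    "patient_id",
    "date",
    "valid_minutes",
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

_DAY_INT_COLUMNS = {"valid_minutes", "light_minutes", "mvpa_minutes", "steps"}


def write_day_summaries(summaries: pd.DataFrame, path: str | Path) -> None:
    """Write day summaries as CSV with the documented column order.

    Integers round-trip bit-exact; floats are written with 6 decimals.
    An empty frame yields a header-only file.
    """
    df = summaries.copy()
    for col in DAY_SUMMARY_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[DAY_SUMMARY_COLUMNS]
    df.to_csv(path, index=False, float_format="%.6f")


def read_day_summaries(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    _require_columns(df, DAY_SUMMARY_COLUMNS, path)
    df["date"] = pd.to_datetime(df["date"]).dt.date
    for col in _DAY_INT_COLUMNS:
        df[col] = df[col].astype("Int64")
    return df.sort_values(["patient_id", "date"], kind="mergesort").reset_index(drop=True)


SLEEP_COLUMNS = ["patient_id", "bed_start", "bed_end", "minutes_asleep", "minutes_in_bed"]


def read_sleep_csv(path: str | Path) -> pd.DataFrame:
    """Read daily sleep sessions; enforces asleep <= in-bed and start < end."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    _require_columns(df, SLEEP_COLUMNS, path)
    df["bed_start"] = pd.to_datetime(df["bed_start"])
    df["bed_end"] = pd.to_datetime(df["bed_end"])
    if (df["bed_start"] >= df["bed_end"]).any():
        raise FormatError(f"{path}: bed_start must precede bed_end")
    if (df["minutes_asleep"] > df["minutes_in_bed"]).any():
        raise FormatError(f"{path}: minutes_asleep exceeds minutes_in_bed")
    return df.sort_values(["patient_id", "bed_start"], kind="mergesort").reset_index(drop=True)


def write_sleep_csv(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    for col in ("bed_start", "bed_end"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d %H:%M:%S")
    out[SLEEP_COLUMNS].to_csv(path, index=False)
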