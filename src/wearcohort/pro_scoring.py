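"""Patient-reported outcome scoring.

Covers instrument totals (PHQ-2, GAD-7, PROMIS raw domain sums), the CDC
Symptom Inventory-style severity composite (frequency x intensity on 0-4
scales, range 0-16), three-level severity categories from PROMIS T-scores,
and within-subject wave-to-wave change scores.

Domain directionality matters: on PHQ-2, GAD-7 and most PROMIS scales a
higher score is worse, while physical function, social roles and cognition
run the other way.  Severity categories mirror accordingly: a higher-worse
domain is acceptable/mild below T=60, moderate in [60, 70) and significant
at 70+; a lower-worse domain uses 40 / 30.

PROMIS raw-to-T conversion is deliberately not shipped (the conversion
tables are licensed HealthMeasures content); a user-supplied lookup CSV is
accepted instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_SEVERITY_CUTOFFS
from .io_wearable import ProRecord, WAVES

__all__ = [
    "SYMPTOMS",
    "LOWER_WORSE_DOMAINS",
    "PHQ2_FLAG_CUTOFF",
    "severity_score",
    "instrument_totals",
    "severity_category",
    "change_scores",
    "score_records",
    "load_tscore_table",
    "raw_to_t",
]

#: The eight screener symptoms, in table order.
SYMPTOMS = (
    "fatigue",
    "muscle_pain",
    "joint_pain",
    "unrefreshing_sleep",
    "sleep_problems",
    "forgetfulness",
    "concentration",
    "dizziness",
)

#: PROMIS domains on which a LOWER score indicates more severe problems.
LOWER_WORSE_DOMAINS = frozenset({"physical_function", "social_roles", "cognition"})

#: A PHQ-2 total of 3 or greater flags likely major depressive disorder.
PHQ2_FLAG_CUTOFF = 3

SEVERITY_CATEGORIES = ("acceptable_mild", "moderate", "significant")


def severity_score(frequency: int, intensity: int) -> int:
    """Symptom severity composite: frequency x intensity, each rated 0-4.

    The product form is the only composite consistent with the documented
    0-16 range; an absent symptom (both ratings 0) scores 0.
    """
    f, i = int(frequency), int(intensity)
    if not (0 <= f <= 4 and 0 <= i <= 4):
        raise ValueError(f"ratings must be in 0-4, got frequency={frequency}, intensity={intensity}")
    return f * i


@dataclass(frozen=True)
class InstrumentTotals:
    phq2: int | None
    phq2_flag: bool | None
    gad7: int | None
    promis_raw: dict[str, int]


def _checked_sum(items: Sequence[float] | None, n_items: int, lo: int, hi: int, name: str) -> int | None:
    if items is None:
        return None
    if len(items) != n_items:
        return None  # incomplete item set -> no prorating, total absent
    arr = [int(v) for v in items]
    if any(v < lo or v > hi for v in arr):
        raise ValueError(f"{name} item out of range {lo}-{hi}: {items}")
    return sum(arr)


def instrument_totals(
    phq2_items: Sequence[int] | None = None,
    gad7_items: Sequence[int] | None = None,
    promis_items: Mapping[str, Sequence[int]] | None = None,
) -> InstrumentTotals:
    """Simple sums of complete item sets; missing any item voids the total.

    PHQ-2: 2 items scored 0-3 (total 0-6, flag at >= 3); GAD-7: 7 items
    scored 0-3 (total 0-21); PROMIS-29 domains: 4 items scored 1-5
    (raw 4-20).
    """
    phq2 = _checked_sum(phq2_items, 2, 0, 3, "PHQ-2")
    gad7 = _checked_sum(gad7_items, 7, 0, 3, "GAD-7")
    promis: dict[str, int] = {}
    for domain, items in (promis_items or {}).items():
        total = _checked_sum(items, 4, 1, 5, f"PROMIS {domain}")
        if total is not None:
            promis[domain] = total
    return InstrumentTotals(
        phq2=phq2,
        phq2_flag=None if phq2 is None else phq2 >= PHQ2_FLAG_CUTOFF,
        gad7=gad7,
        promis_raw=promis,
    )


def severity_category(
    t_score: float,
    domain: str,
    cutoffs: Mapping[str, tuple[float, float]] | None = None,
) -> str:
    """Map a PROMIS T-score to acceptable/mild, moderate or significant.

    Higher-worse domains: T < 60 acceptable/mild, 60 <= T < 70 moderate,
    T >= 70 significant.  Lower-worse domains (physical function, social
    roles, cognition) mirror at 40 / 30; both cutoff pairs are configurable.
    """
    cutoffs = cutoffs or DEFAULT_SEVERITY_CUTOFFS
    if domain in LOWER_WORSE_DOMAINS:
        mild, severe = cutoffs["lower_worse"]
        if t_score <= severe:
            return "significant"
        if t_score <= mild:
            return "moderate"
        return "acceptable_mild"
    mild, severe = cutoffs["higher_worse"]
    if t_score >= severe:
        return "significant"
    if t_score >= mild:
        return "moderate"
    return "acceptable_mild"


def change_scores(scores: pd.DataFrame, from_wave: str = "baseline") -> pd.DataFrame:
    """Within-subject deltas from baseline to each follow-up wave.

    ``scores`` is long: columns ``patient_id, wave, measure, value``.  A
    delta is emitted only when both waves are present for that
    patient-measure (pairwise within-subject calculation); absent pairs are
    skipped.  Returns columns ``patient_id, measure, from_wave, to_wave,
    delta``.
    """
    wide = scores.pivot_table(
        index=["patient_id", "measure"], columns="wave", values="value", aggfunc="first"
    )
    rows = []
    for to_wave in [w for w in WAVES if w != from_wave]:
        if from_wave not in wide.columns or to_wave not in wide.columns:
            continue
        both = wide[[from_wave, to_wave]].dropna()
        for (pid, measure), row in both.iterrows():
            rows.append(
                {
                    "patient_id": pid,
                    "measure": measure,
                    "from_wave": from_wave,
                    "to_wave": to_wave,
                    "delta": float(row[to_wave] - row[from_wave]),
                }
            )
    return pd.DataFrame(rows, columns=["patient_id", "measure", "from_wave", "to_wave", "delta"])


def group_change_table(deltas: pd.DataFrame, labels: pd.DataFrame) -> pd.DataFrame:
    """Group mean (SD, n) of change scores per measure and follow-up wave."""
    merged = deltas.merge(labels[["patient_id", "label"]], on="patient_id")
    rows = []
    for (measure, to_wave, label), grp in merged.groupby(["measure", "to_wave", "label"]):
        rows.append(
            {
                "measure": measure,
                "to_wave": to_wave,
                "label": label,
                "mean_delta": float(grp["delta"].mean()),
                "sd_delta": float(grp["delta"].std(ddof=1)) if len(grp) > 1 else 0.0,
                "n": int(len(grp)),
            }
        )
    return pd.DataFrame(rows)


def score_records(records: Iterable[ProRecord]) -> pd.DataFrame:
    """Derive severity scores and flags from raw PRO records.

    Returns a long frame ``patient_id, wave, measure, value`` containing the
    original instrument scores plus ``severity_<symptom>`` composites and the
    ``phq2_flag`` indicator.  Follow-up symptom gating is honoured upstream
    (a symptom absent at baseline has no follow-up record); here every rated
    symptom present in the record is scored.
    """
    rows = []
    for rec in records:
        for measure, value in rec.scores.items():
            rows.append((rec.patient_id, rec.wave, measure, float(value)))
        if "phq2" in rec.scores:
            rows.append(
                (rec.patient_id, rec.wave, "phq2_flag", float(rec.scores["phq2"] >= PHQ2_FLAG_CUTOFF))
            )
        for name, entry in rec.symptoms.items():
            if entry.get("present") == "unknown":
                continue
            score = severity_score(entry.get("frequency", 0), entry.get("intensity", 0))
            rows.append((rec.patient_id, rec.wave, f"severity_{name}", float(score)))
            rows.append(
                (rec.patient_id, rec.wave, f"symptom_{name}_present",
                 1.0 if entry.get("present") == "yes" else 0.0)
            )
        if rec.pem_flag != "unknown":
            rows.append((rec.patient_id, rec.wave, "pem", 1.0 if rec.pem_flag == "yes" else 0.0))
    return pd.DataFrame(rows, columns=["patient_id", "wave", "measure", "value"])


def load_tscore_table(path: str | Path) -> dict[str, dict[int, float]]:
    """Load a user-supplied raw->T lookup CSV (``domain,raw,t``)."""
    df = pd.read_csv(path)
    for col in ("domain", "raw", "t"):
        if col not in df.columns:
            raise ValueError(f"T-score table missing column {col!r}")
    table: dict[str, dict[int, float]] = {}
    for row in df.itertuples(index=False):
        table.setdefault(str(row.domain), {})[int(row.raw)] = float(row.t)
    return table


def raw_to_t(raw: int, domain: str, table: Mapping[str, Mapping[int, float]]) -> float:
    """Convert a raw domain sum to a T-score via the supplied lookup."""
    try:
        return table[domain][int(raw)]
    except KeyError as exc:
        raise KeyError(f"no T-score entry for domain={domain!r} raw={raw}") from exc
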