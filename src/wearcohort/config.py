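"""Configuration objects shared across the pipeline.

Every threshold the validation and phenotyping stages use is surfaced here as a
named field so a run manifest can record exactly which rules produced a result.
Values default to the conventions of minute-level Fitbit preprocessing for
clinical cohorts: a plausibility window of 45–205 bpm, flat-line exclusion at
11 consecutive identical minutes, a valid wear day of at least 1200 minutes
(20 h) and a valid wear patient of at least 7 valid days.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml


@dataclass(frozen=True)
class ValidationConfig:
    """Thresholds governing minute-level wear validation.

    Parameters
    ----------
    hr_min, hr_max : float
        Physiological plausibility window in beats/minute. Exclusion is
        strict: exactly ``hr_min`` or ``hr_max`` is retained.
    flatline_min_run : int
        Minimum length (minutes) of a run of identical consecutive observed
        heart-rate values that is treated as non-physiological and excluded.
    steps_gate, met_gate, intensity_gate : thresholds for the activity gate
        that decides whether a missing-HR minute is eligible for gap filling
        (``steps > steps_gate OR mets > met_gate OR intensity >
        intensity_gate``).
    max_fill_gap : int
        Maximum distance in minutes to an observed-HR neighbour (on each
        side, within the same calendar day) for gap filling; longer gaps are
        treated as nonwear rather than interpolated.
    valid_day_minutes : int
        Minimum valid minutes for a calendar day to count as a valid wear day.
    valid_patient_days : int
        Minimum valid wear days for a patient to enter analyses.
    """

    hr_min: float = 45.0
    hr_max: float = 205.0
    flatline_min_run: int = 11
    steps_gate: int = 0
    met_gate: float = 1.0
    intensity_gate: int = 0
    max_fill_gap: int = 60
    valid_day_minutes: int = 1200
    valid_patient_days: int = 7
    exclude_filled: bool = True  # plausibility exclusion also applies to filled values

    def __post_init__(self) -> None:
        if not self.hr_min < self.hr_max:
            raise ValueError(f"hr_min ({self.hr_min}) must be < hr_max ({self.hr_max})")
        for name in ("flatline_min_run", "max_fill_gap", "valid_day_minutes", "valid_patient_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


@dataclass(frozen=True)
class PhenotypeConfig:
    """MVPA phenotyping rules.

    The WHO guideline of 150 MVPA minutes/week is converted to a daily
    threshold (21.4 min/day); a patient whose average daily MVPA over valid
    wear days reaches the threshold is labelled ``active``.
    """

    weekly_mvpa_minutes: float = 150.0
    inclusive_threshold: bool = True  # "reached" = >= threshold
    min_valid_days: int = 7

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


#: PROMIS severity-category cutoffs: conventional 1-SD / 2-SD T-score bands.
#: Higher-worse domains: acceptable/mild below 60, moderate 60–70, significant at 70+.
#: Lower-worse domains mirror at 40 / 30.
DEFAULT_SEVERITY_CUTOFFS: dict[str, tuple[float, float]] = {
    "higher_worse": (60.0, 70.0),
    "lower_worse": (40.0, 30.0),
}


def load_yaml_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML config file into a plain dict (empty file -> empty dict)."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return data or {}


def validation_config_from_dict(d: dict[str, Any]) -> ValidationConfig:
    known = {f for f in ValidationConfig.__dataclass_fields__}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown validation config keys: {sorted(unknown)}")
    return ValidationConfig(**d)
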