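"""Validate the cohort's minute-level wear data.

Reads the simulated minute streams, applies HR-based wear detection,
activity-gated gap filling, the 45-205 bpm plausibility window, the
11-minute flat-line rule, and the 1200-minute valid-day / 7-day
valid-patient rules; then cross-checks the exclusion counts against the
generator's artifact ledger.

Run after 01:  python analysis/02_validate_wear.py
"""

from __future__ import annotations

import json
from pathlib import Path

from wearcohort.config import ValidationConfig
from wearcohort.io_wearable import read_minute_csv
from wearcohort.wear_validation import exclusion_tally, validate_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    import pandas as pd

    cohort = RESULTS / "cohort"
    minutes = read_minute_csv(cohort / "minutes.csv")
    config = ValidationConfig()
    flags, days, patients = validate_cohort(minutes, config)

    out = RESULTS / "validation"
    out.mkdir(parents=True, exist_ok=True)
    flags.to_csv(out / "minute_flags.csv", index=False)
    days.to_csv(out / "day_verdicts.csv", index=False)
    patients.to_csv(out / "patient_verdicts.csv", index=False)
    tally = exclusion_tally(flags)
    (out / "exclusion_tally.json").write_text(json.dumps(tally, indent=2, sort_keys=True))

    artifacts = pd.read_csv(cohort / "artifacts_truth.csv")
    injected_flat = int(artifacts.loc[(artifacts["type"] == "flatline")
                                      & (artifacts["length"] >= config.flatline_min_run),
                                      "length"].sum())
    flagged_flat = int((flags["reason"] == "flatline_run").sum())
    print(f"valid wear patients: {int(patients['is_valid_wear_patient'].sum())} / {len(patients)}")
    print(f"valid days: {int(days['is_valid_day'].sum())} / {len(days)}")
    print("exclusions (% of observed minutes): "
          + ", ".join(f"{k.removeprefix('pct_')}={v:.3f}%" for k, v in tally.items() if k.startswith("pct_")))
    print(f"flat-line cross-check: injected {injected_flat} minutes (runs >= "
          f"{config.flatline_min_run}), pipeline flagged {flagged_flat}")


if __name__ == "__main__":
    main()
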