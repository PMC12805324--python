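"""Daily features and MVPA phenotypes.

Aggregates validated minutes and sleep sessions into day summaries,
classifies valid-wear patients against the 21.4 min/day threshold (WHO 150
min/week over 7 days), compares the labels with the generator's true
phenotypes, and writes the group-level daily-feature table.

Run after 02:  python analysis/03_features_and_phenotypes.py
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from wearcohort.daily_features import cohort_daily_table, summarize_cohort_days
from wearcohort.io_wearable import read_sleep_csv, write_day_summaries
from wearcohort.phenotyping import classify_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    flags = pd.read_csv(RESULTS / "validation" / "minute_flags.csv",
                        parse_dates=["timestamp"], dtype={"patient_id": str})
    sleep = read_sleep_csv(RESULTS / "cohort" / "sleep.csv")
    summaries = summarize_cohort_days(flags, sleep)
    write_day_summaries(summaries, RESULTS / "day_summaries.csv")

    patients = pd.read_csv(RESULTS / "validation" / "patient_verdicts.csv", dtype={"patient_id": str})
    valid = patients.loc[patients["is_valid_wear_patient"], "patient_id"]
    labels = classify_cohort(summaries[summaries["patient_id"].isin(valid)])
    labels.to_csv(RESULTS / "labels.csv", index=False)

    truth = pd.read_csv(RESULTS / "cohort" / "profiles_truth.csv", dtype={"patient_id": str})
    merged = labels.merge(truth[["patient_id", "group"]], on="patient_id")
    classified = merged[merged["label"].isin(["active", "inactive"])]
    agree = (classified["label"] == classified["group"]).mean() if len(classified) else float("nan")

    table = cohort_daily_table(summaries, labels)
    table.to_csv(RESULTS / "fitbit_group_table.csv", index=False, float_format="%.3f")

    print(f"day summaries: {len(summaries)} patient-days")
    print(f"labels: {labels['label'].value_counts().to_dict()}")
    print(f"agreement with generating phenotype: {agree:.1%}")
    mvpa = table[table["feature"] == "mvpa_minutes"].iloc[0]
    print(f"group daily MVPA: active {mvpa['active_mean']:.1f} ({mvpa['active_sd']:.1f}) vs "
          f"inactive {mvpa['inactive_mean']:.1f} ({mvpa['inactive_sd']:.1f}) min")


if __name__ == "__main__":
    main()
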