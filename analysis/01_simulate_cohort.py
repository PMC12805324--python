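"""Generate the synthetic study cohort.

Draws 41 MVPA-active and 41 MVPA-inactive patients with lognormal follow-up
(median ~42 valid days), writes their minute-level wearable streams, sleep
sessions and three-wave PRO tables under results/cohort/, and keeps the
ground-truth ledger (true phenotypes, injected artifacts) alongside for the
later recovery checks.

Run:  python analysis/01_simulate_cohort.py [--seed 7] [--scale 0.25]

--scale shrinks the cohort proportionally for quick runs (default 0.25 ->
about 10 patients per group; use 1.0 for the full 82-patient cohort).
"""

from __future__ import annotations

import argparse
from pathlib import Path

import numpy as np

from wearcohort.io_wearable import write_minute_csv, write_pro_table, write_sleep_csv
from wearcohort.synthetic_data import (
    CohortConfig,
    generate_cohort_minutes,
    generate_profiles,
    generate_pro_waves,
    generate_sleep_records,
)

RESULTS = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=7)
    parser.add_argument("--scale", type=float, default=0.25)
    args = parser.parse_args()

    config = CohortConfig(
        n_active=max(int(41 * args.scale), 2),
        n_inactive=max(int(41 * args.scale), 2),
        followup_max_days=int(120 * max(args.scale, 0.25)),
    )
    rng = np.random.default_rng(args.seed)
    RESULTS.mkdir(parents=True, exist_ok=True)

    profiles = generate_profiles(config, rng)
    minutes, ledger = generate_cohort_minutes(config, rng, profiles)
    sleep = generate_sleep_records(profiles, config, rng)
    pro, _ = generate_pro_waves(profiles, config, rng)

    write_minute_csv(minutes, RESULTS / "minutes.csv")
    write_sleep_csv(sleep, RESULTS / "sleep.csv")
    write_pro_table(pro, RESULTS / "pro.csv")
    profiles.to_csv(RESULTS / "profiles_truth.csv", index=False)
    ledger.artifacts.to_csv(RESULTS / "artifacts_truth.csv", index=False)

    n_min = len(minutes)
    print(f"cohort: {len(profiles)} patients ({(profiles['group'] == 'active').sum()} active), "
          f"{profiles['n_days'].sum()} patient-days, {n_min} minutes")
    print(f"injected artifacts: {ledger.artifacts['type'].value_counts().to_dict()}")
    print(f"written under {RESULTS}")


if __name__ == "__main__":
    main()
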