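"""Generator contracts: determinism, signal consistency, ledger completeness."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from wearcohort.config import ValidationConfig
from wearcohort.synthetic_data import (
    ArtifactConfig,
    CohortConfig,
    ProMeasureConfig,
    generate_cohort_minutes,
    generate_minute_day,
    generate_patient_minutes,
    generate_profiles,
    generate_pro_long,
    generate_pro_waves,
    make_fixture_suite,
)
from wearcohort.wear_validation import validate_patient


def _profile(mvpa=40.0, **overrides):
    base = {
        "patient_id": "P001", "group": "active", "n_days": 3, "mvpa_mean": mvpa,
        "steps_mean": 8000.0, "resting_hr": 70.0, "sedentary_frac": 70.0,
        "light_mean": 250.0, "bedtime_h": 23.5, "getup_h": 7.5,
        "hours_asleep": 7.0, "sleep_efficiency": 87.0, "pem": True,
    }
    base.update(overrides)
    return base


CLEAN = CohortConfig(artifacts=ArtifactConfig.none())


class TestMinuteStream:
    def test_clean_stream_entirely_valid(self):
        from datetime import date

        minutes, truth, arts = generate_minute_day(_profile(), date(2022, 6, 1), CLEAN,
                                                   np.random.default_rng(0))
        assert len(minutes) == 1440
        assert arts == []
        _, days, _ = validate_patient(minutes, ValidationConfig())
        assert int(days["valid_minutes"].iloc[0]) == 1440

    def test_signal_consistency_invariant(self):
        from datetime import date

        rng = np.random.default_rng(1)
        for d in range(5):
            minutes, _, _ = generate_minute_day(_profile(), date(2022, 6, 1 + d), CohortConfig(), rng)
            intense = minutes[minutes["intensity"] >= 2]
            assert (intense["mets"] > 3.0).all()
            assert (intense["steps"] > 0).all()

    def test_injected_flatline_is_flagged_exactly(self):
        config = CohortConfig(artifacts=ArtifactConfig(
            gap_runs_per_day=0.0, spikes_per_day=0.0,
            flatline_runs_per_day=1.5, flatline_lengths=(15,)))
        rng = np.random.default_rng(2)
        minutes, truth, arts = generate_patient_minutes(_profile(n_days=20), config, rng, n_days=20)
        flags, _, _ = validate_patient(minutes, ValidationConfig())
        injected = int(arts.loc[arts["type"] == "flatline", "length"].sum())
        flagged = int((flags["reason"] == "flatline_run").sum())
        assert injected > 0
        assert flagged == injected

    def test_sub_threshold_flatlines_not_flagged(self):
        config = CohortConfig(artifacts=ArtifactConfig(
            gap_runs_per_day=0.0, spikes_per_day=0.0,
            flatline_runs_per_day=1.5, flatline_lengths=(8,)))
        rng = np.random.default_rng(3)
        minutes, _, arts = generate_patient_minutes(_profile(), config, rng, n_days=15)
        flags, _, _ = validate_patient(minutes, ValidationConfig())
        assert (arts["type"] == "flatline").sum() > 0
        assert int((flags["reason"] == "flatline_run").sum()) == 0

    def test_spikes_match_out_of_range_exclusions(self):
        config = CohortConfig(artifacts=ArtifactConfig(
            gap_runs_per_day=0.0, flatline_runs_per_day=0.0, spikes_per_day=1.0))
        rng = np.random.default_rng(4)
        minutes, _, arts = generate_patient_minutes(_profile(), config, rng, n_days=15)
        flags, _, _ = validate_patient(minutes, ValidationConfig())
        n_spikes = int((arts["type"] == "spike").sum())
        n_excl = int(flags["reason"].isin(["hr_below_min", "hr_above_max"]).sum())
        assert n_spikes > 0 and n_excl == n_spikes

    def test_gap_minutes_are_filled_or_nonwear(self):
        config = CohortConfig(artifacts=ArtifactConfig(
            flatline_runs_per_day=0.0, spikes_per_day=0.0, gap_runs_per_day=2.0))
        rng = np.random.default_rng(5)
        minutes, _, arts = generate_patient_minutes(_profile(), config, rng, n_days=10)
        flags, _, _ = validate_patient(minutes, ValidationConfig())
        missing = flags["hr"].isna()
        assert missing.sum() == arts.loc[arts["type"] == "hr_gap", "length"].sum()
        assert flags.loc[missing, "status"].isin(["valid_filled", "nonwear"]).all()

    def test_active_profile_mvpa_recovered_through_pipeline(self):
        from wearcohort.daily_features import summarize_cohort_days

        rng = np.random.default_rng(6)
        minutes, truth, _ = generate_patient_minutes(_profile(mvpa=46.9), CLEAN, rng, n_days=30)
        flags, _, _ = validate_patient(minutes, ValidationConfig())
        summaries = summarize_cohort_days(flags)
        assert summaries["mvpa_minutes"].mean() == pytest.approx(46.9, abs=5.0)


class TestProfilesAndDays:
    def test_followup_distribution_matches_cohort_shape(self):
        rng = np.random.default_rng(7)
        config = CohortConfig(n_active=300, n_inactive=300)
        profiles = generate_profiles(config, rng)
        med = profiles["n_days"].median()
        q1, q3 = profiles["n_days"].quantile([0.25, 0.75])
        assert 32 <= med <= 52
        assert 14 <= q1 <= 28
        assert 55 <= q3 <= 90

    def test_group_sizes(self):
        rng = np.random.default_rng(8)
        profiles = generate_profiles(CohortConfig(), rng)
        assert (profiles["group"] == "active").sum() == 41
        assert (profiles["group"] == "inactive").sum() == 41


class TestProWaves:
    def test_zero_effects_zero_noise_constant_waves(self):
        rng = np.random.default_rng(9)
        profiles = generate_profiles(CohortConfig(n_active=5, n_inactive=5), rng)
        config = CohortConfig(dropout=(0.0, 0.0, 0.0))
        params = ProMeasureConfig(45.0, 45.0, tau=0.0, sigma=0.0)
        long, _ = generate_pro_long(profiles, config, rng, "social_roles_t", params)
        wide = long.pivot_table(index="patient_id", columns="wave", values="value")
        assert (wide.nunique(axis=1) == 1).all()
        assert (wide["baseline"] == 45.0).all()

    def test_zero_dropout_gives_complete_records(self):
        rng = np.random.default_rng(10)
        config = CohortConfig(n_active=6, n_inactive=6, dropout=(0.0, 0.0, 0.0))
        profiles = generate_profiles(config, rng)
        records, _ = generate_pro_waves(profiles, config, rng)
        assert len(records) == 12 * 3

    def test_dropout_rate_roughly_respected(self):
        rng = np.random.default_rng(11)
        config = CohortConfig(n_active=150, n_inactive=150, dropout=(0.0, 0.3, 0.3))
        profiles = generate_profiles(config, rng)
        long, _ = generate_pro_long(profiles, config, rng)
        counts = long.groupby("wave")["value"].size()
        assert counts["baseline"] == 300
        assert 0.6 < counts["m3"] / 300 < 0.8

    def test_baseline_gated_follow_up_symptoms(self):
        rng = np.random.default_rng(12)
        config = CohortConfig(n_active=20, n_inactive=20, dropout=(0.0, 0.0, 0.0))
        profiles = generate_profiles(config, rng)
        records, truth = generate_pro_waves(profiles, config, rng)
        by_pid_wave = {(r.patient_id, r.wave): r for r in records}
        for i, pid in enumerate(profiles["patient_id"]):
            for sym, present in truth["symptom_baseline"].items():
                if not present[i]:
                    for wave in ("m3", "m6"):
                        rec = by_pid_wave[(pid, wave)]
                        assert sym not in rec.symptoms


class TestDeterminism:
    def test_same_seed_same_fixture_bytes(self, tmp_path):
        p1 = make_fixture_suite(tmp_path / "a", seed=77)
        p2 = make_fixture_suite(tmp_path / "b", seed=77)
        for name in p1:
            assert p1[name].read_bytes() == p2[name].read_bytes()

    def test_different_seeds_differ(self, tmp_path):
        p1 = make_fixture_suite(tmp_path / "a", seed=77)
        p2 = make_fixture_suite(tmp_path / "b", seed=78)
        assert p1["minutes"].read_bytes() != p2["minutes"].read_bytes()

    def test_fixture_passes_full_pipeline(self, tmp_path):
        from wearcohort.daily_features import summarize_cohort_days
        from wearcohort.io_wearable import read_minute_csv, read_pro_table, read_sleep_csv
        from wearcohort.pro_scoring import score_records
        from wearcohort.wear_validation import validate_cohort

        paths = make_fixture_suite(tmp_path, seed=5)
        minutes = read_minute_csv(paths["minutes"])
        flags, days, verdicts = validate_cohort(minutes)
        sleep = read_sleep_csv(paths["sleep"])
        summaries = summarize_cohort_days(flags, sleep)
        assert len(summaries) > 0
        records = read_pro_table(paths["pro"])
        scored = score_records(records)
        assert {"patient_id", "wave", "measure", "value"} <= set(scored.columns)
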