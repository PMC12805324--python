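"""Daily feature aggregation: arithmetic, partitions, two-stage averaging."""

from __future__ import annotations

from datetime import datetime

import numpy as np
import pandas as pd
import pytest

from wearcohort.config import ValidationConfig
from wearcohort.daily_features import (
    cohort_daily_table,
    minute_activity_class,
    patient_feature_means,
    sleep_features,
    summarize_cohort_days,
    summarize_day,
)
from wearcohort.wear_validation import validate_patient

from conftest import make_stream


def _flags(hr, **kw):
    flags, _, _ = validate_patient(make_stream(hr, **kw), ValidationConfig())
    return flags


class TestMinuteClassification:
    def test_intensity_codes(self):
        intensity = np.array([0, 1, 2, 3, 2], dtype=float)
        mets = np.full(5, 2.0)
        klass = minute_activity_class(intensity, mets)
        assert list(klass) == ["sedentary", "light", "mvpa", "mvpa", "mvpa"]

    def test_mets_fallback_when_intensity_absent(self):
        intensity = np.array([np.nan, np.nan])
        mets = np.array([3.5, 2.0])
        assert list(minute_activity_class(intensity, mets)) == ["mvpa", "unclassified"]


class TestDaySummary:
    def test_counts_and_sedentary_fraction(self):
        hr = [70 + i % 5 for i in range(600)]
        intensity = [0.0] * 400 + [1.0] * 100 + [2.0] * 60 + [3.0] * 40
        flags = _flags(hr, intensity=intensity)
        row = summarize_day(flags)
        assert row["valid_minutes"] == 600
        assert row["sedentary_frac"] == pytest.approx(100 * 400 / 600, abs=0.01)
        assert row["light_minutes"] == 100
        assert row["mvpa_minutes"] == 100

    def test_class_partition_of_valid_minutes(self):
        rng = np.random.default_rng(3)
        n = 500
        hr = [int(v) for v in rng.integers(55, 190, n)]
        intensity = [float(v) for v in rng.integers(0, 4, n)]
        flags = _flags(hr, intensity=intensity)
        row = summarize_day(flags)
        valid = flags[flags["status"].isin(["valid_observed", "valid_filled"])]
        n_sed = int((valid["intensity"] == 0).sum())
        assert row["mvpa_minutes"] + row["light_minutes"] + n_sed == row["valid_minutes"]

    def test_zero_valid_minutes_gives_no_summary(self):
        flags = _flags([None] * 30)
        assert summarize_day(flags) is None

    def test_max_hr_uses_effective_hr(self):
        hr = [100, None, 120, 60, 60]
        flags = _flags(hr, steps=[0, 5, 0, 0, 0])
        row = summarize_day(flags)
        assert row["max_hr"] == 120.0

    def test_supplied_resting_hr_preferred(self):
        flags = _flags([70] * 5)
        assert summarize_day(flags, resting_hr=62.0)["resting_hr"] == 62.0


class TestSleepFeatures:
    def test_efficiency_and_hours(self):
        sessions = pd.DataFrame({
            "patient_id": ["P1"],
            "bed_start": [datetime(2022, 6, 1, 23, 30)],
            "bed_end": [datetime(2022, 6, 2, 7, 30)],
            "minutes_asleep": [420],
            "minutes_in_bed": [480],
        })
        f = sleep_features(sessions)
        assert f["sleep_efficiency"] == pytest.approx(87.5)
        assert f["hours_asleep"] == pytest.approx(7.0)
        assert f["bedtime_h"] == pytest.approx(23.5)

    def test_after_midnight_bedtime_reported_past_24(self):
        sessions = pd.DataFrame({
            "patient_id": ["P1"],
            "bed_start": [datetime(2022, 6, 2, 0, 6)],
            "bed_end": [datetime(2022, 6, 2, 7, 0)],
            "minutes_asleep": [360],
            "minutes_in_bed": [400],
        })
        assert sleep_features(sessions)["bedtime_h"] == pytest.approx(24.1)


class TestCohortTable:
    def _summaries(self, patients):
        rows = []
        for pid, label, day_values in patients:
            for i, v in enumerate(day_values):
                rows.append({
                    "patient_id": pid, "date": pd.Timestamp("2022-06-01") + pd.Timedelta(days=i),
                    "valid_minutes": 1440, "sedentary_frac": 70.0, "light_minutes": 200,
                    "mvpa_minutes": v, "steps": 6000, "resting_hr": 70.0, "max_hr": 120.0,
                    "bedtime_h": 23.5, "getup_h": 7.5, "hours_asleep": 7.0, "sleep_efficiency": 87.0,
                })
        labels = pd.DataFrame({"patient_id": [p for p, _, _ in patients],
                               "label": [l for _, l, _ in patients]})
        return pd.DataFrame(rows), labels

    def test_identical_days_give_day_value_and_zero_sd(self):
        summaries, labels = self._summaries([("P1", "active", [30] * 8), ("P2", "inactive", [5] * 8)])
        table = cohort_daily_table(summaries, labels)
        row = table[table["feature"] == "mvpa_minutes"].iloc[0]
        assert row["active_mean"] == 30.0 and row["active_sd"] == 0.0

    def test_two_patients_average_of_averages(self):
        summaries, labels = self._summaries([
            ("P1", "active", [10] * 10), ("P2", "active", [20] * 2), ("P3", "inactive", [1] * 8),
        ])
        table = cohort_daily_table(summaries, labels)
        row = table[table["feature"] == "mvpa_minutes"].iloc[0]
        assert row["active_mean"] == 15.0  # patient-first averaging, not day-pooled

    def test_two_stage_equals_single_stage_only_when_balanced(self):
        summaries, labels = self._summaries([
            ("P1", "active", [10] * 5), ("P2", "active", [20] * 5), ("P3", "inactive", [1] * 8),
        ])
        table = cohort_daily_table(summaries, labels)
        pooled = summaries[summaries["patient_id"].isin(["P1", "P2"])]["mvpa_minutes"].mean()
        assert table[table["feature"] == "mvpa_minutes"].iloc[0]["active_mean"] == pooled
        # unbalanced: the two disagree
        summaries2, labels2 = self._summaries([
            ("P1", "active", [10] * 10), ("P2", "active", [20] * 2), ("P3", "inactive", [1] * 8),
        ])
        table2 = cohort_daily_table(summaries2, labels2)
        pooled2 = summaries2[summaries2["patient_id"].isin(["P1", "P2"])]["mvpa_minutes"].mean()
        assert table2[table2["feature"] == "mvpa_minutes"].iloc[0]["active_mean"] != pooled2

    def test_empty_group_is_error(self):
        summaries, labels = self._summaries([("P1", "active", [30] * 8)])
        with pytest.raises(ValueError, match="inactive"):
            cohort_daily_table(summaries, labels)

    def test_group_recovery_from_generator(self):
        """Two-group cohort generated at the configured means is recovered
        by the two-stage table within Monte-Carlo error."""
        from wearcohort.synthetic_data import CohortConfig, generate_day_summaries

        rng = np.random.default_rng(11)
        config = CohortConfig(n_active=30, n_inactive=30,
                              followup_min_days=40, followup_max_days=60)
        summaries, profiles = generate_day_summaries(config, rng)
        labels = profiles.rename(columns={"group": "label"})[["patient_id", "label"]]
        table = cohort_daily_table(summaries, labels)
        mvpa = table[table["feature"] == "mvpa_minutes"].iloc[0]
        se_active = config.mvpa_between_sd[0] / np.sqrt(30)
        assert abs(mvpa["active_mean"] - 46.9) < 3 * se_active + 1
        assert abs(mvpa["inactive_mean"] - 8.2) < 3 * config.mvpa_between_sd[1] / np.sqrt(30) + 1

    def test_valid_day_filter(self):
        summaries, _ = self._summaries([("P1", "active", [30] * 3)])
        summaries.loc[0, "valid_minutes"] = 100  # below the 1200-minute rule
        means = patient_feature_means(summaries)
        assert int(means["n_valid_days"].iloc[0]) == 2
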