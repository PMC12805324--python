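"""Minute-level wear validation: rules, boundaries, properties, oracle."""

from __future__ import annotations

from datetime import datetime, timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from wearcohort.config import ValidationConfig
from wearcohort.wear_validation import (
    ContractError,
    exclude_flatlines,
    exclude_implausible,
    fill_hr_gaps,
    validate_patient,
)

from conftest import frame_to_oracle_rows, make_stream
from oracle_wear import validate_minutes_bruteforce


class TestGapFilling:
    def test_mean_of_adjacent_neighbours(self, vconfig):
        df = make_stream([80, None, 90], steps=[0, 30, 0])
        out = fill_hr_gaps(df, vconfig)
        assert out.loc[1, "status"] == "valid_filled"
        assert out.loc[1, "filled_hr"] == 85.0

    def test_activity_gate_blocks_fill(self, vconfig):
        # steps=0, METs=1.0, intensity=0: no activity evidence, stays nonwear
        df = make_stream([80, None, 90], steps=[0, 0, 0], mets=[1.0, 1.0, 1.0], intensity=[0, 0, 0])
        out = fill_hr_gaps(df, vconfig)
        assert out.loc[1, "status"] == "nonwear"
        assert out.loc[1, "reason"] == "no_signal"

    @pytest.mark.parametrize("col,value", [("steps", 1), ("mets", 1.1), ("intensity", 1)])
    def test_any_gate_signal_allows_fill(self, vconfig, col, value):
        kwargs = {"steps": [0, 0, 0], "mets": [1.0, 1.0, 1.0], "intensity": [0, 0, 0]}
        kwargs[col][1] = value
        df = make_stream([80, None, 90], **kwargs)
        out = fill_hr_gaps(df, vconfig)
        assert out.loc[1, "status"] == "valid_filled"

    def test_multi_minute_gap_filled_with_same_mean(self, vconfig):
        # 3-minute gap, all gated: each minute uses its nearest observed
        # neighbours, which are the same pair, so all get (60+70)/2
        hr = [60, None, None, None, 70]
        df = make_stream(hr, steps=[0, 5, 5, 5, 0])
        out = fill_hr_gaps(df, vconfig)
        assert list(out.loc[1:3, "filled_hr"]) == [65.0, 65.0, 65.0]
        # filled values never seed further fills: neighbours were observed only
        assert out.loc[1:3, "status"].eq("valid_filled").all()

    def test_missing_neighbour_on_one_side(self, vconfig):
        df = make_stream([None, 80, None], steps=[9, 0, 9])
        out = fill_hr_gaps(df, vconfig)
        assert out.loc[0, "status"] == "nonwear"
        assert out.loc[2, "status"] == "nonwear"

    def test_gap_longer_than_max_not_filled(self):
        config = ValidationConfig(max_fill_gap=5)
        start = datetime(2022, 6, 1, 12, 0)
        rows = pd.DataFrame(
            {
                "patient_id": "P001",
                "timestamp": [start, start + timedelta(minutes=10), start + timedelta(minutes=11)],
                "hr": [70.0, np.nan, 72.0],
                "steps": [0, 5, 0],
                "mets": [1.0, 1.0, 1.0],
                "intensity": [0.0, 0.0, 0.0],
            }
        )
        out = fill_hr_gaps(rows, config)
        assert out.loc[1, "status"] == "nonwear"

    def test_fill_does_not_cross_midnight(self, vconfig):
        start = datetime(2022, 6, 1, 23, 59)
        df = make_stream([70, None, 74], steps=[0, 9, 0], start=start)
        out = fill_hr_gaps(df, vconfig)  # neighbours at 23:59 and 00:01 next day
        assert out.loc[1, "status"] == "nonwear"

    def test_unsorted_input_rejected(self, vconfig):
        df = make_stream([70, 71, 72]).iloc[::-1].reset_index(drop=True)
        with pytest.raises(ContractError):
            fill_hr_gaps(df, vconfig)


class TestPlausibilityWindow:
    @pytest.mark.parametrize(
        "hr,excluded,reason",
        [
            (44, True, "hr_below_min"),
            (45, False, "none"),
            (205, False, "none"),
            (206, True, "hr_above_max"),
        ],
    )
    def test_strict_bounds(self, vconfig, hr, excluded, reason):
        df = fill_hr_gaps(make_stream([hr]), vconfig)
        out = exclude_implausible(df, vconfig)
        assert (out.loc[0, "status"] == "excluded") == excluded
        assert out.loc[0, "reason"] == reason

    def test_filled_values_also_windowed(self, vconfig):
        df = make_stream([46, None, 46], steps=[0, 9, 0])
        out = exclude_implausible(fill_hr_gaps(df, vconfig), vconfig)
        assert out.loc[1, "status"] == "valid_filled"  # 46 within window
        low = make_stream([46, None, 40], steps=[0, 9, 0])
        out = exclude_implausible(fill_hr_gaps(low, vconfig), vconfig)
        assert out.loc[1, "status"] == "excluded"  # mean 43 < 45
        assert out.loc[2, "reason"] == "hr_below_min"


class TestFlatlines:
    def _run(self, hr, config=None):
        config = config or ValidationConfig()
        df = fill_hr_gaps(make_stream(hr), config)
        df = exclude_implausible(df, config)
        return exclude_flatlines(df, config)

    def test_eleven_identical_minutes_excluded(self):
        out = self._run([72] * 11)
        assert (out["reason"] == "flatline_run").all()

    def test_ten_identical_minutes_kept(self):
        out = self._run([72] * 10)
        assert (out["status"] == "valid_observed").all()

    def test_long_run_fully_excluded_maximal_semantics(self):
        out = self._run([60] * 25)
        assert int((out["reason"] == "flatline_run").sum()) == 25

    def test_value_change_breaks_run(self):
        out = self._run([72] * 10 + [73] + [72] * 10)
        assert (out["status"] == "valid_observed").all()

    def test_missing_minute_breaks_run(self, vconfig):
        hr = [72] * 6 + [None] + [72] * 6
        df = make_stream(hr, steps=[0] * 13)
        out = exclude_flatlines(exclude_implausible(fill_hr_gaps(df, vconfig), vconfig), vconfig)
        assert not (out["reason"] == "flatline_run").any()

    def test_filled_minutes_do_not_join_runs(self, vconfig):
        # 5 observed + 1 filled (same value) + 5 observed: two runs of 5
        hr = [72] * 5 + [None] + [72] * 5
        df = make_stream(hr, steps=[0] * 5 + [9] + [0] * 5)
        out = exclude_flatlines(exclude_implausible(fill_hr_gaps(df, vconfig), vconfig), vconfig)
        assert not (out["reason"] == "flatline_run").any()


class TestPatientValidation:
    def _day(self, date, n_valid, patient="P001"):
        """One calendar day with n_valid observed minutes (varying HR)."""
        start = datetime(date.year, date.month, date.day, 0, 0)
        hr = [70 + (i % 7) for i in range(n_valid)]
        return make_stream(hr, start=start, patient_id=patient)

    def _patient(self, day_valid_counts):
        frames = []
        d0 = datetime(2022, 6, 1)
        for i, n in enumerate(day_valid_counts):
            frames.append(self._day(d0 + timedelta(days=i), n))
        return pd.concat(frames, ignore_index=True)

    def test_seven_full_days_is_valid_patient(self, vconfig):
        df = self._patient([1200] * 7)
        _, days, ok = validate_patient(df, vconfig)
        assert days["is_valid_day"].all() and ok

    def test_1199_minute_day_not_valid(self, vconfig):
        df = self._patient([1200] * 6 + [1199])
        _, days, ok = validate_patient(df, vconfig)
        assert int(days["is_valid_day"].sum()) == 6
        assert not ok

    def test_empty_stream(self, vconfig):
        df = make_stream([]).iloc[:0]
        flags, days, ok = validate_patient(df, vconfig)
        assert len(days) == 0 and not ok

    def test_partition_and_tally_identity(self, vconfig):
        rng = np.random.default_rng(0)
        hr = [None if rng.random() < 0.2 else int(rng.integers(40, 210)) for _ in range(500)]
        steps = [int(rng.integers(0, 30)) for _ in range(500)]
        df = make_stream(hr, steps=steps)
        flags, days, _ = validate_patient(df, vconfig)
        assert set(flags["status"]) <= {"valid_observed", "valid_filled", "excluded", "nonwear"}
        for _, d in days.iterrows():
            total = (
                d["valid_minutes"] + d["nonwear_minutes"] + d["excluded_hr_below_min"]
                + d["excluded_hr_above_max"] + d["excluded_flatline_run"]
            )
            assert total == d["n_minutes"]

    def test_idempotent_on_valid_output(self, vconfig):
        df = self._patient([300])
        flags, _, _ = validate_patient(df, vconfig)
        valid = flags[flags["status"].isin(["valid_observed", "valid_filled"])].copy()
        valid["hr"] = valid["hr_effective"]
        again, _, _ = validate_patient(
            valid[["patient_id", "timestamp", "hr", "steps", "mets", "intensity"]].reset_index(drop=True),
            vconfig,
        )
        assert again["status"].isin(["valid_observed"]).all()

    @pytest.mark.parametrize("param,raise_to", [("hr_max", 250.0), ("flatline_min_run", 30)])
    def test_relaxing_thresholds_is_monotone(self, param, raise_to):
        rng = np.random.default_rng(1)
        hr = []
        i = 0
        while i < 800:
            if rng.random() < 0.05:
                run = int(rng.integers(5, 20))
                hr.extend([int(rng.integers(60, 220))] * run)
                i += run
            else:
                hr.append(int(rng.integers(40, 215)))
                i += 1
        df = make_stream(hr[:800])
        base = ValidationConfig()
        relaxed = ValidationConfig(**{**base.to_dict(), param: raise_to})
        _, days_base, _ = validate_patient(df, base)
        _, days_relaxed, _ = validate_patient(df, relaxed)
        assert days_relaxed["valid_minutes"].sum() >= days_base["valid_minutes"].sum()


class TestOracleEquivalence:
    def _random_stream(self, seed, n=1500):
        rng = np.random.default_rng(seed)
        hr, steps, mets, intensity = [], [], [], []
        i = 0
        while i < n:
            u = rng.random()
            if u < 0.04:  # flat-line run
                run = int(rng.integers(5, 18))
                v = int(rng.integers(50, 190))
                hr.extend([v] * run)
                steps.extend([0] * run)
                mets.extend([1.0] * run)
                intensity.extend([0.0] * run)
                i += run
            elif u < 0.18:  # missing HR
                hr.append(None)
                active = rng.random() < 0.5
                steps.append(int(rng.integers(1, 60)) if active else 0)
                mets.append(1.0)
                intensity.append(0.0)
                i += 1
            else:
                hr.append(int(rng.integers(35, 215)))
                steps.append(int(rng.integers(0, 80)))
                mets.append(float(rng.uniform(1.0, 8.0)))
                intensity.append(float(rng.integers(0, 4)))
                i += 1
        return make_stream(hr[:n], steps=steps[:n], mets=mets[:n], intensity=intensity[:n],
                           start=datetime(2022, 6, 1, 22, 0))

    @pytest.mark.parametrize("seed", range(5))
    def test_flags_match_bruteforce(self, vconfig, seed):
        df = self._random_stream(seed)
        flags, _, _ = validate_patient(df, vconfig)
        expected = validate_minutes_bruteforce(frame_to_oracle_rows(df))
        got = list(zip(flags["status"], flags["reason"]))
        assert got == expected


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    hr=st.lists(st.one_of(st.none(), st.integers(30, 220)), min_size=1, max_size=120),
    data=st.data(),
)
def test_status_partition_property(hr, data):
    """Every minute gets exactly one status consistent with its reason."""
    steps = data.draw(st.lists(st.integers(0, 50), min_size=len(hr), max_size=len(hr)))
    df = make_stream(hr, steps=steps)
    flags, _, _ = validate_patient(df, ValidationConfig())
    valid = flags["status"].isin(["valid_observed", "valid_filled"])
    assert (flags.loc[valid, "reason"] == "none").all()
    assert (flags.loc[flags["status"] == "nonwear", "reason"] == "no_signal").all()
    assert flags.loc[flags["status"] == "excluded", "reason"].isin(
        ["hr_below_min", "hr_above_max", "flatline_run"]
    ).all()
    # oracle agreement on arbitrary streams
    expected = validate_minutes_bruteforce(frame_to_oracle_rows(df))
    assert list(zip(flags["status"], flags["reason"])) == expected
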