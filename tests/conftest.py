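from __future__ import annotations

from datetime import datetime, timedelta

import numpy as np
import pandas as pd
import pytest

from wearcohort.config import ValidationConfig


@pytest.fixture
def vconfig() -> ValidationConfig:
    return ValidationConfig()


def make_stream(
    hr,
    steps=None,
    mets=None,
    intensity=None,
    patient_id: str = "P001",
    start: datetime = datetime(2022, 6, 1, 12, 0),
) -> pd.DataFrame:
    """Build a minute stream from parallel value lists (None -> missing)."""
    n = len(hr)
    def col(vals, default):
        if vals is None:
            return [default] * n
        return [np.nan if v is None else v for v in vals]
    return pd.DataFrame(
        {
            "patient_id": patient_id,
            "timestamp": [start + timedelta(minutes=i) for i in range(n)],
            "hr": col(hr, np.nan),
            "steps": pd.Series(col(steps, 0)).fillna(0).astype(int),
            "mets": col(mets, 1.0),
            "intensity": col(intensity, 0.0),
        }
    )


def frame_to_oracle_rows(df: pd.DataFrame) -> list[dict]:
    """Convert a canonical minute frame to the oracle's plain-dict rows."""
    ts = pd.to_datetime(df["timestamp"])
    minutes = (ts.astype("int64") // 60_000_000_000).to_numpy()
    days = (ts.astype("int64") // 86_400_000_000_000).to_numpy()
    rows = []
    for i in range(len(df)):
        hr = df["hr"].iloc[i]
        rows.append(
            {
                "minute": int(minutes[i]),
                "day": int(days[i]),
                "hr": None if pd.isna(hr) else float(hr),
                "steps": int(df["steps"].iloc[i]),
                "mets": None if pd.isna(df["mets"].iloc[i]) else float(df["mets"].iloc[i]),
                "intensity": None if pd.isna(df["intensity"].iloc[i]) else float(df["intensity"].iloc[i]),
            }
        )
    return rows
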