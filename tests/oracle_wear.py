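"""Independent brute-force re-implementation of minute-level wear validation.

Deliberately written as explicit per-minute loops with no shared code or
vectorization, to serve as the oracle against which the pipeline's
vectorized implementation is checked minute-for-minute.
"""

from __future__ import annotations

import math


def validate_minutes_bruteforce(
    rows: list[dict],
    hr_min: float = 45.0,
    hr_max: float = 205.0,
    flatline_min_run: int = 11,
    max_fill_gap: int = 60,
    steps_gate: int = 0,
    met_gate: float = 1.0,
    intensity_gate: int = 0,
) -> list[tuple[str, str]]:
    """Return (status, reason) per minute for one patient's sorted stream.

    ``rows`` are dicts with keys ``minute`` (integer minutes since epoch),
    ``day`` (integer day ordinal), ``hr`` (float or None), ``steps``,
    ``mets`` (float or None), ``intensity`` (float or None).
    """
    n = len(rows)
    status = [""] * n
    reason = [""] * n
    eff_hr: list[float | None] = [None] * n

    def observed(i: int) -> bool:
        return rows[i]["hr"] is not None and not (
            isinstance(rows[i]["hr"], float) and math.isnan(rows[i]["hr"])
        )

    def gate(i: int) -> bool:
        r = rows[i]
        if r["steps"] is not None and r["steps"] > steps_gate:
            return True
        if r["mets"] is not None and not math.isnan(r["mets"]) and r["mets"] > met_gate:
            return True
        if r["intensity"] is not None and not math.isnan(r["intensity"]) and r["intensity"] > intensity_gate:
            return True
        return False

    # stage 1+2: wear detection and gap filling
    for i in range(n):
        if observed(i):
            status[i] = "valid_observed"
            reason[i] = "none"
            eff_hr[i] = float(rows[i]["hr"])
            continue
        status[i] = "nonwear"
        reason[i] = "no_signal"
        if not gate(i):
            continue
        prev = None
        for j in range(i - 1, -1, -1):
            if observed(j):
                prev = j
                break
        nxt = None
        for j in range(i + 1, n):
            if observed(j):
                nxt = j
                break
        if prev is None or nxt is None:
            continue
        if rows[prev]["day"] != rows[i]["day"] or rows[nxt]["day"] != rows[i]["day"]:
            continue
        if rows[i]["minute"] - rows[prev]["minute"] > max_fill_gap:
            continue
        if rows[nxt]["minute"] - rows[i]["minute"] > max_fill_gap:
            continue
        status[i] = "valid_filled"
        reason[i] = "none"
        eff_hr[i] = (float(rows[prev]["hr"]) + float(rows[nxt]["hr"])) / 2.0

    # stage 3: plausibility window, strict inequalities
    for i in range(n):
        if status[i] in ("valid_observed", "valid_filled"):
            if eff_hr[i] < hr_min:
                status[i] = "excluded"
                reason[i] = "hr_below_min"
            elif eff_hr[i] > hr_max:
                status[i] = "excluded"
                reason[i] = "hr_above_max"

    # stage 4: flat-line runs over observed minutes only
    i = 0
    while i < n:
        if not observed(i):
            i += 1
            continue
        j = i
        while (
            j + 1 < n
            and observed(j + 1)
            and rows[j + 1]["minute"] - rows[j]["minute"] == 1
            and float(rows[j + 1]["hr"]) == float(rows[i]["hr"])
        ):
            j += 1
        run_len = j - i + 1
        if run_len >= flatline_min_run:
            for t in range(i, j + 1):
                if status[t] == "valid_observed":
                    status[t] = "excluded"
                    reason[t] = "flatline_run"
        i = j + 1

    return list(zip(status, reason))


def day_tally_bruteforce(rows: list[dict], flags: list[tuple[str, str]], valid_day_minutes: int = 1200) -> dict:
    """Per-day valid-minute counts and valid-day verdicts from oracle flags."""
    days: dict[int, int] = {}
    for r, (st, _) in zip(rows, flags):
        days.setdefault(r["day"], 0)
        if st in ("valid_observed", "valid_filled"):
            days[r["day"]] += 1
    return {d: {"valid_minutes": v, "is_valid_day": v >= valid_day_minutes} for d, v in days.items()}
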