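"""Data-coverage assessment of the cleaned channels and PROs.

Coverage of the regularly sampled channels (HR, respiratory rate, skin
temperature, steps, posture) is the number of clean samples over the
number expected from the nominal rate.  The beat-timed R-to-R channel is
covered by duration instead: the sum of recorded intervals divided by
the length of the actual measurement period.  PRO coverage counts
responses against the per-item prompt schedule on device-wear days.
Daily values run midnight-to-midnight; a participant-level value is the
mean of the daily values.
"""

from __future__ import annotations

from typing import Dict, Iterable, Optional, Tuple

import numpy as np
import pandas as pd

from .core import PRO_SCHEDULE, RR_INTERVAL, SampleSeries, seconds

#: a gap longer than this splits wear sessions for R-to-R coverage
WEAR_SESSION_GAP_MIN = 30.0


def coverage_sampled(series: SampleSeries, start, end) -> float:
    """Observed / expected sample count in [start, end); capped at 1."""
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    length_s = (end - start).total_seconds()
    if length_s <= 0:
        raise ValueError("interval must have positive length")
    if series.nominal_rate is None:
        raise ValueError("use coverage_rr for the beat-timed R-to-R channel")
    expected = series.nominal_rate * length_s
    idx = series.times
    observed = int(((idx >= start) & (idx < end)).sum())
    return min(observed / expected, 1.0)


def wear_sessions(
    series: SampleSeries, gap_min: float = WEAR_SESSION_GAP_MIN
) -> list:
    """Contiguous wear sessions split at gaps > ``gap_min`` minutes."""
    if len(series) == 0:
        return []
    t = seconds(series.times)
    brk = np.flatnonzero(np.diff(t) > gap_min * 60.0)
    starts = np.concatenate([[0], brk + 1])
    ends = np.concatenate([brk, [len(t) - 1]])
    return [(series.times[a], series.times[b]) for a, b in zip(starts, ends)]


def coverage_rr(
    series: SampleSeries, start, end, gap_min: float = WEAR_SESSION_GAP_MIN
) -> float:
    """Sum of R-to-R intervals over the wear time inside [start, end)."""
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    if (end - start).total_seconds() <= 0:
        raise ValueError("interval must have positive length")
    sub = series.between(start, end, closed="left")
    if len(sub) == 0:
        return 0.0
    total_s = float(sub.values.astype(float).sum()) / 1000.0
    period = 0.0
    for a, b in wear_sessions(series, gap_min):
        lo = max(a, start)
        hi = min(b, end)
        if hi > lo:
            period += (hi - lo).total_seconds()
    if period <= 0:
        return 0.0
    return min(total_s / period, 1.0)


def _day_edges(series: SampleSeries, tz: str = "UTC"):
    idx = series.times.tz_convert(tz)
    first = idx[0].normalize()
    last = idx[-1].normalize()
    days = pd.date_range(first, last, freq="D", tz=tz)
    return [(d, d + pd.Timedelta(days=1)) for d in days]


def daily_coverage(series: SampleSeries, tz: str = "UTC") -> pd.DataFrame:
    """Midnight-to-midnight coverage per calendar day of the recording."""
    rows = []
    if len(series) == 0:
        return pd.DataFrame(columns=["participant_id", "modality", "date", "coverage"])
    for d0, d1 in _day_edges(series, tz):
        if series.modality == RR_INTERVAL:
            cov = coverage_rr(series, d0, d1)
        else:
            cov = coverage_sampled(series, d0, d1)
        rows.append(
            {
                "participant_id": series.participant_id,
                "modality": series.modality,
                "date": d0.date(),
                "coverage": cov,
            }
        )
    return pd.DataFrame(rows)


def participant_coverage(series: SampleSeries, tz: str = "UTC") -> float:
    """Mean of the daily midnight-to-midnight coverage values."""
    daily = daily_coverage(series, tz)
    return float(daily["coverage"].mean()) if len(daily) else np.nan


def coverage_pro(
    pro: pd.DataFrame, wear_days: Iterable, schedule: Optional[Dict] = None
) -> pd.Series:
    """Responses received / expected per PRO item over the wear days.

    ``wear_days`` is a collection of dates on which the device was worn.
    Items expected on zero days come back as NaN.
    """
    schedule = schedule or PRO_SCHEDULE
    wear_days = set(pd.Timestamp(d).date() for d in wear_days)
    out = {}
    if len(pro):
        resp_days = pd.to_datetime(pro["timestamp"]).dt.date
    for item, slots in schedule.items():
        expected = len(slots) * len(wear_days)
        if expected == 0:
            out[item] = np.nan
            continue
        if len(pro) == 0:
            out[item] = 0.0
            continue
        mask = (pro["item_id"] == item) & resp_days.isin(wear_days)
        out[item] = min(int(mask.sum()) / expected, 1.0)
    return pd.Series(out, name="coverage")


def cohort_coverage_table(bundles, tz: str = "UTC") -> pd.DataFrame:
    """Tidy participant-level coverage, one row per participant-modality."""
    rows = []
    for b in bundles:
        for mod, s in b.series.items():
            rows.append(
                {
                    "participant_id": b.participant_id,
                    "group": b.group,
                    "modality": mod,
                    "coverage": participant_coverage(s, tz),
                }
            )
    return pd.DataFrame(rows)
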