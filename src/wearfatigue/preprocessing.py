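"""Cleaning of the raw wearable channels.

Each physiological channel is cleaned in a fixed order: timestamps are
sorted and de-duplicated, then three mutually exclusive outlier classes
are removed — (1) invalid values (the device's out-of-band failure
code), (2) physiologically unrealistic values outside a per-channel
accepted range, and (3) contextual outliers deviating from the mean of a
short sliding window centred on the sample.  Removed values become gaps,
except range/contextual R-to-R outliers, which are re-filled by linear
interpolation so HRV analysis keeps a continuous tachogram.  Step and
posture channels only undergo sorting/de-duplication and invalid-value
removal.

Self-reported sleep clock times entered on a 24-h dial are prone to
12-hour shifts; a repair pass shifts implausible bedtimes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .core import (
    HR,
    INVALID_POSTURE,
    INVALID_VALUE,
    PHYSIO_MODALITIES,
    POSTURE,
    RESP_RATE,
    RR_INTERVAL,
    SKIN_T,
    STEPS,
    SampleSeries,
    seconds,
)

#: accepted physiological range per channel (inclusive on both ends)
ACCEPTED_RANGES: Dict[str, Tuple[float, float]] = {
    HR: (30.0, 200.0),  # beats/min
    RR_INTERVAL: (300.0, 2000.0),  # ms
    RESP_RATE: (4.0, 60.0),  # breaths/min
    SKIN_T: (28.0, 40.0),  # deg C
}

#: sliding-window length in minutes for the contextual filter
CONTEXTUAL_WINDOW_MIN: Dict[str, float] = {
    HR: 1.0,
    RR_INTERVAL: 1.0,
    RESP_RATE: 3.0,
    SKIN_T: 5.0,
}

#: allowed fractional deviation from the window mean
CONTEXTUAL_THRESHOLD: Dict[str, float] = {
    HR: 0.30,
    RR_INTERVAL: 0.30,
    RESP_RATE: 0.50,
    SKIN_T: 0.30,
}


@dataclass
class CleaningConfig:
    accepted_range: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(ACCEPTED_RANGES)
    )
    contextual_window_min: Dict[str, float] = field(
        default_factory=lambda: dict(CONTEXTUAL_WINDOW_MIN)
    )
    contextual_threshold: Dict[str, float] = field(
        default_factory=lambda: dict(CONTEXTUAL_THRESHOLD)
    )
    invalid_value: float = INVALID_VALUE
    invalid_posture: str = INVALID_POSTURE
    #: implied sleep durations above this are treated as entry errors (h)
    max_sleep_duration_h: float = 16.0

    def __post_init__(self):
        for mod, (lo, hi) in self.accepted_range.items():
            if lo >= hi:
                raise ValueError(f"range for {mod}: min must be < max")
        for mod, thr in self.contextual_threshold.items():
            if thr <= 0:
                raise ValueError(f"threshold for {mod} must be > 0")


@dataclass
class CleaningReport:
    """Per-modality removal counts and fractions, by outlier class."""

    n_raw: Dict[str, int] = field(default_factory=dict)
    removed: Dict[str, Dict[str, int]] = field(default_factory=dict)
    n_interpolated_rr: int = 0
    n_sleep_shifted: int = 0
    n_flagged_nonpositive_mean: Dict[str, int] = field(default_factory=dict)

    def fraction_removed(self, modality: str, cls: str) -> float:
        n = self.n_raw.get(modality, 0)
        return self.removed.get(modality, {}).get(cls, 0) / n if n else np.nan

    def to_dict(self) -> dict:
        return {
            "n_raw": self.n_raw,
            "removed": self.removed,
            "fractions": {
                m: {c: self.fraction_removed(m, c) for c in d}
                for m, d in self.removed.items()
            },
            "n_interpolated_rr": self.n_interpolated_rr,
            "n_sleep_shifted": self.n_sleep_shifted,
        }


# ---------------------------------------------------------------------------
# stage operations


def sort_dedup(series: SampleSeries) -> SampleSeries:
    """Sort by timestamp and keep the first-seen record per timestamp."""
    s = series.samples
    if s.index.is_monotonic_increasing and s.index.is_unique:
        return series
    s = s.sort_index(kind="stable")
    s = s[~s.index.duplicated(keep="first")]
    return series.with_samples(s)


def filter_invalid(
    series: SampleSeries, config: Optional[CleaningConfig] = None
) -> Tuple[SampleSeries, np.ndarray]:
    """Drop the device's invalid-value code; returns surviving series and
    the positions removed (into the input)."""
    config = config or CleaningConfig()
    if series.modality == POSTURE:
        bad = series.samples.to_numpy(dtype=object) == config.invalid_posture
    else:
        v = series.values.astype(float)
        bad = (v == config.invalid_value) | ~np.isfinite(v)
    removed = np.flatnonzero(bad)
    return series.with_samples(series.samples[~bad]), removed


def filter_range(
    series: SampleSeries, config: Optional[CleaningConfig] = None
) -> Tuple[SampleSeries, np.ndarray]:
    """Drop values outside the accepted range (bounds inclusive)."""
    config = config or CleaningConfig()
    if series.modality not in config.accepted_range:
        raise KeyError(f"no accepted range configured for {series.modality!r}")
    lo, hi = config.accepted_range[series.modality]
    v = series.values.astype(float)
    bad = (v < lo) | (v > hi)
    removed = np.flatnonzero(bad)
    return series.with_samples(series.samples[~bad]), removed


def contextual_outlier_mask(
    times_s: np.ndarray, values: np.ndarray, window_s: float, threshold: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorised sliding-window contextual-outlier test.

    A sample is an outlier iff |x - m| / m > threshold where m is the
    mean of all *other* samples within +-window/2 of its timestamp.
    Samples with no neighbour are kept; samples whose window mean is
    non-positive are kept but flagged (division would be meaningless).
    Returns (outlier mask, nonpositive-mean flag mask).
    """
    n = len(values)
    if n == 0:
        return np.zeros(0, bool), np.zeros(0, bool)
    half = window_s / 2.0
    left = np.searchsorted(times_s, times_s - half, side="left")
    right = np.searchsorted(times_s, times_s + half, side="right")
    csum = np.concatenate([[0.0], np.cumsum(values)])
    n_other = (right - left) - 1
    sum_other = csum[right] - csum[left] - values
    with np.errstate(invalid="ignore", divide="ignore"):
        m = sum_other / n_other
        dev = np.abs(values - m) / m
    has_nb = n_other > 0
    flagged = has_nb & (m <= 0)
    outlier = has_nb & (m > 0) & (dev > threshold)
    return outlier, flagged


def filter_contextual(
    series: SampleSeries, config: Optional[CleaningConfig] = None
) -> Tuple[SampleSeries, np.ndarray]:
    """Single-pass contextual filter over the range-filtered series."""
    config = config or CleaningConfig()
    window_s = config.contextual_window_min[series.modality] * 60.0
    thr = config.contextual_threshold[series.modality]
    out, _ = contextual_outlier_mask(
        seconds(series.times), series.values.astype(float), window_s, thr
    )
    removed = np.flatnonzero(out)
    return series.with_samples(series.samples[~out]), removed


def repair_rr(
    clean: SampleSeries, removed_times: pd.DatetimeIndex
) -> Tuple[SampleSeries, int]:
    """Re-fill range/contextual R-to-R outlier positions by linear
    interpolation in time between surviving neighbours.

    Positions outside the surviving span (only one neighbour) are
    dropped, not extrapolated.  Invalid-class positions are *not* passed
    here; they remain gaps.
    """
    if clean.modality != RR_INTERVAL:
        raise ValueError("repair_rr applies to the R-to-R channel only")
    if len(removed_times) == 0 or len(clean) < 2:
        return clean, 0
    t_keep = seconds(clean.times)
    v_keep = clean.values.astype(float)
    t_rm = seconds(pd.DatetimeIndex(removed_times))
    inside = (t_rm > t_keep[0]) & (t_rm < t_keep[-1])
    t_rm = t_rm[inside]
    if t_rm.size == 0:
        return clean, 0
    v_new = np.interp(t_rm, t_keep, v_keep)
    filled = pd.Series(
        v_new, index=pd.DatetimeIndex(removed_times[inside])
    )
    merged = pd.concat([clean.samples, filled]).sort_index(kind="stable")
    return clean.with_samples(merged), int(t_rm.size)


def clean_series(
    series: SampleSeries,
    config: Optional[CleaningConfig] = None,
    report: Optional[CleaningReport] = None,
) -> SampleSeries:
    """Full cleaning pipeline for one channel.

    Order is fixed: sort/dedup -> invalid -> range -> contextual, with
    contextual means computed over the values surviving earlier stages.
    For R-to-R, range and contextual positions are re-filled by linear
    interpolation.  Steps/posture stop after invalid removal.
    """
    config = config or CleaningConfig()
    report = report if report is not None else CleaningReport()
    mod = series.modality
    s = sort_dedup(series)
    report.n_raw[mod] = len(s)
    rem: Dict[str, int] = {}

    s, idx_inv = filter_invalid(s, config)
    rem["invalid"] = len(idx_inv)
    if mod in (STEPS, POSTURE):
        report.removed[mod] = rem
        return s

    repair_times = []
    s2, idx_rng = filter_range(s, config)
    rem["range"] = len(idx_rng)
    repair_times.append(s.times[idx_rng])

    s3, idx_ctx = filter_contextual(s2, config)
    rem["contextual"] = len(idx_ctx)
    repair_times.append(s2.times[idx_ctx])
    report.removed[mod] = rem

    if mod == RR_INTERVAL:
        rm_times = repair_times[0].append(repair_times[1])
        s3, n_interp = repair_rr(s3, rm_times)
        report.n_interpolated_rr += n_interp
    return s3


def clean_bundle(bundle, config: Optional[CleaningConfig] = None):
    """Clean every channel of a participant bundle; returns (bundle, report)."""
    from dataclasses import replace

    config = config or CleaningConfig()
    report = CleaningReport()
    cleaned = {
        mod: clean_series(s, config, report) for mod, s in bundle.series.items()
    }
    pros, n_shift = repair_sleep_times(bundle.pros, config)
    report.n_sleep_shifted = n_shift
    return replace(bundle, series=cleaned, pros=pros), report


# ---------------------------------------------------------------------------
# sleep-time repair


def _implied_duration(bed_h: float, wake_h: float) -> float:
    """Sleep duration in hours under the naive previous-evening /
    same-morning reading of the two clock values."""
    if bed_h >= 12.0:
        return 24.0 - bed_h + wake_h
    return wake_h - bed_h


def repair_sleep_times(
    pro: pd.DataFrame, config: Optional[CleaningConfig] = None
) -> Tuple[pd.DataFrame, int]:
    """Fix 12-h-shifted self-reported bedtimes.

    For each morning (participant, day) pair of bed/wake clock values:
    if the implied duration is not in (0, max] hours, the bedtime is
    shifted by 12 h; if the shifted reading is plausible it replaces the
    original, otherwise the pair is marked unusable
    (``sleep_usable = False``).
    """
    config = config or CleaningConfig()
    max_h = config.max_sleep_duration_h
    pro = pro.copy()
    if "sleep_usable" not in pro.columns:
        pro["sleep_usable"] = True
    n_shifted = 0
    clock = pro[pro["item_id"].isin(["bed_time", "wake_time"])]
    for (pid, day), grp in clock.groupby(["participant_id", "day"]):
        bed = grp[grp["item_id"] == "bed_time"]
        wake = grp[grp["item_id"] == "wake_time"]
        if bed.empty or wake.empty:
            continue
        b = float(bed["value"].iloc[0])
        w = float(wake["value"].iloc[0])
        dur = _implied_duration(b, w)
        if 0.0 < dur <= max_h:
            continue
        b2 = (b + 12.0) % 24.0
        dur2 = _implied_duration(b2, w)
        if 0.0 < dur2 <= max_h:
            pro.loc[bed.index, "value"] = b2
            n_shifted += 1
        else:
            pro.loc[bed.index, "sleep_usable"] = False
            pro.loc[wake.index, "sleep_usable"] = False
    return pro, n_shifted
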