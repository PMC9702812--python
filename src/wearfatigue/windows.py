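"""Aggregation windows, least-active-5-hour (L5) rest detection, and
rest-referenced normalization.

Physiological features are summarised over the 2-h window preceding
each PRO response (mean, SD, min, max per signal plus the HRV battery
and per-channel coverage).  Major rest is proxied by the L5 window: the
5-h stretch of a noon-to-noon day with at most 100 steps and at least
80% lying posture, chosen at 1-min start resolution by maximal lying
fraction.  Each participant's 2-h aggregates are then normalized as
x_norm = (x − µ_L5) / σ_L5, with the reference parameters taken either
from the nearest previous L5 window (variant "a") or averaged over all
of the participant's L5 windows (variant "b").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .core import (
    HR,
    LIKERT_ITEMS,
    POSTURE,
    RESP_RATE,
    RR_INTERVAL,
    SKIN_T,
    STEPS,
    ParticipantBundle,
    SampleSeries,
    seconds,
)
from .hrv import FEATURE_NAMES as HRV_FEATURES
from .hrv import features_from_series
from .quality import coverage_rr

WINDOW_HOURS = 2.0
L5_HOURS = 5.0
L5_MAX_STEPS = 100.0
L5_MIN_LYING = 0.80
#: sub-segments of the L5 window used to give window-level HRV features
#: a spread for normalization
L5_HRV_SUBSEGMENTS = 5

SIGNAL_LABEL = {
    HR: "HR",
    RR_INTERVAL: "R-to-R",
    RESP_RATE: "Resp rate",
    SKIN_T: "Skin T",
}
AGG_STATS = ("mean", "SD", "min", "max")


def signal_feature_names() -> List[str]:
    return [f"{lbl} {st}" for lbl in SIGNAL_LABEL.values() for st in AGG_STATS]


def feature_modality(feature: str) -> str:
    """The channel a feature derives from (HRV features -> R-to-R)."""
    for mod, lbl in SIGNAL_LABEL.items():
        if feature.startswith(lbl + " ") and feature[len(lbl) + 1 :] in AGG_STATS:
            return mod
    return RR_INTERVAL


# ---------------------------------------------------------------------------
# 2-h aggregates


def aggregate_window(
    bundle: ParticipantBundle, anchor_time, window_hours: float = WINDOW_HOURS
) -> Tuple[Dict[str, float], Dict[str, float]]:
    """Aggregates and per-channel coverage over (anchor−2h, anchor].

    Returns ``(features, coverage)`` where coverage is keyed by
    modality.  Empty windows yield NaN features and zero coverage.
    """
    end = pd.Timestamp(anchor_time)
    start = end - pd.Timedelta(hours=window_hours)
    feats: Dict[str, float] = {}
    cov: Dict[str, float] = {}
    for mod, lbl in SIGNAL_LABEL.items():
        sub = bundle[mod].between(start, end, closed="right")
        v = sub.values.astype(float)
        if len(v):
            feats[f"{lbl} mean"] = float(np.mean(v))
            feats[f"{lbl} SD"] = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
            feats[f"{lbl} min"] = float(np.min(v))
            feats[f"{lbl} max"] = float(np.max(v))
        else:
            for st in AGG_STATS:
                feats[f"{lbl} {st}"] = np.nan
        if mod == RR_INTERVAL:
            cov[mod] = coverage_rr(bundle[mod], start, end)
        else:
            expected = bundle[mod].nominal_rate * window_hours * 3600.0
            cov[mod] = min(len(sub) / expected, 1.0)
    hrv = features_from_series(bundle[RR_INTERVAL].between(start, end, closed="right"))
    for name in HRV_FEATURES:
        feats[name] = hrv[name] if hrv else np.nan
    return feats, cov


def build_aggregate_table(
    bundle: ParticipantBundle, window_hours: float = WINDOW_HOURS
) -> pd.DataFrame:
    """Long table of raw 2-h aggregates, one row per (PRO response,
    feature), with the feature's channel coverage attached."""
    pros = bundle.pros
    pros = pros[pros["item_id"].isin(LIKERT_ITEMS)]
    rows = []
    cache: Dict[pd.Timestamp, tuple] = {}
    for r in pros.itertuples():
        t = pd.Timestamp(r.timestamp)
        if t not in cache:
            cache[t] = aggregate_window(bundle, t, window_hours)
        feats, cov = cache[t]
        for feature, value in feats.items():
            rows.append(
                {
                    "participant_id": bundle.participant_id,
                    "group": bundle.group,
                    "anchor_time": t,
                    "item_id": r.item_id,
                    "pro_value": r.value,
                    "feature": feature,
                    "raw": value,
                    "coverage": cov[feature_modality(feature)],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# L5 detection


@dataclass
class L5Window:
    participant_id: str
    start: pd.Timestamp
    end: pd.Timestamp
    step_total: float
    lying_fraction: float
    #: per-signal sample-level (mean, SD) inside the window
    signal_params: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    #: per-HRV-feature (mean, SD) over L5 sub-segments
    hrv_params: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    #: window-level HRV features (rest-state summaries)
    hrv_features: Dict[str, float] = field(default_factory=dict)


def detect_l5(
    steps: SampleSeries,
    posture: SampleSeries,
    span_start,
    span_end,
    max_steps: float = L5_MAX_STEPS,
    min_lying: float = L5_MIN_LYING,
    min_present_fraction: float = 0.5,
) -> Optional[L5Window]:
    """Best 5-h low-activity window inside ``[span_start, span_end)``.

    Candidate windows start each minute and must total <= ``max_steps``
    steps with >= ``min_lying`` lying fraction (over posture samples
    present).  Overlapping runs of candidates are merged; the winner
    maximises lying fraction (ties: fewer steps, then earliest start).
    Windows with less than ``min_present_fraction`` of the nominal 1 Hz
    posture samples are not eligible (a near-empty window is no
    evidence of rest), and candidates must lie within the recorded
    posture span (1-min slack) so absent data cannot masquerade as
    rest at the recording edges.
    """
    span_start, span_end = pd.Timestamp(span_start), pd.Timestamp(span_end)
    win_s = L5_HOURS * 3600.0
    last_start = (span_end - span_start).total_seconds() - win_s
    if last_start < 0:
        return None
    p_in = posture.between(span_start, span_end, closed="left")
    if len(p_in) == 0:
        return None

    starts_s = np.arange(0.0, last_start + 1e-9, 60.0)
    t0 = span_start

    st = steps.between(span_start, span_end, closed="left")
    ts = seconds(st.times) - seconds(pd.DatetimeIndex([t0]))[0]
    sv = st.values.astype(float)
    s_csum = np.concatenate([[0.0], np.cumsum(sv)])

    tp = seconds(p_in.times) - seconds(pd.DatetimeIndex([t0]))[0]
    lying = (p_in.values == "lying").astype(float)
    l_csum = np.concatenate([[0.0], np.cumsum(lying)])

    lo_s = np.searchsorted(ts, starts_s, side="left")
    hi_s = np.searchsorted(ts, starts_s + win_s, side="left")
    step_tot = s_csum[hi_s] - s_csum[lo_s]
    lo_p = np.searchsorted(tp, starts_s, side="left")
    hi_p = np.searchsorted(tp, starts_s + win_s, side="left")
    present = (hi_p - lo_p).astype(float)
    lying_cnt = l_csum[hi_p] - l_csum[lo_p]
    with np.errstate(invalid="ignore", divide="ignore"):
        lying_frac = np.where(present > 0, lying_cnt / present, np.nan)

    cand = (
        (step_tot <= max_steps)
        & (present >= min_present_fraction * win_s)
        & (lying_frac >= min_lying)
        & (starts_s >= tp[0] - 60.0)
        & (starts_s + win_s <= tp[-1] + 61.0)
    )
    idx = np.flatnonzero(cand)
    if idx.size == 0:
        return None

    # merge overlapping candidate runs (starts < 5 h apart overlap)
    gap_limit = win_s / 60.0  # in minutes between start indices
    runs = np.split(idx, np.flatnonzero(np.diff(idx) >= gap_limit) + 1)
    winners = []
    for run in runs:
        order = sorted(
            run, key=lambda i: (-lying_frac[i], step_tot[i], starts_s[i])
        )
        winners.append(order[0])
    best = sorted(
        winners, key=lambda i: (-lying_frac[i], step_tot[i], starts_s[i])
    )[0]
    w_start = t0 + pd.Timedelta(seconds=float(starts_s[best]))
    return L5Window(
        participant_id=steps.participant_id,
        start=w_start,
        end=w_start + pd.Timedelta(seconds=win_s),
        step_total=float(step_tot[best]),
        lying_fraction=float(lying_frac[best]),
    )


def noon_spans(bundle: ParticipantBundle, tz: str = "UTC") -> List[tuple]:
    """Noon-to-noon search days covering the recording."""
    idx = bundle[POSTURE].times.tz_convert(tz)
    if len(idx) == 0:
        return []
    d = idx[0].normalize() - pd.Timedelta(hours=12)
    spans = []
    while d < idx[-1]:
        spans.append((d, d + pd.Timedelta(hours=24)))
        d += pd.Timedelta(days=1)
    return spans


def l5_params(l5: L5Window, bundle: ParticipantBundle) -> L5Window:
    """Attach sample-level signal (µ, σ) and sub-segment HRV (µ, σ)."""
    for mod in SIGNAL_LABEL:
        sub = bundle[mod].between(l5.start, l5.end, closed="left")
        v = sub.values.astype(float)
        if len(v) >= 2:
            l5.signal_params[mod] = (float(np.mean(v)), float(np.std(v, ddof=1)))
        elif len(v) == 1:
            l5.signal_params[mod] = (float(v[0]), 0.0)
    rr = bundle[RR_INTERVAL]
    whole = features_from_series(rr.between(l5.start, l5.end, closed="left"))
    if whole:
        l5.hrv_features = whole
    edges = pd.date_range(l5.start, l5.end, periods=L5_HRV_SUBSEGMENTS + 1)
    sub_feats = []
    for a, b in zip(edges[:-1], edges[1:]):
        f = features_from_series(rr.between(a, b, closed="left"))
        if f:
            sub_feats.append(f)
    if len(sub_feats) >= 2:
        df = pd.DataFrame(sub_feats)
        mu = df.mean()
        sd = df.std(ddof=1)
        for name in HRV_FEATURES:
            if np.isfinite(mu.get(name, np.nan)):
                l5.hrv_params[name] = (float(mu[name]), float(sd[name]))
    return l5


def detect_l5_all(bundle: ParticipantBundle, tz: str = "UTC") -> List[L5Window]:
    """One parameterised L5 window per noon-to-noon day, where found."""
    out = []
    for a, b in noon_spans(bundle, tz):
        w = detect_l5(bundle[STEPS], bundle[POSTURE], a, b)
        if w is not None:
            out.append(l5_params(w, bundle))
    return out


# ---------------------------------------------------------------------------
# normalization


def _params_for_feature(l5: L5Window, feature: str):
    mod = feature_modality(feature)
    if feature in HRV_FEATURES:
        return l5.hrv_params.get(feature)
    return l5.signal_params.get(mod)


def normalize_table(
    agg: pd.DataFrame, l5_windows: List[L5Window], variant: str = "b"
) -> pd.DataFrame:
    """Add a ``normalized`` column to a participant's aggregate table.

    Variant "a" references the nearest L5 window ending before the
    aggregate window's start; rows with no previous L5 window are
    excluded.  Variant "b" references the participant-mean of µ and of
    σ over all L5 windows.  A zero or missing σ leaves the normalized
    value NaN.
    """
    if variant not in ("a", "b"):
        raise ValueError("variant must be 'a' or 'b'")
    agg = agg.copy()
    agg["normalized"] = np.nan
    agg["variant"] = variant
    if len(agg) == 0:
        return agg
    if not l5_windows:
        return agg.iloc[0:0]

    features = agg["feature"].unique()
    if variant == "b":
        ref: Dict[str, tuple] = {}
        for feature in features:
            pairs = [
                p for w in l5_windows if (p := _params_for_feature(w, feature))
            ]
            if pairs:
                mus, sds = zip(*pairs)
                ref[feature] = (float(np.mean(mus)), float(np.mean(sds)))
        for feature in features:
            if feature not in ref:
                continue
            mu, sd = ref[feature]
            mask = agg["feature"] == feature
            if sd > 0:
                agg.loc[mask, "normalized"] = (agg.loc[mask, "raw"] - mu) / sd
        return agg

    # variant a
    ends = pd.DatetimeIndex([w.end for w in l5_windows])
    order = np.argsort(ends.asi8)
    sorted_w = [l5_windows[i] for i in order]
    sorted_ends = ends[order]
    keep_rows = []
    for anchor, grp in agg.groupby("anchor_time", sort=False):
        win_start = pd.Timestamp(anchor) - pd.Timedelta(hours=WINDOW_HOURS)
        pos = int(np.searchsorted(sorted_ends.asi8, win_start.value, side="right")) - 1
        if pos < 0:
            continue  # no previous L5 window: aggregate excluded
        w = sorted_w[pos]
        for i in grp.index:
            p = _params_for_feature(w, agg.at[i, "feature"])
            if p and p[1] > 0:
                agg.at[i, "normalized"] = (agg.at[i, "raw"] - p[0]) / p[1]
            keep_rows.append(i)
    return agg.loc[keep_rows]


# ---------------------------------------------------------------------------
# agreement between L5 windows and self-reported sleep


def reported_sleep_intervals(pros: pd.DataFrame) -> List[tuple]:
    """Reported (bed, wake) timestamp pairs from repaired morning PROs.

    Bedtime hours >= 12 are placed on the previous evening.  Pairs
    flagged unusable by the sleep-time repair are skipped.
    """
    out = []
    clock = pros[pros["item_id"].isin(["bed_time", "wake_time"])]
    if "sleep_usable" in clock.columns:
        clock = clock[clock["sleep_usable"].fillna(True)]
    for (pid, day), grp in clock.groupby(["participant_id", "day"]):
        bed = grp[grp["item_id"] == "bed_time"]
        wake = grp[grp["item_id"] == "wake_time"]
        if bed.empty or wake.empty:
            continue
        morning = pd.Timestamp(wake["timestamp"].iloc[0]).normalize()
        b, w = float(bed["value"].iloc[0]), float(wake["value"].iloc[0])
        bed_ts = morning + pd.Timedelta(hours=b) - pd.Timedelta(days=1 if b >= 12 else 0)
        wake_ts = morning + pd.Timedelta(hours=w)
        if wake_ts > bed_ts:
            out.append((pid, bed_ts, wake_ts))
    return out


def l5_sleep_agreement(
    l5_windows: List[L5Window],
    sleep_intervals: List[tuple],
    threshold_min: float = 30.0,
) -> dict:
    """Fractions of L5 windows aligned with reported sleep.

    Each L5 window is compared against the overlapping reported sleep
    interval of the same participant (the one with the largest
    overlap); windows with no concurrent report are not compared.
    """
    thr = pd.Timedelta(minutes=threshold_min)
    n_cmp = n_within = n_start = n_end = n_thr = n_start_thr = n_end_thr = 0
    for w in l5_windows:
        best, best_ov = None, pd.Timedelta(0)
        for pid, b, e in sleep_intervals:
            if pid != w.participant_id:
                continue
            ov = min(e, w.end) - max(b, w.start)
            if ov > best_ov:
                best, best_ov = (b, e), ov
        if best is None:
            continue
        b, e = best
        n_cmp += 1
        n_start += w.start >= b
        n_end += w.end <= e
        n_within += (w.start >= b) and (w.end <= e)
        n_start_thr += w.start >= b - thr
        n_end_thr += w.end <= e + thr
        n_thr += (w.start >= b - thr) and (w.end <= e + thr)
    if n_cmp == 0:
        return {"n_compared": 0, "n_l5": len(l5_windows)}
    return {
        "n_compared": n_cmp,
        "n_l5": len(l5_windows),
        "frac_entirely_within": n_within / n_cmp,
        "frac_start_within": n_start / n_cmp,
        "frac_end_within": n_end / n_cmp,
        "frac_within_threshold": n_thr / n_cmp,
        "frac_start_within_threshold": n_start_thr / n_cmp,
        "frac_end_within_threshold": n_end_thr / n_cmp,
    }


def build_feature_table(
    bundle: ParticipantBundle, variant: str = "b", tz: str = "UTC"
) -> pd.DataFrame:
    """End-to-end per-participant table: 2-h aggregates normalized by L5."""
    agg = build_aggregate_table(bundle)
    l5 = detect_l5_all(bundle, tz)
    return normalize_table(agg, l5, variant)
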