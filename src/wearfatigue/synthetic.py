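"""Synthetic cohort generator with known ground truth.

Because the study data this pipeline targets cannot be shared, every
downstream stage is validated against simulated multi-day recordings in
which the quantities of interest are *planted*: a latent daily fatigue
trajectory that shifts both heart rate and the Likert responses, nightly
lying bouts for rest (L5) detection, daily sustained walks followed by a
heart-rate-recovery minute of known magnitude, wear gaps, and injected
outliers of the three cleaning classes (invalid / out-of-range /
contextual).

The generative model is deliberately minimal but structured enough for
the analyses to be meaningful:

* heart rate = group baseline + fatigue effect + cosinor (peak
  mid-afternoon) + activity term + slow AR(1) wander + white noise;
* skin temperature runs in anti-phase to the HR cosinor;
* R-to-R intervals are emitted per detected beat, obtained by
  integrating the instantaneous rate (plus respiratory and
  low-frequency modulation so the tachogram has realistic spectral
  content); the value is the interval between consecutive beats in ms;
* steps and posture are emitted at 1 Hz following a daily schedule of
  sitting/standing, one compliant walk (>= 6 min, cadence >= 60) with a
  seated recovery, two non-compliant decoy walks, and a nightly lying
  bout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .core import (
    GROUPS,
    HR,
    INVALID_POSTURE,
    INVALID_VALUE,
    POSTURE,
    PRO_COLUMNS,
    PRO_SCHEDULE,
    PRO_SLOT_HOURS,
    RESP_RATE,
    RR_INTERVAL,
    SKIN_T,
    STEPS,
    ParticipantBundle,
    SampleSeries,
    make_series,
)
from .preprocessing import ACCEPTED_RANGES, CONTEXTUAL_THRESHOLD, CONTEXTUAL_WINDOW_MIN

DAY = 86_400  # seconds

OUTLIER_CLASSES = ("invalid", "range", "contextual")


def _default_outlier_rates() -> Dict[str, Dict[str, float]]:
    # magnitudes of the same order as reported device data quality:
    # a few permille per physiological channel, skin T dominated by
    # range outliers
    physio = {"invalid": 0.001, "range": 0.002, "contextual": 0.001}
    return {
        HR: dict(physio),
        RR_INTERVAL: dict(physio),
        RESP_RATE: dict(physio),
        SKIN_T: {"invalid": 0.001, "range": 0.02, "contextual": 0.001},
        STEPS: {"invalid": 0.0005},
        POSTURE: {"invalid": 0.0005},
    }


@dataclass
class CohortConfig:
    """Study-condition knobs for the synthetic cohort."""

    n_healthy: int = 3
    n_ndd: int = 3
    n_imid: int = 3
    days_per_participant: int = 5
    seed: int = 0
    start_date: str = "2021-03-01"
    #: resting HR baseline per group, beats/min
    hr_baseline_by_group: Dict[str, float] = field(
        default_factory=lambda: {"healthy": 62.0, "NDD": 70.0, "IMID": 67.0}
    )
    #: additive shift of the planted heart-rate recovery per group, beats/min
    hrr_shift_by_group: Dict[str, float] = field(
        default_factory=lambda: {"healthy": 0.0, "NDD": -10.0, "IMID": -6.0}
    )
    hrr_base: float = 30.0
    #: beats/min of daytime HR per unit of latent fatigue
    fatigue_effect_beta: float = 3.0
    #: group-mean latent fatigue on the 0-6 scale
    fatigue_base_by_group: Dict[str, float] = field(
        default_factory=lambda: {"healthy": 2.0, "NDD": 2.33, "IMID": 2.39}
    )
    fatigue_sd: float = 0.8
    circadian_amplitude: float = 8.0
    #: per modality, per outlier class, fraction of emitted samples
    outlier_rates: Dict[str, Dict[str, float]] = field(
        default_factory=_default_outlier_rates
    )
    pro_noise_sd: float = 0.7
    #: fraction of each day the device is not worn (single daytime block)
    wear_gap_rate: float = 0.1
    #: slot-level Bernoulli dropout of PRO responses
    pro_dropout: float = 0.1
    #: probability that a late bedtime is mis-entered 12 h off
    sleep_shift_error_rate: float = 0.05

    def __post_init__(self):
        for name in ("n_healthy", "n_ndd", "n_imid", "days_per_participant"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.wear_gap_rate <= 0.375:
            raise ValueError("wear_gap_rate must be in [0, 0.375]")
        for mod, rates in self.outlier_rates.items():
            for cls, r in rates.items():
                if not 0 <= r <= 1:
                    raise ValueError(f"outlier rate {mod}/{cls} not in [0,1]")

    def group_sizes(self) -> Dict[str, int]:
        return {"healthy": self.n_healthy, "NDD": self.n_ndd, "IMID": self.n_imid}


@dataclass
class GroundTruth:
    """Planted quantities for one participant."""

    participant_id: str
    group: str
    fatigue: np.ndarray  # latent fatigue per day
    rest_intervals: List[Tuple[pd.Timestamp, pd.Timestamp]]
    walk_bouts: List[dict]  # start, end, steps, compliant
    planted_hrr: float
    outlier_indices: Dict[str, Dict[str, np.ndarray]]
    sleep_reports: List[dict] = field(default_factory=list)
    age: float = 50.0
    sex: str = "F"


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    eps = rng.normal(0.0, sd * np.sqrt(1.0 - phi**2), n)
    out = lfilter([1.0], [1.0, -phi], eps)
    return np.asarray(out)


def _interval_mask(n: int, intervals: Sequence[Tuple[int, int]]) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for a, b in intervals:
        mask[max(a, 0) : min(b, n)] = True
    return mask


# ---------------------------------------------------------------------------
# outlier injection


def inject_outliers(
    series: SampleSeries,
    rates: Dict[str, float],
    rng: np.random.Generator,
    protect: Optional[Sequence[Tuple[pd.Timestamp, pd.Timestamp]]] = None,
) -> Tuple[SampleSeries, Dict[str, np.ndarray]]:
    """Corrupt a fraction of samples per outlier class.

    ``rates`` maps class name (invalid/range/contextual) to a fraction of
    the emitted samples.  ``protect`` intervals are never corrupted (used
    to keep planted walk-recovery minutes intact).  Returns the corrupted
    series and the injected positions per class.
    """
    n = len(series)
    indices = {cls: np.array([], dtype=int) for cls in OUTLIER_CLASSES}
    total_rate = sum(rates.get(cls, 0.0) for cls in OUTLIER_CLASSES)
    if n == 0 or total_rate == 0:
        return series.with_samples(series.samples.copy()), indices

    eligible = np.ones(n, dtype=bool)
    if protect:
        idx = series.times
        for a, b in protect:
            eligible &= ~((idx >= a) & (idx <= b))
    pool = np.flatnonzero(eligible)

    counts = {
        cls: int(round(rates.get(cls, 0.0) * n)) for cls in OUTLIER_CLASSES
    }
    k = sum(counts.values())
    if k == 0 or len(pool) == 0:
        return series.with_samples(series.samples.copy()), indices
    k = min(k, len(pool))
    chosen = np.sort(rng.choice(pool, size=k, replace=False))

    # enforce separation so injected samples do not sit in each other's
    # contextual windows
    window_min = CONTEXTUAL_WINDOW_MIN.get(series.modality)
    if window_min is not None and len(series) > 1:
        dt = np.median(np.diff(series.times.asi8)) / 1e9
        sep = max(1, int(np.ceil(window_min * 60.0 / max(dt, 1e-9))) + 1)
    else:
        sep = 1
    keep = [chosen[0]]
    for c in chosen[1:]:
        if c - keep[-1] >= sep:
            keep.append(c)
    chosen = np.array(keep, dtype=int)

    # assign classes proportionally to the surviving positions
    labels = np.repeat(
        [cls for cls in OUTLIER_CLASSES], [counts[cls] for cls in OUTLIER_CLASSES]
    )
    rng.shuffle(labels)
    rng.shuffle(chosen)
    labels = labels[: len(chosen)]

    values = series.samples.copy()
    out_idx: Dict[str, list] = {cls: [] for cls in OUTLIER_CLASSES}
    lohi = ACCEPTED_RANGES.get(series.modality)
    thr = CONTEXTUAL_THRESHOLD.get(series.modality)
    for cls in OUTLIER_CLASSES:
        take = chosen[labels == cls]
        for i in take:
            v = values.iloc[i]
            if cls == "invalid":
                values.iloc[i] = (
                    INVALID_POSTURE if series.modality == POSTURE else INVALID_VALUE
                )
                out_idx[cls].append(i)
            elif cls == "range":
                lo, hi = lohi
                if rng.random() < 0.5:
                    values.iloc[i] = hi * rng.uniform(1.05, 1.5)
                else:
                    values.iloc[i] = lo * rng.uniform(0.3, 0.9)
                out_idx[cls].append(i)
            else:  # contextual: violate the sliding-window criterion but
                # stay inside the accepted range
                lo, hi = lohi
                factor = 1.0 + thr + 0.5
                if v * factor <= hi:
                    values.iloc[i] = v * factor
                elif v / factor >= lo:
                    values.iloc[i] = v / factor
                else:
                    continue
                out_idx[cls].append(i)
    for cls in OUTLIER_CLASSES:
        indices[cls] = np.sort(np.array(out_idx[cls], dtype=int))
    return series.with_samples(values), indices


# ---------------------------------------------------------------------------
# participant generation


def generate_participant(
    config: CohortConfig,
    group: str,
    rng: np.random.Generator,
    participant_id: str = "P01",
) -> Tuple[Dict[str, SampleSeries], pd.DataFrame, GroundTruth]:
    """Generate one participant's six signal channels, PRO table and truth."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")

    D = config.days_per_participant
    n = D * DAY
    t0 = pd.Timestamp(config.start_date, tz="UTC")
    tsec = np.arange(n, dtype=float)  # seconds since t0
    hour = (tsec / 3600.0) % 24.0

    # --- demographics -----------------------------------------------------
    age_mu, age_sd = {"healthy": (47.0, 16.0), "NDD": (55.0, 11.0), "IMID": (50.0, 13.0)}[group]
    age = float(np.clip(rng.normal(age_mu, age_sd), 21, 82))
    sex = "F" if rng.random() < 0.6 else "M"

    # --- latent daily fatigue -------------------------------------------
    base_f = config.fatigue_base_by_group[group]
    fatigue = np.clip(base_f + _ar1(rng, D, 0.5, config.fatigue_sd), 0.0, 6.0)
    fatigue_sec = fatigue[np.minimum(tsec.astype(int) // DAY, D - 1)]

    planted_hrr = max(
        5.0,
        config.hrr_base
        + config.hrr_shift_by_group[group]
        - 0.12 * (age - 50.0)
        + rng.normal(0.0, 1.5),
    )

    # --- daily schedule --------------------------------------------------
    rest_intervals: List[Tuple[int, int]] = []  # seconds since t0
    walk_bouts: List[dict] = []  # sec-based, filled with steps later
    sleep_truth: List[dict] = []  # per night: start/end seconds

    wake0 = int(6.75 * 3600 + rng.normal(0, 900))
    rest_intervals.append((0, wake0))
    for d in range(D):
        s = d * DAY + int(22.5 * 3600 + rng.normal(0, 900))
        e = (d + 1) * DAY + int(6.75 * 3600 + rng.normal(0, 900))
        rest_intervals.append((s, min(e, n)))
        sleep_truth.append({"day": d, "start": s, "end": e})

        # compliant walk: whole-minute boundaries, morning
        ws = d * DAY + 60 * int((10.5 * 3600 + rng.normal(0, 2000)) // 60)
        dur = 60 * int(rng.integers(8, 13))
        walk_bouts.append(
            {"start": ws, "end": ws + dur, "kind": "main", "compliant": True}
        )
        # decoys: too short / too slow
        ds = d * DAY + 60 * int((15.0 * 3600 + rng.normal(0, 1500)) // 60)
        walk_bouts.append(
            {"start": ds, "end": ds + 180, "kind": "short", "compliant": False}
        )
        ls = d * DAY + 60 * int((17.5 * 3600 + rng.normal(0, 1500)) // 60)
        walk_bouts.append(
            {"start": ls, "end": ls + 420, "kind": "slow", "compliant": False}
        )

    lying = _interval_mask(n, rest_intervals)

    # --- posture & steps at 1 Hz ----------------------------------------
    posture = np.full(n, "sitting", dtype=object)
    for d in range(D):
        a = d * DAY + int(8.0 * 3600 + rng.uniform(0, 3600))
        posture[a : a + 600] = "standing"
        b = d * DAY + int(19.0 * 3600 + rng.uniform(0, 3600))
        posture[b : b + 600] = "standing"
    posture[lying] = "lying"
    steps = np.zeros(n, dtype=float)
    protect_zones: List[Tuple[int, int]] = []  # around recovery minutes
    for wb in walk_bouts:
        a, b = wb["start"], wb["end"]
        posture[a:b] = "walking"
        rate = 0.75 if wb["kind"] == "slow" else 1.7
        steps[a:b] = rng.poisson(rate, b - a)
        wb["steps"] = float(steps[a:b].sum())
        if wb["kind"] == "main":
            # seated recovery: zero steps for 3 min after the walk
            steps[b : b + 180] = 0.0
            protect_zones.append((a - 120, b + 300))
    # sporadic daytime steps outside rest/walk/recovery zones
    sporadic = rng.random(n) < 0.003
    sporadic &= ~lying
    sporadic &= posture != "walking"
    sporadic &= ~_interval_mask(n, protect_zones)
    steps[sporadic] += rng.integers(1, 4, int(sporadic.sum()))

    # --- activity term of HR (piecewise linear knots) --------------------
    act = np.zeros(n, dtype=float)
    for wb in walk_bouts:
        a, b = wb["start"], wb["end"]
        if wb["kind"] == "main":
            elev = planted_hrr + rng.uniform(6.0, 12.0)
            knots_t = [a, a + 60, b + 5, b + 53, b + 179, b + 299]
            knots_v = [0.0, elev, elev, elev - planted_hrr, elev - planted_hrr, 0.0]
        else:
            elev = rng.uniform(12.0, 22.0) if wb["kind"] == "slow" else rng.uniform(22.0, 30.0)
            knots_t = [a, a + 60, b, b + 120]
            knots_v = [0.0, elev, elev, 0.0]
        lo, hi = max(knots_t[0], 0), min(knots_t[-1] + 1, n)
        seg = np.arange(lo, hi, dtype=float)
        act[lo:hi] += np.interp(seg, knots_t, knots_v)
    act += np.where(lying, -5.0, 0.0)

    # taper stochastic HR noise inside recovery minutes so planted HRR is
    # a well-defined ground truth of the emitted signal
    taper = np.ones(n)
    for wb in walk_bouts:
        if wb["kind"] == "main":
            taper[max(wb["end"] - 10, 0) : wb["end"] + 70] = 0.1

    circ = config.circadian_amplitude * np.cos(2 * np.pi * (hour - 16.0) / 24.0)
    hr_1s = (
        config.hr_baseline_by_group[group]
        + config.fatigue_effect_beta * fatigue_sec
        + circ
        + act
        + _ar1(rng, n, 0.995, 2.0) * taper
    )
    hr_1s = np.clip(hr_1s, 32.0, 198.0)

    skin_1s = (
        33.5
        + 1.2 * np.cos(2 * np.pi * (hour - 4.0) / 24.0)
        + 0.5 * lying
        + _ar1(rng, n, 0.999, 0.25)
    )
    resp_1s = (
        14.0
        + 1.0 * np.cos(2 * np.pi * (hour - 15.0) / 24.0)
        + 4.0 * (posture == "walking")
        + _ar1(rng, n, 0.99, 0.8)
    )
    resp_1s = np.clip(resp_1s, 5.0, 55.0)

    # --- beat times and R-to-R intervals ---------------------------------
    inst_rate = (
        hr_1s
        + 2.2 * np.sin(2 * np.pi * 0.26 * tsec + rng.uniform(0, 2 * np.pi))
        + 1.5 * np.sin(2 * np.pi * 0.095 * tsec + rng.uniform(0, 2 * np.pi))
        + _ar1(rng, n, 0.3, 1.2) * taper
    )
    inst_rate = np.clip(inst_rate, 31.0, 199.0)
    cum_beats = np.cumsum(inst_rate / 60.0)  # beats elapsed by end of each second
    n_beats = int(np.floor(cum_beats[-1]))
    beat_t = np.interp(np.arange(1, n_beats + 1), cum_beats, tsec + 1.0)
    rr_ms = np.diff(beat_t) * 1000.0
    rr_t = beat_t[1:]

    # --- emission grids ---------------------------------------------------
    grid4 = np.arange(0, n, 4)
    hr_obs = np.clip(hr_1s[grid4] + rng.normal(0, 0.6, grid4.size) * taper[grid4], 30, 200)
    resp_obs = np.clip(resp_1s[grid4] + rng.normal(0, 0.5, grid4.size), 4, 60)
    skin_obs = np.clip(skin_1s[grid4] + rng.normal(0, 0.1, grid4.size), 28, 40)
    rr_ms = np.clip(rr_ms, 300.0, 2000.0)

    # --- wear gaps: one daytime block per day ----------------------------
    gap_intervals: List[Tuple[int, int]] = []
    if config.wear_gap_rate > 0:
        gdur = int(round(config.wear_gap_rate * DAY))
        for d in range(D):
            latest = 22.0 * 3600 - gdur
            gs = d * DAY + int(rng.uniform(13.0 * 3600, latest))
            gap_intervals.append((gs, gs + gdur))

    def _emit(mod, t_rel, vals, rate):
        keep = np.ones(len(t_rel), dtype=bool)
        for a, b in gap_intervals:
            keep &= ~((t_rel >= a) & (t_rel < b))
        times = t0 + pd.to_timedelta(t_rel[keep], unit="s")
        return make_series(participant_id, mod, times, np.asarray(vals)[keep], rate)

    series = {
        HR: _emit(HR, grid4.astype(float), hr_obs, 0.25),
        RESP_RATE: _emit(RESP_RATE, grid4.astype(float), resp_obs, 0.25),
        SKIN_T: _emit(SKIN_T, grid4.astype(float), skin_obs, 0.25),
        RR_INTERVAL: _emit(RR_INTERVAL, rr_t, rr_ms, None),
        STEPS: _emit(STEPS, tsec, steps, 1.0),
        POSTURE: _emit(POSTURE, tsec, posture, 1.0),
    }

    # --- outlier injection ------------------------------------------------
    protect_ts = [
        (t0 + pd.Timedelta(seconds=a), t0 + pd.Timedelta(seconds=b))
        for a, b in protect_zones
    ]
    outlier_idx: Dict[str, Dict[str, np.ndarray]] = {}
    for mod in series:
        rates = config.outlier_rates.get(mod, {})
        series[mod], idx = inject_outliers(series[mod], rates, rng, protect=protect_ts)
        outlier_idx[mod] = idx

    # --- PRO responses ----------------------------------------------------
    rows = []
    sleep_reports = []
    for d in range(D):
        f = fatigue[d]
        for slot, slot_h in PRO_SLOT_HOURS.items():
            latest = 2.4 if slot == "evening" else 2.8
            resp_t = t0 + pd.Timedelta(
                seconds=d * DAY + slot_h * 3600 + rng.uniform(360, latest * 3600)
            )
            for item, slots in PRO_SCHEDULE.items():
                if slot not in slots:
                    continue
                if rng.random() < config.pro_dropout:
                    continue
                nz = rng.normal(0, config.pro_noise_sd)
                if item == "physical_fatigue":
                    val = f + nz
                elif item == "mental_fatigue":
                    val = 0.85 * f + 0.4 + nz
                elif item == "anxiousness":
                    val = 1.2 + 0.3 * f + nz
                elif item == "depression":
                    val = 1.0 + 0.3 * f + nz
                elif item == "pain":
                    val = {"healthy": 0.5, "NDD": 1.5, "IMID": 2.0}[group] + 0.2 * f + nz
                elif item == "sleep_quality":
                    val = 4.3 - 0.5 * f + nz
                elif item == "sleepiness":
                    val = 0.8 + 0.6 * f + nz
                elif item == "activity_physical":
                    val = 3.0 - 0.3 * f + nz
                elif item == "activity_mental":
                    val = 3.0 + nz
                elif item in ("bed_time", "wake_time"):
                    if d == 0:
                        continue  # previous night predates the recording
                    night = sleep_truth[d - 1]
                    if item == "bed_time":
                        true_h = (night["start"] % DAY) / 3600.0
                        rep = (true_h + rng.normal(0, 1 / 6)) % 24.0
                        shifted = False
                        if rep >= 12.0 and rng.random() < config.sleep_shift_error_rate:
                            rep -= 12.0
                            shifted = True
                        sleep_reports.append(
                            {"day": d, "item": item, "true_hour": true_h, "shifted": shifted}
                        )
                        val = rep
                    else:
                        true_h = (night["end"] % DAY) / 3600.0
                        val = (true_h + rng.normal(0, 1 / 6)) % 24.0
                    rows.append(
                        {
                            "participant_id": participant_id,
                            "timestamp": resp_t,
                            "day": d,
                            "slot": slot,
                            "item_id": item,
                            "value": float(val),
                        }
                    )
                    continue
                val = float(np.clip(np.round(val), 0, 6))
                rows.append(
                    {
                        "participant_id": participant_id,
                        "timestamp": resp_t,
                        "day": d,
                        "slot": slot,
                        "item_id": item,
                        "value": val,
                    }
                )
    pros = pd.DataFrame(rows, columns=PRO_COLUMNS)

    def _ts(sec):
        return t0 + pd.Timedelta(seconds=int(sec))

    truth = GroundTruth(
        participant_id=participant_id,
        group=group,
        fatigue=fatigue,
        rest_intervals=[(_ts(a), _ts(b)) for a, b in rest_intervals],
        walk_bouts=[
            {
                "start": _ts(wb["start"]),
                "end": _ts(wb["end"]),
                "steps": wb["steps"],
                "kind": wb["kind"],
                "compliant": wb["compliant"],
            }
            for wb in walk_bouts
        ],
        planted_hrr=float(planted_hrr),
        outlier_indices=outlier_idx,
        sleep_reports=sleep_reports,
        age=age,
        sex=sex,
    )
    return series, pros, truth


def generate_cohort(
    config: CohortConfig,
) -> Tuple[List[ParticipantBundle], Dict[str, GroundTruth]]:
    """Generate the full cohort with independent per-participant streams."""
    sizes = config.group_sizes()
    bundles: List[ParticipantBundle] = []
    truths: Dict[str, GroundTruth] = {}
    prefix = {"healthy": "H", "NDD": "N", "IMID": "I"}
    for gi, group in enumerate(GROUPS):
        for k in range(sizes[group]):
            pid = f"{prefix[group]}{k + 1:02d}"
            # stream keyed by (seed, group, index): one participant's
            # stream is independent of every other's and of group sizes
            rng = np.random.default_rng(np.random.SeedSequence([config.seed, gi, k]))
            series, pros, truth = generate_participant(config, group, rng, pid)
            bundles.append(
                ParticipantBundle(pid, group, series, pros, age=truth.age, sex=truth.sex)
            )
            truths[pid] = truth
    return bundles, truths


# ---------------------------------------------------------------------------
# on-disk layout: tidy CSV per participant-modality + JSON ground truth


def write_cohort(bundles, truths, outdir) -> None:
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for b in bundles:
        pdir = outdir / b.participant_id
        pdir.mkdir(exist_ok=True)
        for mod, s in b.series.items():
            df = pd.DataFrame(
                {"timestamp": s.times.strftime("%Y-%m-%dT%H:%M:%S.%f%z"), "value": s.values}
            )
            df.to_csv(pdir / f"{mod}.csv", index=False)
        b.pros.to_csv(pdir / "pro.csv", index=False)
        t = truths[b.participant_id]
        gt = {
            "participant_id": t.participant_id,
            "group": t.group,
            "fatigue": [float(x) for x in t.fatigue],
            "rest_intervals": [[str(a), str(b_)] for a, b_ in t.rest_intervals],
            "walk_bouts": [
                {**wb, "start": str(wb["start"]), "end": str(wb["end"])}
                for wb in t.walk_bouts
            ],
            "planted_hrr": t.planted_hrr,
            "outlier_indices": {
                m: {c: [int(i) for i in v] for c, v in d.items()}
                for m, d in t.outlier_indices.items()
            },
            "sleep_reports": t.sleep_reports,
            "age": t.age,
            "sex": t.sex,
        }
        (pdir / "ground_truth.json").write_text(json.dumps(gt, indent=1))
    index = pd.DataFrame(
        [
            {
                "participant_id": b.participant_id,
                "group": b.group,
                "age": b.age,
                "sex": b.sex,
            }
            for b in bundles
        ]
    )
    index.to_csv(outdir / "participants.csv", index=False)


def read_bundle(
    outdir, participant_id: str, group: str, age=None, sex=None
) -> ParticipantBundle:
    import pathlib

    pdir = pathlib.Path(outdir) / participant_id
    series = {}
    for mod in (HR, RR_INTERVAL, RESP_RATE, SKIN_T, STEPS, POSTURE):
        df = pd.read_csv(pdir / f"{mod}.csv", parse_dates=["timestamp"])
        vals = df["value"].to_numpy()
        if mod != POSTURE:
            vals = vals.astype(float)
        series[mod] = make_series(participant_id, mod, df["timestamp"], vals)
    pros = pd.read_csv(pdir / "pro.csv", parse_dates=["timestamp"])
    return ParticipantBundle(participant_id, group, series, pros, age=age, sex=sex)


def read_cohort(outdir) -> List[ParticipantBundle]:
    import pathlib

    index = pd.read_csv(pathlib.Path(outdir) / "participants.csv")
    return [
        read_bundle(
            outdir,
            row.participant_id,
            row.group,
            getattr(row, "age", None),
            getattr(row, "sex", None),
        )
        for row in index.itertuples()
    ]
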