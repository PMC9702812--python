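"""Shared domain types and constants for the wearable signal pipeline.

The pipeline handles six modalities from a chest-worn ECG patch sensor:
heart rate, R-to-R interval, respiratory rate and skin temperature
(derived channels, nominally 0.25 Hz except R-to-R which is emitted per
detected beat), plus step count and posture class at 1 Hz.  Patient
reported outcomes (PROs) are 0-6 Likert self-ratings and sleep clock
times collected at four daily slots.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Modalities

HR = "hr"
RR_INTERVAL = "rr_interval"
RESP_RATE = "resp_rate"
SKIN_T = "skin_t"
STEPS = "steps"
POSTURE = "posture"

MODALITIES = (HR, RR_INTERVAL, RESP_RATE, SKIN_T, STEPS, POSTURE)

#: physiological channels that are range/contextually filtered
PHYSIO_MODALITIES = (HR, RR_INTERVAL, RESP_RATE, SKIN_T)

#: nominal sampling rate in Hz; R-to-R is beat-timed (no fixed grid)
NOMINAL_RATE = {
    HR: 0.25,
    RR_INTERVAL: None,
    RESP_RATE: 0.25,
    SKIN_T: 0.25,
    STEPS: 1.0,
    POSTURE: 1.0,
}

#: out-of-band code marking an unsuccessfully measured (invalid) sample
INVALID_VALUE = -1.0
INVALID_POSTURE = "unknown"

POSTURE_CLASSES = ("lying", "sitting", "standing", "walking")

# ---------------------------------------------------------------------------
# PRO schedule (items x daily slots)

PRO_SLOT_HOURS = {
    "morning": 9,
    "early_afternoon": 13,
    "late_afternoon": 17,
    "evening": 21,
}

ALL_SLOTS = tuple(PRO_SLOT_HOURS)

#: item -> slots at which it is prompted
PRO_SCHEDULE = {
    "physical_fatigue": ALL_SLOTS,
    "mental_fatigue": ALL_SLOTS,
    "anxiousness": ALL_SLOTS,
    "depression": ALL_SLOTS,
    "pain": ALL_SLOTS,
    "bed_time": ("morning",),
    "wake_time": ("morning",),
    "sleep_quality": ("morning",),
    "sleepiness": ("early_afternoon", "late_afternoon", "evening"),
    "activity_physical": ("evening",),
    "activity_mental": ("evening",),
}

LIKERT_ITEMS = (
    "physical_fatigue",
    "mental_fatigue",
    "anxiousness",
    "depression",
    "pain",
    "sleep_quality",
    "sleepiness",
    "activity_physical",
    "activity_mental",
)

CLOCK_ITEMS = ("bed_time", "wake_time")

GROUPS = ("healthy", "NDD", "IMID")


# ---------------------------------------------------------------------------


@dataclass
class SampleSeries:
    """One modality's timestamped samples for one participant.

    ``samples`` is a pandas Series indexed by tz-aware UTC timestamps.
    Values are floats for numeric channels and posture-class strings for
    the posture channel.
    """

    participant_id: str
    modality: str
    samples: pd.Series
    nominal_rate: Optional[float] = None

    def __post_init__(self):
        if self.nominal_rate is None:
            self.nominal_rate = NOMINAL_RATE.get(self.modality)
        if not isinstance(self.samples.index, pd.DatetimeIndex):
            raise TypeError("samples must be indexed by a DatetimeIndex")
        if self.samples.index.tz is None:
            self.samples = self.samples.tz_localize("UTC")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def times(self) -> pd.DatetimeIndex:
        return self.samples.index

    @property
    def values(self) -> np.ndarray:
        return self.samples.to_numpy()

    def between(self, start, end, closed: str = "right") -> "SampleSeries":
        """Samples inside the interval; ``closed`` as in pandas slicing."""
        idx = self.samples.index
        if closed == "right":
            mask = (idx > start) & (idx <= end)
        elif closed == "left":
            mask = (idx >= start) & (idx < end)
        elif closed == "both":
            mask = (idx >= start) & (idx <= end)
        else:
            mask = (idx > start) & (idx < end)
        return replace(self, samples=self.samples[mask])

    def with_samples(self, samples: pd.Series) -> "SampleSeries":
        return replace(self, samples=samples)


def seconds(index: pd.DatetimeIndex) -> np.ndarray:
    """Timestamps as float seconds since the epoch."""
    return index.asi8 / 1e9


def make_series(
    participant_id: str,
    modality: str,
    times,
    values,
    nominal_rate: Optional[float] = None,
) -> SampleSeries:
    idx = pd.DatetimeIndex(times)
    if idx.tz is None:
        idx = idx.tz_localize("UTC")
    return SampleSeries(
        participant_id, modality, pd.Series(values, index=idx), nominal_rate
    )


@dataclass
class ParticipantBundle:
    """All six signal channels plus the PRO table for one participant."""

    participant_id: str
    group: str
    series: dict  # modality -> SampleSeries
    pros: pd.DataFrame  # columns: participant_id, timestamp, day, slot, item_id, value
    age: Optional[float] = None
    sex: Optional[str] = None  # 'F' / 'M'

    def __getitem__(self, modality: str) -> SampleSeries:
        return self.series[modality]


PRO_COLUMNS = ["participant_id", "timestamp", "day", "slot", "item_id", "value"]


def empty_pro_table() -> pd.DataFrame:
    return pd.DataFrame(columns=PRO_COLUMNS)
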