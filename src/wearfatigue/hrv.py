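"""Heart-rate-variability feature battery on an R-to-R segment.

The cleaned R-to-R tachogram is first corrected to normal-to-normal
(NN) intervals with the Malik rule — an interval deviating more than
20% from the previous *accepted* interval is replaced by linear
interpolation — then summarised in four domains:

* time domain: NN mean/CV/SD/median/range, RMSSD, CVSD, SDSD, NN50,
  NN20, pNN50, pNN20 and heart-rate statistics on 60000/NN;
* frequency domain: Welch power in the VLF (0.003–0.04 Hz),
  LF (0.04–0.15 Hz) and HF (0.15–0.40 Hz) bands of the tachogram
  resampled to an even 4 Hz grid, plus LF/HF and normalised powers;
* geometric: the triangular index (sample count over the modal bin of
  the NN histogram, bin width 1/128 s);
* non-linear: Poincaré SD1/SD2 and the cardiac sympathetic/vagal
  indices CSI, mCSI (Toichi's modified longitudinal²/transverse form)
  and CVI.

Standard deviations use the unbiased (n−1) estimator throughout, which
keeps the Poincaré identity SD1² + SD2² = 2·SDNN² exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import detrend, welch

VLF_BAND = (0.003, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)

#: Malik rule: deviation beyond this fraction of the previous accepted
#: interval marks an ectopic beat
MALIK_THRESHOLD = 0.20

#: triangular-index histogram bin width: 1/128 s in ms
TRI_BIN_MS = 1000.0 / 128.0

RESAMPLE_HZ = 4.0
WELCH_SEG_S = 256.0

#: Table-style feature names, one per battery entry
FEATURE_NAMES = (
    "NN mean", "NN CV", "NN SD", "NN median", "NN range",
    "RMSSD", "CVSD", "SDSD", "NN50", "NN20", "pNN50", "pNN20",
    "HRV HR mean", "HRV HR SD", "HRV HR min", "HRV HR max",
    "VLF", "LF", "HF", "Total power", "LF/HF", "LFnu", "HFnu",
    "Triangular index", "CSI", "mCSI", "CVI", "SD1", "SD2", "SD2/SD1",
)


@dataclass
class NNSeries:
    """Normal-to-normal intervals after ectopic replacement."""

    times_s: np.ndarray  # seconds (monotone)
    intervals_ms: np.ndarray
    n_replaced: int = 0

    def __len__(self) -> int:
        return len(self.intervals_ms)


def malik_correct(times_s: np.ndarray, rr_ms: np.ndarray) -> NNSeries:
    """Replace ectopic intervals by the Malik 20% rule.

    Scanning in time order, an interval deviating more than 20% from
    the previous accepted interval is replaced by linear interpolation
    (in time) between the previous accepted interval and the next
    acceptable one.  Trailing intervals with no acceptable successor
    are dropped.
    """
    times_s = np.asarray(times_s, dtype=float)
    rr = np.asarray(rr_ms, dtype=float)
    n = len(rr)
    if n < 3:
        raise ValueError("need at least 3 intervals")
    out_t: list = [times_s[0]]
    out_v: list = [rr[0]]
    n_replaced = 0
    prev_v = rr[0]
    prev_t = times_s[0]
    i = 1
    while i < n:
        if abs(rr[i] - prev_v) / prev_v <= MALIK_THRESHOLD:
            out_t.append(times_s[i])
            out_v.append(rr[i])
            prev_v, prev_t = rr[i], times_s[i]
            i += 1
            continue
        # find next acceptable interval
        j = i + 1
        while j < n and abs(rr[j] - prev_v) / prev_v > MALIK_THRESHOLD:
            j += 1
        if j == n:
            break  # no anchor on the right: drop the tail
        for k in range(i, j):
            frac = (times_s[k] - prev_t) / (times_s[j] - prev_t)
            out_t.append(times_s[k])
            out_v.append(prev_v + frac * (rr[j] - prev_v))
            n_replaced += 1
        out_t.append(times_s[j])
        out_v.append(rr[j])
        prev_v, prev_t = rr[j], times_s[j]
        i = j + 1
    return NNSeries(np.array(out_t), np.array(out_v), n_replaced)


def nn_from_series(series) -> NNSeries:
    """Malik-correct a cleaned R-to-R :class:`SampleSeries` segment."""
    from .core import seconds

    return malik_correct(seconds(series.times), series.values.astype(float))


# ---------------------------------------------------------------------------


def time_domain(nn: NNSeries) -> Dict[str, float]:
    x = nn.intervals_ms
    if len(x) < 2:
        raise ValueError("need at least 2 intervals")
    d = np.diff(x)
    f: Dict[str, float] = {}
    f["NN mean"] = float(np.mean(x))
    f["NN SD"] = float(np.std(x, ddof=1))
    f["NN CV"] = f["NN SD"] / f["NN mean"] if f["NN mean"] else np.nan
    f["NN median"] = float(np.median(x))
    f["NN range"] = float(np.max(x) - np.min(x))
    if len(x) >= 3:
        f["RMSSD"] = float(np.sqrt(np.mean(d**2)))
        f["SDSD"] = float(np.std(d, ddof=1))
        f["CVSD"] = f["RMSSD"] / f["NN mean"] if f["NN mean"] else np.nan
        f["NN50"] = int(np.sum(np.abs(d) > 50.0))
        f["NN20"] = int(np.sum(np.abs(d) > 20.0))
        f["pNN50"] = 100.0 * f["NN50"] / len(d)
        f["pNN20"] = 100.0 * f["NN20"] / len(d)
    else:
        for k in ("RMSSD", "SDSD", "CVSD", "NN50", "NN20", "pNN50", "pNN20"):
            f[k] = np.nan
    hr = 60000.0 / x
    f["HRV HR mean"] = float(np.mean(hr))
    f["HRV HR SD"] = float(np.std(hr, ddof=1))
    f["HRV HR min"] = float(np.min(hr))
    f["HRV HR max"] = float(np.max(hr))
    return f


def _band_power(freqs: np.ndarray, psd: np.ndarray, band) -> float:
    lo, hi = band
    mask = (freqs >= lo) & (freqs < hi)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd[mask], freqs[mask]))


def freq_domain(
    nn: NNSeries,
    fs: float = RESAMPLE_HZ,
    max_gap_fraction: float = 0.20,
    gap_s: float = 5.0,
) -> Dict[str, float]:
    """Welch band powers of the evenly resampled tachogram.

    The NN series is cubic-interpolated onto a ``fs`` grid, linearly
    detrended, and analysed with Welch (256-s Hann segments, 50%
    overlap).  Returns NaNs when the segment is shorter than 5 min or
    more than 20% of the grid falls into tachogram gaps (> ``gap_s``
    between beats).
    """
    missing = {k: np.nan for k in ("VLF", "LF", "HF", "Total power", "LF/HF", "LFnu", "HFnu")}
    t, x = nn.times_s, nn.intervals_ms
    if len(x) < 4 or t[-1] - t[0] < 300.0:
        return missing
    grid = np.arange(t[0], t[-1], 1.0 / fs)
    gaps = np.diff(t)
    if np.any(gaps > gap_s):
        # fraction of grid points inside long gaps
        bad = 0
        for i in np.flatnonzero(gaps > gap_s):
            bad += np.sum((grid > t[i]) & (grid < t[i + 1]))
        if bad / len(grid) > max_gap_fraction:
            return missing
    xi = CubicSpline(t, x)(grid)
    xi = detrend(xi, type="linear")
    nperseg = min(int(WELCH_SEG_S * fs), len(xi))
    freqs, psd = welch(xi, fs=fs, window="hann", nperseg=nperseg)
    vlf = _band_power(freqs, psd, VLF_BAND)
    lf = _band_power(freqs, psd, LF_BAND)
    hf = _band_power(freqs, psd, HF_BAND)
    out = {
        "VLF": vlf,
        "LF": lf,
        "HF": hf,
        "Total power": vlf + lf + hf,
        "LF/HF": lf / hf if hf > 0 else np.nan,
        "LFnu": lf / (lf + hf) if lf + hf > 0 else np.nan,
        "HFnu": hf / (lf + hf) if lf + hf > 0 else np.nan,
    }
    return out


def geometric_nonlinear(nn: NNSeries) -> Dict[str, float]:
    x = nn.intervals_ms
    f: Dict[str, float] = {}
    if len(x) >= 20:
        edges = np.arange(0.0, np.max(x) + 2 * TRI_BIN_MS, TRI_BIN_MS)
        counts, _ = np.histogram(x, bins=edges)
        f["Triangular index"] = float(len(x) / counts.max())
    else:
        f["Triangular index"] = np.nan
    if len(x) < 3:
        for k in ("SD1", "SD2", "SD2/SD1", "CSI", "mCSI", "CVI"):
            f[k] = np.nan
        return f
    d = np.diff(x)
    var_d = np.var(d, ddof=1)
    var_x = np.var(x, ddof=1)
    sd1 = np.sqrt(var_d / 2.0)
    sd2_sq = 2.0 * var_x - var_d / 2.0
    sd2 = np.sqrt(max(sd2_sq, 0.0))
    f["SD1"] = float(sd1)
    f["SD2"] = float(sd2)
    if sd1 > 0:
        f["SD2/SD1"] = float(sd2 / sd1)
        f["CSI"] = float(sd2 / sd1)
        f["mCSI"] = float((4.0 * sd2) ** 2 / (4.0 * sd1))
    else:
        f["SD2/SD1"] = f["CSI"] = f["mCSI"] = np.nan
    prod = (4.0 * sd1) * (4.0 * sd2)
    f["CVI"] = float(np.log10(prod)) if prod > 0 else np.nan
    return f


def compute_features(nn: NNSeries) -> Dict[str, float]:
    """Full battery; keys follow :data:`FEATURE_NAMES`."""
    f = {}
    f.update(time_domain(nn))
    f.update(freq_domain(nn))
    f.update(geometric_nonlinear(nn))
    return {k: f.get(k, np.nan) for k in FEATURE_NAMES}


def features_from_series(series, min_intervals: int = 3) -> Optional[Dict[str, float]]:
    """Malik-correct and summarise a cleaned R-to-R segment; ``None`` if
    the segment is too short."""
    if len(series) < min_intervals:
        return None
    try:
        nn = nn_from_series(series)
    except ValueError:
        return None
    if len(nn) < min_intervals:
        return None
    return compute_features(nn)
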