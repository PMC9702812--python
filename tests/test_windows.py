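"""2-h aggregates, L5 rest detection, and L5-referenced normalization."""

import numpy as np
import pandas as pd
import pytest

from wearfatigue.core import (
    HR,
    POSTURE,
    RESP_RATE,
    RR_INTERVAL,
    SKIN_T,
    STEPS,
    ParticipantBundle,
    make_series,
)
from wearfatigue.windows import (
    L5Window,
    aggregate_window,
    detect_l5,
    detect_l5_all,
    l5_params,
    normalize_table,
)

from conftest import T0


def make_bundle(hr_vals=None, rr_vals=None, hr_dt=4.0, participant="P"):
    """Minimal bundle with constant default channels.

    The sampled grid starts one step after T0 so a (T0, T0+2h] window
    holds exactly its nominal number of samples.
    """
    n = len(hr_vals) if hr_vals is not None else 1800
    hr_vals = hr_vals if hr_vals is not None else np.full(n, 60.0)
    times = T0 + pd.to_timedelta((np.arange(len(hr_vals)) + 1) * hr_dt, unit="s")
    series = {
        HR: make_series(participant, HR, times, np.asarray(hr_vals, float)),
        RESP_RATE: make_series(participant, RESP_RATE, times, np.full(len(hr_vals), 14.0)),
        SKIN_T: make_series(participant, SKIN_T, times, np.full(len(hr_vals), 33.0)),
    }
    if rr_vals is None:
        rr_vals = np.full(7200, 1000.0)
    rr_t = T0 + pd.to_timedelta(np.cumsum(np.asarray(rr_vals)) / 1000.0, unit="s")
    series[RR_INTERVAL] = make_series(participant, RR_INTERVAL, rr_t, np.asarray(rr_vals, float))
    sec = T0 + pd.to_timedelta(np.arange(7200), unit="s")
    series[STEPS] = make_series(participant, STEPS, sec, np.zeros(7200))
    series[POSTURE] = make_series(participant, POSTURE, sec, np.array(["sitting"] * 7200, dtype=object))
    pros = pd.DataFrame(
        columns=["participant_id", "timestamp", "day", "slot", "item_id", "value"]
    )
    return ParticipantBundle(participant, "healthy", series, pros)


class TestAggregateWindow:
    def test_constant_hr(self):
        b = make_bundle(np.full(1800, 60.0))
        feats, cov = aggregate_window(b, T0 + pd.Timedelta(hours=2))
        assert feats["HR mean"] == 60.0
        assert feats["HR SD"] == 0.0
        assert feats["HR min"] == feats["HR max"] == 60.0
        assert cov[HR] == pytest.approx(1.0)

    def test_half_empty_window_coverage(self):
        b = make_bundle(np.full(900, 60.0))  # only first hour present
        feats, cov = aggregate_window(b, T0 + pd.Timedelta(hours=2))
        assert cov[HR] == pytest.approx(0.5)

    def test_two_level_values(self):
        vals = np.tile([50.0, 70.0], 900)
        b = make_bundle(vals)
        feats, _ = aggregate_window(b, T0 + pd.Timedelta(hours=2))
        assert feats["HR mean"] == pytest.approx(60.0)
        assert feats["HR min"] == 50.0 and feats["HR max"] == 70.0

    def test_empty_window_missing(self):
        b = make_bundle(np.full(100, 60.0))
        feats, cov = aggregate_window(b, T0 + pd.Timedelta(days=2))
        assert np.isnan(feats["HR mean"])
        assert cov[HR] == 0.0


def build_day(posture_spec, steps_spec=None, t0=T0):
    """1 Hz posture/steps over 24 h from [(hours, class), ...] blocks."""
    post = []
    for hours, cls in posture_spec:
        post.extend([cls] * int(hours * 3600))
    post = np.array(post[:86400], dtype=object)
    steps = np.zeros(len(post))
    if steps_spec:
        for (h0, h1), rate in steps_spec:
            steps[int(h0 * 3600) : int(h1 * 3600)] = rate
    sec = t0 + pd.to_timedelta(np.arange(len(post)), unit="s")
    return (
        make_series("P", STEPS, sec, steps),
        make_series("P", POSTURE, sec, post),
    )


class TestDetectL5:
    def test_planted_night_found(self):
        # lying 22:00-06:00 inside an active day (span noon-noon)
        steps, posture = build_day(
            [(12, "sitting"), (10, "sitting"), (2, "lying")],
            steps_spec=[((8, 20), 0.1)],
        )
        steps2, posture2 = build_day(
            [(6, "lying"), (18, "sitting")],
            t0=T0 + pd.Timedelta(days=1),
        )
        st = steps.with_samples(pd.concat([steps.samples, steps2.samples]))
        po = posture.with_samples(pd.concat([posture.samples, posture2.samples]))
        w = detect_l5(st, po, T0 + pd.Timedelta(hours=12), T0 + pd.Timedelta(hours=36))
        assert w is not None
        assert w.lying_fraction >= 0.99
        # fully inside the 22:00-06:00 lying block
        assert w.start >= T0 + pd.Timedelta(hours=22) - pd.Timedelta(minutes=1)
        assert w.end <= T0 + pd.Timedelta(hours=30) + pd.Timedelta(minutes=1)

    def test_all_day_walking_no_window(self):
        steps, posture = build_day([(24, "walking")], steps_spec=[((0, 24), 2.0)])
        assert detect_l5(steps, posture, T0, T0 + pd.Timedelta(hours=24)) is None

    def test_higher_lying_fraction_wins(self):
        # two separated rest blocks: 0.85 lying vs pure lying
        spec = [
            (5 * 0.85, "lying"), (5 * 0.15, "sitting"),  # block A: 85%
            (4, "walking"),
            (5, "lying"),  # block B: 100%
            (24 - 5 - 4 - 5, "walking"),
        ]
        steps, posture = build_day(spec, steps_spec=[((14.4, 24), 2.0)])
        w = detect_l5(steps, posture, T0, T0 + pd.Timedelta(hours=24))
        assert w.lying_fraction == pytest.approx(1.0)
        assert abs((w.start - (T0 + pd.Timedelta(hours=9))).total_seconds()) <= 60

    def test_absent_posture_no_window(self):
        steps, posture = build_day([(24, "sitting")])
        empty = posture.with_samples(posture.samples.iloc[:0])
        assert detect_l5(steps, empty, T0, T0 + pd.Timedelta(hours=24)) is None

    def test_step_budget_enforced(self):
        steps, posture = build_day(
            [(24, "lying")], steps_spec=[((2, 2.1), 0.5)]
        )  # 180 steps inside every candidate window overlapping 02:00
        w = detect_l5(steps, posture, T0, T0 + pd.Timedelta(hours=24))
        assert w is not None
        assert w.step_total <= 100

    def test_exhaustive_scan_oracle_agreement(self, tiny_cleaned):
        cleaned, _, _ = tiny_cleaned
        b = cleaned[0]
        from wearfatigue.windows import noon_spans

        for span in noon_spans(b):
            got = detect_l5(b[STEPS], b[POSTURE], *span)
            exp = brute_force_l5(b[STEPS], b[POSTURE], *span)
            if exp is None:
                assert got is None
            else:
                assert got is not None
                assert got.start == exp[0]
                assert got.lying_fraction == pytest.approx(exp[1])


def brute_force_l5(steps, posture, span_start, span_end):
    """Naive scan over all 1-min starts with the same eligibility rules."""
    win = pd.Timedelta(hours=5)
    slack = pd.Timedelta(minutes=1)
    first, last = posture.times[0], posture.times[-1]
    best = None
    t = span_start
    while t + win <= span_end:
        if t < first - slack or t + win > last + slack:
            t += pd.Timedelta(minutes=1)
            continue
        p = posture.between(t, t + win, closed="left")
        s = steps.between(t, t + win, closed="left")
        present = len(p)
        if present >= 0.5 * 18000:
            lying = float((p.samples == "lying").mean())
            tot = float(s.values.astype(float).sum())
            if tot <= 100 and lying >= 0.80:
                key = (-lying, tot, t.value)
                if best is None or key < best[0]:
                    best = (key, t, lying)
        t += pd.Timedelta(minutes=1)
    return None if best is None else (best[1], best[2])


class TestL5Params:
    def test_constant_hr(self):
        b = make_bundle(np.full(5400, 55.0), hr_dt=4.0)
        w = L5Window("P", T0, T0 + pd.Timedelta(hours=5), 0.0, 1.0)
        w = l5_params(w, b)
        mu, sd = w.signal_params[HR]
        assert mu == 55.0 and sd == 0.0

    def test_alternating_unbiased_sd(self):
        vals = np.tile([50.0, 60.0], 500)  # n = 1000 inside the window
        b = make_bundle(vals, hr_dt=17.9)
        w = L5Window("P", T0, T0 + pd.Timedelta(hours=5), 0.0, 1.0)
        w = l5_params(w, b)
        mu, sd = w.signal_params[HR]
        assert mu == pytest.approx(55.0)
        assert sd == pytest.approx(5.0025, abs=1e-3)  # n-1 estimator at n=1000

    def test_missing_channel_missing_params(self):
        b = make_bundle(np.full(5400, 55.0))
        b.series[SKIN_T] = b.series[SKIN_T].with_samples(
            b.series[SKIN_T].samples.iloc[:0]
        )
        w = L5Window("P", T0, T0 + pd.Timedelta(hours=5), 0.0, 1.0)
        w = l5_params(w, b)
        assert SKIN_T not in w.signal_params


def agg_row(anchor, feature, raw, coverage=1.0):
    return {
        "participant_id": "P",
        "group": "healthy",
        "anchor_time": anchor,
        "item_id": "physical_fatigue",
        "pro_value": 3.0,
        "feature": feature,
        "raw": raw,
        "coverage": coverage,
    }


def l5_with_params(start, mu=60.0, sd=5.0):
    w = L5Window("P", start, start + pd.Timedelta(hours=5), 0.0, 1.0)
    w.signal_params = {HR: (mu, sd), RR_INTERVAL: (1000.0, 50.0)}
    return w


class TestNormalize:
    def test_zscore_values(self):
        anchor = T0 + pd.Timedelta(hours=10)
        agg = pd.DataFrame(
            [agg_row(anchor, "HR mean", 60.0), agg_row(anchor, "HR max", 65.0)]
        )
        out = normalize_table(agg, [l5_with_params(T0)], variant="b")
        by_feat = out.set_index("feature")["normalized"]
        assert by_feat["HR mean"] == pytest.approx(0.0)  # x = mu
        assert by_feat["HR max"] == pytest.approx(1.0)  # x = mu + sigma

    def test_variant_b_averages_params(self):
        anchor = T0 + pd.Timedelta(hours=30)
        agg = pd.DataFrame([agg_row(anchor, "HR mean", 70.0)])
        refs = [
            l5_with_params(T0, mu=60.0, sd=4.0),
            l5_with_params(T0 + pd.Timedelta(days=1), mu=64.0, sd=6.0),
        ]
        out = normalize_table(agg, refs, variant="b")
        assert out["normalized"].iloc[0] == pytest.approx((70.0 - 62.0) / 5.0)

    def test_variant_a_uses_nearest_previous(self):
        anchor = T0 + pd.Timedelta(hours=30)
        refs = [
            l5_with_params(T0, mu=60.0, sd=4.0),  # ends 05:00
            l5_with_params(T0 + pd.Timedelta(hours=20), mu=64.0, sd=6.0),  # ends 25:00
            l5_with_params(T0 + pd.Timedelta(hours=40), mu=90.0, sd=1.0),  # future
        ]
        agg = pd.DataFrame([agg_row(anchor, "HR mean", 70.0)])
        out = normalize_table(agg, refs, variant="a")
        assert out["normalized"].iloc[0] == pytest.approx((70.0 - 64.0) / 6.0)

    def test_variant_a_excludes_without_previous_l5(self):
        anchor = T0 + pd.Timedelta(hours=2)
        refs = [l5_with_params(T0 + pd.Timedelta(hours=20))]  # ends later
        agg = pd.DataFrame([agg_row(anchor, "HR mean", 70.0)])
        out = normalize_table(agg, refs, variant="a")
        assert len(out) == 0

    def test_zero_sigma_flagged_missing(self):
        anchor = T0 + pd.Timedelta(hours=10)
        agg = pd.DataFrame([agg_row(anchor, "HR mean", 70.0)])
        out = normalize_table(agg, [l5_with_params(T0, sd=0.0)], variant="b")
        assert len(out) == 1 and np.isnan(out["normalized"].iloc[0])

    def test_l5_self_normalization_unit_moments(self, tiny_cleaned):
        cleaned, _, _ = tiny_cleaned
        b = cleaned[0]
        w = detect_l5_all(b)[0]
        v = b[HR].between(w.start, w.end, closed="left").values.astype(float)
        mu, sd = w.signal_params[HR]
        z = (v - mu) / sd
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, rel=1e-12)


class TestL5Recovery:
    def test_detected_l5_within_true_rest(self, tiny_cleaned):
        cleaned, truths, _ = tiny_cleaned
        tol = pd.Timedelta(minutes=30)
        for b in cleaned:
            rests = truths[b.participant_id].rest_intervals
            for w in detect_l5_all(b):
                ok = any(
                    w.start >= a - tol and w.end <= e + tol for a, e in rests
                )
                assert ok, f"L5 {w.start} outside true rest for {b.participant_id}"
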