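"""Walk detection, rest-minute HRR extraction, and group ANCOVA."""

import numpy as np
import pandas as pd
import pytest

from wearfatigue.core import HR, POSTURE, STEPS, make_series
from wearfatigue.hrr import (
    ancova_groups,
    detect_rest_and_hrr,
    detect_walks,
    fatigue_split,
    representative_hrr,
)

from conftest import T0


def posture_steps(blocks, step_rate=None):
    """1 Hz posture/steps from [(n_seconds, class), ...]; walking seconds
    get ``step_rate`` steps each (default 1.2)."""
    classes = []
    for n, cls in blocks:
        classes.extend([cls] * n)
    classes = np.array(classes, dtype=object)
    sec = T0 + pd.to_timedelta(np.arange(len(classes)), unit="s")
    steps = np.where(classes == "walking", step_rate if step_rate else 1.2, 0.0)
    return (
        make_series("P", POSTURE, sec, classes),
        make_series("P", STEPS, sec, steps),
    )


def hr_series(values, t0=T0, dt=4.0, offset=0.0):
    t = t0 + pd.to_timedelta(np.arange(len(values)) * dt + offset, unit="s")
    return make_series("P", HR, t, np.asarray(values, float))


class TestDetectWalks:
    def test_seven_min_walk_with_short_gap(self):
        # 7 min of walking with one 2-s standing interruption, 480 steps
        posture, _ = posture_steps(
            [(60, "sitting"), (200, "walking"), (2, "standing"), (218, "walking"), (60, "sitting")]
        )
        sec = posture.times
        steps_v = np.zeros(len(sec))
        walking = posture.samples.to_numpy(dtype=object) == "walking"
        steps_v[walking] = 480.0 / walking.sum()
        steps = make_series("P", STEPS, sec, steps_v)
        bouts = detect_walks(posture, steps)
        assert len(bouts) == 1
        b = bouts[0]
        assert b.duration_min == pytest.approx(7.0)
        assert b.cadence == pytest.approx(480.0 / 7.0, rel=1e-6)
        assert b.interruption_s == pytest.approx(2.0)

    def test_just_under_six_minutes_rejected(self):
        posture, steps = posture_steps([(60, "sitting"), (359, "walking"), (60, "sitting")])
        assert detect_walks(posture, steps) == []

    def test_six_minutes_accepted(self):
        posture, steps = posture_steps([(60, "sitting"), (360, "walking"), (60, "sitting")])
        assert len(detect_walks(posture, steps)) == 1

    def test_low_cadence_rejected(self):
        # 8 min walking but only 400 steps -> cadence 50 < 60
        posture, steps = posture_steps(
            [(60, "sitting"), (480, "walking"), (60, "sitting")], step_rate=400.0 / 480.0
        )
        assert detect_walks(posture, steps) == []

    def test_long_interruption_splits_run(self):
        posture, steps = posture_steps(
            [(300, "walking"), (5, "standing"), (300, "walking")]
        )
        assert detect_walks(posture, steps) == []  # both halves < 6 min

    def test_brute_force_enumeration_agreement(self, clean_participant):
        _, bundle, _ = clean_participant
        got = detect_walks(bundle[POSTURE], bundle[STEPS])
        exp = brute_force_walks(bundle[POSTURE], bundle[STEPS])
        assert [(b.start, b.end) for b in got] == [(s, e) for s, e, *_ in exp]
        for b, (_, _, tot) in zip(got, exp):
            assert b.step_total == pytest.approx(tot)


def brute_force_walks(posture, steps):
    """Naive scan: group walking samples, bridge <= 3 s, apply gates."""
    cls = posture.samples.to_numpy(dtype=object)
    t = posture.times
    runs = []
    cur = None
    for i in range(len(cls)):
        if cls[i] != "walking":
            continue
        if cur is None:
            cur = [t[i], t[i]]
        elif (t[i] - cur[1]).total_seconds() <= 4.0:
            cur[1] = t[i]
        else:
            runs.append(cur)
            cur = [t[i], t[i]]
    if cur is not None:
        runs.append(cur)
    out = []
    for s, e in runs:
        dur = (e - s).total_seconds() + 1.0
        if dur < 360.0:
            continue
        sel = steps.samples[(steps.times >= s) & (steps.times <= e)]
        tot = float(sel.sum())
        if tot / (dur / 60.0) >= 60.0:
            out.append((s, e, tot))
    return out


def make_walk(end_s=600):
    from wearfatigue.hrr import WalkBout

    return WalkBout(
        start=T0,
        end=T0 + pd.Timedelta(seconds=end_s),
        duration_min=end_s / 60.0,
        step_total=700.0,
        cadence=70.0,
        interruption_s=0.0,
    )


class TestRestAndHRR:
    def _channels(self, n_hr=15, steps_in_rest=0.0, offset=4.0):
        walk = make_walk(600)
        hr_vals = np.linspace(120.0, 85.0, 15)[:n_hr]
        hr = hr_series(hr_vals, t0=walk.end, dt=4.0, offset=offset)
        sec = walk.end + pd.to_timedelta(np.arange(1, 61), unit="s")
        steps_v = np.zeros(60)
        if steps_in_rest:
            steps_v[30] = steps_in_rest
        steps = make_series("P", STEPS, sec, steps_v)
        return walk, hr, steps

    def test_descending_rest_gives_max_minus_min(self):
        walk, hr, steps = self._channels()
        obs = detect_rest_and_hrr(walk, hr, steps)
        assert obs is not None
        assert obs.hrr == pytest.approx(35.0)
        assert obs.hr_coverage == 1.0 and obs.steps_in_rest == 0

    def test_missing_hr_sample_no_observation(self):
        walk, hr, steps = self._channels(n_hr=14)
        assert detect_rest_and_hrr(walk, hr, steps) is None

    def test_any_step_in_rest_no_observation(self):
        walk, hr, steps = self._channels(steps_in_rest=1.0)
        assert detect_rest_and_hrr(walk, hr, steps) is None

    def test_walking_resuming_invalidates(self):
        walk, hr, steps = self._channels()
        sec = walk.end + pd.to_timedelta(np.arange(1, 61), unit="s")
        cls = np.array(["sitting"] * 60, dtype=object)
        cls[45:] = "walking"
        posture = make_series("P", POSTURE, sec, cls)
        assert detect_rest_and_hrr(walk, hr, steps, posture) is None

    def test_onset_minus_min_definition(self):
        walk, hr, steps = self._channels()
        obs = detect_rest_and_hrr(walk, hr, steps, definition="onset_minus_min")
        assert obs.hrr == pytest.approx(120.0 - 85.0)


class TestRepresentative:
    def _obs(self, hrr, start_s):
        from wearfatigue.hrr import HRRObservation

        return HRRObservation(
            "P", make_walk(), T0 + pd.Timedelta(seconds=start_s),
            T0 + pd.Timedelta(seconds=start_s + 60), hrr, 1.0, 0.0,
        )

    def test_maximum_selected(self):
        obs = [self._obs(20, 0), self._obs(35, 100), self._obs(28, 200)]
        assert representative_hrr(obs).hrr == 35

    def test_single_observation(self):
        o = self._obs(12, 0)
        assert representative_hrr([o]) is o

    def test_tie_broken_by_earlier_time(self):
        obs = [self._obs(30, 500), self._obs(30, 100)]
        assert representative_hrr(obs).rest_start == T0 + pd.Timedelta(seconds=100)


def ancova_oracle(d):
    """Type II normal-equations oracle for hrr ~ group + age + sex."""
    y = d["hrr"].to_numpy(float)
    groups = sorted(d["group"].unique())
    G = np.column_stack([(d["group"] == g).astype(float) for g in groups[1:]])
    sex = (d["sex"] == sorted(d["sex"].unique())[1]).astype(float).to_numpy()
    age = d["age"].to_numpy(float)
    ones = np.ones(len(d))

    def sse(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    X_full = np.column_stack([ones, G, age, sex])
    X_red = np.column_stack([ones, age, sex])
    sse_full, sse_red = sse(X_full), sse(X_red)
    df_res = len(d) - X_full.shape[1]
    df_g = G.shape[1]
    ss_group = sse_red - sse_full
    F = (ss_group / df_g) / (sse_full / df_res)
    eta = ss_group / (ss_group + sse_full)
    return F, eta


class TestAncova:
    def toy(self):
        rng = np.random.default_rng(12)
        rows = []
        for g, shift in (("healthy", 10.0), ("NDD", 0.0), ("IMID", 4.0)):
            for i in range(5):
                age = 40 + 5 * i
                sex = "F" if i % 2 else "M"
                rows.append(
                    {
                        "participant_id": f"{g}{i}",
                        "group": g,
                        "hrr": 20 + shift - 0.1 * age + (2 if sex == "F" else 0) + rng.normal(0, 2),
                        "age": age,
                        "sex": sex,
                    }
                )
        return pd.DataFrame(rows)

    def test_matches_normal_equations_oracle(self):
        d = self.toy()
        comp = ancova_groups(d)
        F, eta = ancova_oracle(d)
        assert comp.f_stat == pytest.approx(F, abs=1e-8)
        assert comp.partial_eta2["group"] == pytest.approx(eta, abs=1e-8)

    def test_tukey_three_pairs(self):
        comp = ancova_groups(self.toy())
        assert len(comp.tukey) == 3
        assert ((comp.tukey["p_adj"] >= 0) & (comp.tukey["p_adj"] <= 1)).all()

    def test_age_confound_separated_from_group(self):
        rng = np.random.default_rng(5)
        rows = []
        for g in ("healthy", "NDD", "IMID"):
            for i in range(100):
                age = rng.uniform(20, 80)
                rows.append(
                    {
                        "participant_id": f"{g}{i}",
                        "group": g,
                        "hrr": 40 - 0.3 * age + rng.normal(0, 2),
                        "age": age,
                        "sex": "F" if rng.random() < 0.5 else "M",
                    }
                )
        comp = ancova_groups(pd.DataFrame(rows))
        assert comp.partial_eta2["group"] < 0.05
        assert comp.partial_eta2["age"] > 0.5

    def test_too_few_groups_raises(self):
        d = self.toy()
        with pytest.raises(ValueError):
            ancova_groups(d[d["group"] == "healthy"])


class TestFatigueSplit:
    def test_planted_coupling_flagged(self):
        rng = np.random.default_rng(8)
        rows = []
        fatigue = {}
        for i in range(20):
            f = rng.uniform(0, 6)
            pid = f"H{i}"
            fatigue[pid] = f
            rows.append(
                {"participant_id": pid, "group": "healthy", "hrr": 40 - 3 * f + rng.normal(0, 1)}
            )
        out = fatigue_split(pd.DataFrame(rows), pd.Series(fatigue))
        assert out.iloc[0]["significant"]
        assert out.iloc[0]["hrr_high_mean"] < out.iloc[0]["hrr_low_mean"]

    def test_identical_fatigue_skipped(self):
        rows = [
            {"participant_id": f"P{i}", "group": "healthy", "hrr": 30.0 + i}
            for i in range(6)
        ]
        fatigue = pd.Series({f"P{i}": 3.0 for i in range(6)})
        out = fatigue_split(pd.DataFrame(rows), fatigue)
        assert len(out) == 0  # median split degenerate: no high half

    def test_small_group_skipped(self):
        rows = [
            {"participant_id": f"P{i}", "group": "NDD", "hrr": 30.0} for i in range(3)
        ]
        fatigue = pd.Series({f"P{i}": float(i) for i in range(3)})
        assert len(fatigue_split(pd.DataFrame(rows), fatigue)) == 0
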