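"""Free-living heart-rate recovery (HRR) and group-level comparison.

Walk-then-rest sequences are detected retrospectively from the cleaned
1 Hz posture/step channels, in the spirit of a six-minute walk test
performed incidentally during daily living: a walk is a maximal run of
"walking" posture (interruptions up to 3 s bridged) lasting at least
6 min with mean cadence >= 60 steps/min.  HRR is the maximum difference
of the heart-rate signal inside the 1-min rest immediately after the
walk, accepted only with all expected HR samples present and zero
steps.  An alternative reading — HR at rest onset minus the rest
minimum — is available via ``definition="onset_minus_min"``.

Group differences are assessed with a one-way, two-sided ANCOVA of the
per-participant representative (highest) HRR on group with age and sex
as covariates, effect sizes as partial eta^2, and Tukey-adjusted
pairwise comparisons of the covariate-adjusted group means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .core import HR, POSTURE, STEPS, ParticipantBundle, SampleSeries, seconds

MIN_WALK_S = 360.0
MIN_CADENCE = 60.0  # steps/min
MAX_INTERRUPTION_S = 3.0
REST_S = 60.0
REST_EXPECTED_HR_SAMPLES = 15  # 60 s at 0.25 Hz


@dataclass
class WalkBout:
    start: pd.Timestamp  # first walking sample
    end: pd.Timestamp  # last walking sample
    duration_min: float
    step_total: float
    cadence: float  # steps/min
    interruption_s: float


@dataclass
class HRRObservation:
    participant_id: str
    walk: WalkBout
    rest_start: pd.Timestamp
    rest_end: pd.Timestamp
    hrr: float
    hr_coverage: float
    steps_in_rest: float


@dataclass
class GroupComparison:
    f_stat: float
    p: float
    partial_eta2: Dict[str, float]
    tukey: pd.DataFrame  # pair, estimate, p_adj
    group_n: Dict[str, int]
    residual_df: int = 0


def detect_walks(
    posture: SampleSeries,
    steps: SampleSeries,
    min_walk_s: float = MIN_WALK_S,
    min_cadence: float = MIN_CADENCE,
    max_interruption_s: float = MAX_INTERRUPTION_S,
) -> List[WalkBout]:
    """Maximal walking-posture runs with short interruptions bridged."""
    mask = posture.samples.to_numpy(dtype=object) == "walking"
    t = seconds(posture.times)[mask]
    if t.size == 0:
        return []
    # bridge: successive walking samples more than (max_interruption + 1 s)
    # apart start a new run (1 Hz nominal spacing)
    brk = np.flatnonzero(np.diff(t) > max_interruption_s + 1.0)
    starts = np.concatenate([[0], brk + 1])
    ends = np.concatenate([brk, [t.size - 1]])
    ts = seconds(steps.times)
    sv = steps.values.astype(float)
    s_csum = np.concatenate([[0.0], np.cumsum(sv)])
    bouts = []
    for a, b in zip(starts, ends):
        t0, t1 = t[a], t[b]
        duration = t1 - t0 + 1.0  # each 1 Hz sample covers one second
        if duration < min_walk_s:
            continue
        lo = np.searchsorted(ts, t0, side="left")
        hi = np.searchsorted(ts, t1, side="right")
        step_total = float(s_csum[hi] - s_csum[lo])
        cadence = step_total / (duration / 60.0)
        if cadence < min_cadence:
            continue
        n_walk = b - a + 1
        bouts.append(
            WalkBout(
                start=posture.times[0] + pd.Timedelta(seconds=t0 - seconds(posture.times)[0]),
                end=posture.times[0] + pd.Timedelta(seconds=t1 - seconds(posture.times)[0]),
                duration_min=duration / 60.0,
                step_total=step_total,
                cadence=cadence,
                interruption_s=float(duration - n_walk),
            )
        )
    return bouts


def detect_rest_and_hrr(
    walk: WalkBout,
    hr: SampleSeries,
    steps: SampleSeries,
    posture: Optional[SampleSeries] = None,
    definition: str = "max_minus_min",
) -> Optional[HRRObservation]:
    """HRR over the 1-min rest starting at the walk's end.

    Requires all 15 expected 0.25 Hz HR samples, zero steps, and no
    walking posture inside the window; otherwise no observation.
    """
    rest_start = walk.end
    rest_end = rest_start + pd.Timedelta(seconds=REST_S)
    hr_win = hr.between(rest_start, rest_end, closed="right")
    if len(hr_win) < REST_EXPECTED_HR_SAMPLES:
        return None
    step_win = steps.between(rest_start, rest_end, closed="right")
    steps_in_rest = float(step_win.values.astype(float).sum())
    if steps_in_rest != 0:
        return None
    if posture is not None:
        p_win = posture.between(rest_start, rest_end, closed="right")
        if np.any(p_win.samples.to_numpy(dtype=object) == "walking"):
            return None
    v = hr_win.values.astype(float)
    if definition == "max_minus_min":
        hrr = float(np.max(v) - np.min(v))
    elif definition == "onset_minus_min":
        hrr = float(v[0] - np.min(v))
    else:
        raise ValueError(f"unknown HRR definition {definition!r}")
    return HRRObservation(
        participant_id=hr.participant_id,
        walk=walk,
        rest_start=rest_start,
        rest_end=rest_end,
        hrr=hrr,
        hr_coverage=1.0,
        steps_in_rest=steps_in_rest,
    )


def detect_participant_hrr(
    bundle: ParticipantBundle, definition: str = "max_minus_min"
) -> List[HRRObservation]:
    obs = []
    for walk in detect_walks(bundle[POSTURE], bundle[STEPS]):
        o = detect_rest_and_hrr(
            walk, bundle[HR], bundle[STEPS], bundle[POSTURE], definition
        )
        if o is not None:
            obs.append(o)
    return obs


def representative_hrr(observations: List[HRRObservation]) -> HRRObservation:
    """The highest HRR; ties broken by the earliest rest start."""
    if not observations:
        raise ValueError("no observations")
    return sorted(observations, key=lambda o: (-o.hrr, o.rest_start))[0]


# ---------------------------------------------------------------------------
# group statistics


def ancova_groups(data: pd.DataFrame, adjusted_tukey: bool = True) -> GroupComparison:
    """One-way, two-sided ANCOVA of hrr ~ group + age + sex.

    ``data`` columns: participant_id, group, hrr, age, sex (binary).
    Partial eta^2 = SS_term / (SS_term + SS_residual); Tukey pairwise
    p-values use the studentized range on covariate-adjusted group
    means (plain observed means if ``adjusted_tukey`` is False).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    d = data.dropna(subset=["hrr", "age", "sex", "group"]).copy()
    groups = sorted(d["group"].unique())
    if len(groups) < 2 or d.groupby("group").size().min() < 2:
        raise ValueError("need >= 2 groups with >= 2 participants each")
    model = smf.ols("hrr ~ C(group) + age + C(sex)", data=d).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValueError("rank-deficient design")
    aov = sm.stats.anova_lm(model, typ=2)
    ss_res = float(aov.loc["Residual", "sum_sq"])
    term_map = {"C(group)": "group", "age": "age", "C(sex)": "sex"}
    eta = {
        name: float(aov.loc[term, "sum_sq"] / (aov.loc[term, "sum_sq"] + ss_res))
        for term, name in term_map.items()
        if term in aov.index
    }
    f_stat = float(aov.loc["C(group)", "F"])
    p = float(aov.loc["C(group)", "PR(>F)"])
    df_res = int(model.df_resid)

    # covariate-adjusted group means and their pairwise Tukey tests
    ref = pd.DataFrame(
        {
            "group": groups,
            "age": d["age"].mean(),
            "sex": d["sex"].mode().iloc[0],
        }
    )
    if adjusted_tukey:
        design = model.model.data.design_info
        from patsy import dmatrix

        X = np.asarray(dmatrix(design, ref))
        means = X @ model.params.to_numpy()
        cov = model.cov_params().to_numpy()
        rows = []
        k = len(groups)
        for i in range(k):
            for j in range(i + 1, k):
                c = X[i] - X[j]
                est = float(c @ model.params.to_numpy())
                se = float(np.sqrt(c @ cov @ c))
                q = abs(est) / se * np.sqrt(2.0)
                p_adj = float(stats.studentized_range.sf(q, k, df_res))
                rows.append(
                    {
                        "pair": f"{groups[i]} - {groups[j]}",
                        "estimate": est,
                        "se": se,
                        "t": est / se,
                        "p_adj": p_adj,
                    }
                )
        tukey = pd.DataFrame(rows)
    else:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        res = pairwise_tukeyhsd(d["hrr"], d["group"])
        tukey = pd.DataFrame(
            res.summary().data[1:], columns=res.summary().data[0]
        ).rename(columns={"meandiff": "estimate", "p-adj": "p_adj"})
        tukey["pair"] = tukey["group1"] + " - " + tukey["group2"]
    return GroupComparison(
        f_stat=f_stat,
        p=p,
        partial_eta2=eta,
        tukey=tukey,
        group_n=d.groupby("group").size().to_dict(),
        residual_df=df_res,
    )


def fatigue_split(
    hrr_table: pd.DataFrame, fatigue_means: pd.Series, min_group_n: int = 4
) -> pd.DataFrame:
    """Within each group, Welch-t of HRR between high/low halves of a
    median split on mean physical fatigue.

    ``hrr_table`` columns: participant_id, group, hrr; ``fatigue_means``
    maps participant_id to mean physical-fatigue score.  Groups with
    fewer than ``min_group_n`` rated participants, or no fatigue
    spread, are skipped.
    """
    rows = []
    d = hrr_table.copy()
    d["fatigue"] = d["participant_id"].map(fatigue_means)
    d = d.dropna(subset=["fatigue"])
    for group, grp in d.groupby("group"):
        if len(grp) < min_group_n:
            continue
        med = grp["fatigue"].median()
        high = grp[grp["fatigue"] > med]
        low = grp[grp["fatigue"] <= med]
        if len(high) < 2 or len(low) < 2:
            continue
        t, p = stats.ttest_ind(
            high["hrr"], low["hrr"], equal_var=False
        )
        rows.append(
            {
                "group": group,
                "n_high": len(high),
                "n_low": len(low),
                "hrr_high_mean": float(high["hrr"].mean()),
                "hrr_low_mean": float(low["hrr"].mean()),
                "group_mean_fatigue": float(grp["fatigue"].mean()),
                "t": float(t),
                "p": float(p),
                "significant": bool(p < 0.05),
            }
        )
    return pd.DataFrame(rows)


def cohort_hrr_table(bundles, definition: str = "max_minus_min") -> pd.DataFrame:
    """Representative HRR per participant plus all detected sequences."""
    rows = []
    for b in bundles:
        obs = detect_participant_hrr(b, definition)
        if not obs:
            continue
        rep = representative_hrr(obs)
        rows.append(
            {
                "participant_id": b.participant_id,
                "group": b.group,
                "hrr": rep.hrr,
                "n_sequences": len(obs),
                "walk_duration_min": rep.walk.duration_min,
                "cadence": rep.walk.cadence,
            }
        )
    return pd.DataFrame(rows)
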