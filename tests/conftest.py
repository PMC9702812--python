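import numpy as np
import pandas as pd
import pytest

from wearfatigue.core import ParticipantBundle, make_series
from wearfatigue.preprocessing import clean_bundle
from wearfatigue.synthetic import CohortConfig, generate_cohort, generate_participant

T0 = pd.Timestamp("2021-03-01", tz="UTC")


def series_from(values, modality="hr", dt_s=4.0, participant="P", t0=T0):
    """Regular-grid SampleSeries from a plain list of values."""
    times = t0 + pd.to_timedelta(np.arange(len(values)) * dt_s, unit="s")
    return make_series(participant, modality, times, np.asarray(values, dtype=float))


@pytest.fixture(scope="session")
def tiny_cohort():
    """One participant per group, 2 days, fixed seed."""
    cfg = CohortConfig(
        n_healthy=1, n_ndd=1, n_imid=1, days_per_participant=2, seed=123
    )
    bundles, truths = generate_cohort(cfg)
    return cfg, bundles, truths


@pytest.fixture(scope="session")
def tiny_cleaned(tiny_cohort):
    _, bundles, truths = tiny_cohort
    cleaned = []
    reports = {}
    for b in bundles:
        cb, rep = clean_bundle(b)
        cleaned.append(cb)
        reports[b.participant_id] = rep
    return cleaned, truths, reports


@pytest.fixture(scope="session")
def clean_participant():
    """A gap-free, outlier-free 2-day healthy participant."""
    cfg = CohortConfig(
        days_per_participant=2, wear_gap_rate=0.0, outlier_rates={}, seed=42
    )
    rng = np.random.default_rng(np.random.SeedSequence([42, 0, 0]))
    series, pros, truth = generate_participant(cfg, "healthy", rng, "H01")
    bundle = ParticipantBundle("H01", "healthy", series, pros, truth.age, truth.sex)
    return cfg, bundle, truth
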