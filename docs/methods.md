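# Methods

This note documents the models, rules and numerical choices behind
`wearfatigue`, in the order the pipeline applies them, together with
what the synthetic cohort does and does not emulate.

## Signals and sampling model

Six channels per participant: heart rate (HR, beats/min), respiratory
rate (breaths/min) and skin temperature (°C) on a nominal 0.25 Hz
grid; step count and posture class (`lying`/`sitting`/`standing`/
`walking`) at 1 Hz; and R-to-R intervals carried per detected beat
(timestamp = beat time, value = interbeat interval in ms). Beat-timed
R-to-R is the only representation consistent with both the
duration-based coverage definition (summed intervals ≈ wall time when
every beat is captured) and frequency-domain HRV, whose HF band
(0.15–0.40 Hz) cannot be recovered from a 0.25 Hz sample grid. All
timestamps are tz-aware UTC; "day" means local midnight-to-midnight
with the timezone fixed per configuration (UTC by default).

## Cleaning

Order is fixed and single-pass: sort/de-duplicate (first record per
timestamp wins) → drop invalid device codes (out-of-band value −1;
`unknown` for posture) → drop range outliers → drop contextual
outliers. The three removal classes are mutually exclusive, and
contextual window means are computed over values that survived the
earlier stages. Accepted ranges (inclusive on both ends): HR 30–200
beats/min, R-to-R 300–2000 ms, respiratory rate 4–60 breaths/min,
skin temperature 28–40 °C.

A sample is a contextual outlier iff |x − m|/m > threshold, where m is
the mean of all *other* samples within a centred time window
(1 min for HR and R-to-R, 3 min for respiratory rate, 5 min for skin
temperature; thresholds 0.30, 0.50 for respiration). The centre
sample is excluded from its own window mean so a spike cannot drag the
mean toward itself. Samples with no in-window neighbour are kept;
windows with non-positive mean are flagged and the sample kept
(division would be meaningless). Filtering is not iterated to
convergence — one pass against the range-filtered series.

Range and contextual R-to-R removals are re-filled by linear
interpolation in time between the nearest surviving neighbours;
invalid-code positions stay gaps, and boundary outliers with only one
surviving neighbour are dropped rather than extrapolated. Steps and
posture only undergo sorting/de-duplication and invalid removal.

Self-reported bed/wake clock times: if the naive
previous-evening/same-morning reading implies a sleep duration outside
(0, 16] hours, the bedtime is shifted by 12 h; if still implausible
the pair is marked unusable. The 16-h plausibility bound
operationalizes "implausibly long sleep" and lives in
`CleaningConfig`, not in code.

## Coverage

Sampled channels: clean samples observed / expected at the nominal
rate, capped at 1 (cap absorbs timestamp jitter). R-to-R: summed
interval duration (s) divided by the wear time inside the interval,
where wear sessions split at gaps > 30 min (configurable; the device
itself marks no sessions). Participant-level coverage is the mean of
daily midnight-to-midnight values; partial first/last days are
evaluated against a full-day expectation. PRO coverage counts
responses against the per-item prompt schedule on device-wear days.

## HRV battery

R-to-R segments are corrected to normal-to-normal (NN) intervals with
the Malik rule: scanning in time order, an interval deviating > 20%
from the previous *accepted* interval (not the raw previous one, which
would let slow drifts cascade into acceptance) is replaced by linear
interpolation between the previous accepted interval and the next
acceptable one; trailing intervals with no right anchor are dropped.
Segments with fewer than three intervals are rejected.

Time domain follows the textbook definitions; standard deviations use
the unbiased (n−1) estimator; NN50/NN20 count absolute successive
differences strictly greater than 50/20 ms; heart-rate statistics use
60000/NN (the NN series itself, not the device HR channel, so the
features are internally consistent). Frequency domain: the NN series
is cubic-spline interpolated onto an even 4 Hz grid, linearly
detrended, and analysed by Welch (256-s Hann segments, 50% overlap);
band powers integrate the PSD over VLF 0.003–0.04, LF 0.04–0.15 and
HF 0.15–0.40 Hz; segments shorter than 5 min, or with more than 20%
of the grid inside tachogram gaps (> 5 s between beats), return
missing values. Geometric: triangular index with 1/128-s histogram
bins. Non-linear: SD1 = √(var(Δ)/2), SD2 = √(2·var(NN) − var(Δ)/2)
(same n−1 estimator throughout, which makes SD1² + SD2² = 2·SDNN²
exact), CSI = SD2/SD1, CVI = log10(16·SD1·SD2), and the modified
sympathetic index mCSI = (4·SD2)²/(4·SD1) (longitudinal² /
transverse); since competing definitions of mCSI circulate, the
formula is isolated in one place and easy to swap.

## Windows, L5 and normalization

Aggregates (mean, SD, min, max per signal; the HRV battery; per-channel
coverage) are computed over the half-open 2-h window (t−2h, t]
anchored at the PRO *submission* time, not the slot's nominal time.
An empty window yields missing aggregates and zero coverage.

L5 windows are searched per noon-to-noon day (so nocturnal rest is not
bisected at midnight) at 1-min start resolution: a candidate 5-h
window needs ≤ 100 steps and ≥ 80% lying posture, with the lying
denominator being the posture samples *present* (robust to wear gaps).
Two eligibility guards handle missing data: a candidate must contain
at least half the nominal posture samples, and must lie within the
recorded posture span (1-min slack) — otherwise absent data before or
after the recording would masquerade as perfect rest via the
earliest-start tie-break. Overlapping candidate runs are merged and
the winner maximises lying fraction (ties: fewer steps, then earliest
start); when several disjoint runs exist in one day, the same rule
picks the overall winner.

Normalization, x_norm = (x − µ_L5)/σ_L5, applies to every aggregate
except coverage. For a raw-signal aggregate, µ_L5/σ_L5 are the
sample-level mean/SD of that signal inside the reference L5 window
(one pair per signal, shared by its mean/SD/min/max aggregates). A
window-level HRV feature has no within-window sample spread, so its
µ/σ come from the feature evaluated on five 1-h sub-segments of the
L5 window (mean and n−1 SD over sub-segment values). Variant *a*
references the nearest L5 window ending before the aggregate window
starts and excludes aggregates with no previous window; variant *b*
(the default) references the participant means of µ and of σ over all
L5 windows. σ = 0 leaves the feature missing rather than infinite;
missing features are dropped pairwise downstream, not listwise.

## Association

Repeated-measures correlation in its ANCOVA formulation: within-
participant centring of both variables, common slope b, and
r = sign(b)·√(SS_x/(SS_x + SS_err)) with df = N − k − 1 (N pairs, k
participants); the p-value is the two-sided t-test on that df and the
95% CI is Fisher-z with SE = 1/√(df − 1). The inclusion rules drop
windows with feature coverage below 0.70 (the boundary value 0.70 is
kept) and participants with fewer than three surviving pairs per
feature-PRO cell. Cells are flagged at raw p < 0.05, matching a
screening-style heat map; an optional Benjamini-Hochberg flag is off
by default. A null simulation (20 participants × 6 pairs) reproduces
the nominal type-I rate and CI coverage (see the test suite).

## Heart-rate recovery

Walks are maximal runs of `walking` posture with interruptions up to
3 s bridged, at least 6 min long, with mean cadence (steps per minute
over the bout) ≥ 60 and no upper duration limit. The rest window is
the 60 s starting exactly at the walk's last walking sample (no
latency allowance); it must contain all 15 HR samples expected at
0.25 Hz, zero steps, and no walking posture. HRR is max − min of the
HR samples in that minute; the phrase "maximum HR difference during
rest" is ambiguous, so the alternative reading (HR at rest onset minus
the rest minimum) is available as `definition="onset_minus_min"`, with
max − min the default. The representative value per participant is
the highest HRR (ties: earliest).

Groups are compared with a one-way, two-sided ANCOVA
(hrr ~ group + age + sex, type II sums of squares via statsmodels);
partial η² = SS_term/(SS_term + SS_residual). Tukey contrasts are
computed on covariate-adjusted group means (model predictions at the
covariate means) with the studentized-range distribution on the
residual df, because the omnibus test is covariate-adjusted; plain
observed-means Tukey is available as an option. The fatigue analysis
median-splits each group on mean physical-fatigue score and compares
HRR between halves with Welch's t; groups with fewer than four rated
participants, or a degenerate split, are skipped.

## Synthetic cohort

The generator plants everything the pipeline is supposed to find.
Heart rate is group baseline + β·fatigue + cosinor (default amplitude
8 beats/min, acrophase 16:00) + activity term + slow AR(1) wander,
clipped to the accepted range; skin temperature runs anti-phase
(acrophase 04:00); beats are obtained by integrating the instantaneous
rate (with respiratory ~0.26 Hz and low-frequency ~0.095 Hz
modulation so the tachogram has realistic spectral content) and the
R-to-R value is the exact interbeat gap. The latent fatigue
trajectory is a daily AR(1) around a group-specific level (2.0 healthy
/ 2.33 NDD / 2.39 IMID, the scale of typical chronic-disease cohorts);
PRO responses are the discretized latent value plus noise (SD 0.7),
clipped to 0–6, with slot-level Bernoulli dropout (0.1) and a 5%
chance of a 12-h bedtime entry error. Each day contains a nightly
lying bout (~22:30–06:45, zero steps), one compliant walk
(8–12 min, cadence ~102 steps/min) followed by a seated recovery in
which HR falls by the participant's planted HRR (group base 30
beats/min, shifts 0/−10/−6 for healthy/NDD/IMID, −0.12 beats/min per
year of age, SD 1.5), and two decoy walks that fail the duration or
cadence gate. Wear gaps are one daytime block per day (13:00–22:00)
sized to the configured fraction. Stochastic HR noise is attenuated
(×0.1) inside each planted recovery minute so the planted HRR is a
well-defined ground truth of the emitted signal. Outlier injection
respects the class definitions (sentinel codes; values pushed outside
the accepted range; in-range values scaled ~1.8× to violate the
sliding-window criterion while staying in range — impossible for skin
temperature, whose ±30% band exceeds its accepted range, so skin-T
contextual injections are skipped and reported as such) and spaces
injections at least one contextual window apart so they do not mask
each other. Per-participant RNG streams are keyed by (seed, group,
index), so one participant's data never depends on another's or on
group sizes.

What the generator does **not** emulate: real accelerometry and
posture-classifier errors, ectopic-beat morphology (Malik correction
is exercised mainly by injected/contextual outliers), motion-dependent
respiratory artefacts, ambient-temperature effects on skin T,
between-slot PRO dynamics beyond the daily latent level, and
informative missingness (gaps and dropout are random). Passing tests
therefore demonstrate that the implementation recovers what it is
specified to recover under a plausible physiology, not that the
device's real artefact spectrum is handled.

## Problem sizes and defaults

The demo configuration runs 9 participants × 5 days; the acceptance
script uses 30 participants × 4 days; statistical calibration tests
use 1,000 null replicates (rmcorr: 20 participants × 6 pairs; ANCOVA:
3 × 20 with σ = 5) and 500/200 replicates for CI coverage and power.
These sizes give stable Monte-Carlo estimates at interactive runtimes.
Known limitations: daily (not slot-level) latent fatigue bounds the
within-participant correlation near |r| ≈ 0.2–0.3 at realistic noise
— the magnitude such studies report — so small cohorts recover its
sign but not always its significance; single-seed demo runs should be
read accordingly.
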