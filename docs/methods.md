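# Methods

This note documents the models, conventions and design choices behind
`infermap`.  The package analyzes multi-day sensory-preconditioning
("inference") sessions: spike trains from chronically recorded hippocampal
units, a trial table of cue events, a 25 Hz position trace, and optionally
a wide-band LFP pair for ripple detection.  Everything is exercised on a
synthetic-session generator with planted ground truth; the last section
states what passing those benchmarks does and does not establish.

## Conventions

All times are seconds on a single session clock; intervals are half-open
`[start, end)`.  Speed is the backward-difference step length of the
position trace divided by the frame period (40 ms at 25 Hz), so each sample
reports how fast the animal moved *into* its position — this makes the last
sample of a planted pause the last sub-threshold sample, aligning measured
decision points with planted ones to one frame.  Sets: set 1 cues predict
reward, set 2 cues a neutral outcome.

## Behavior

**Decision point.**  The latest time in a trial at which speed < 5 cm/s
before the animal first *enters* the outcome-area polygon.  Entry is an
outside→inside transition; a trial that begins with the animal already
inside the area (e.g. an outcome-delivery window reached by an anticipatory
approach) has no entry and is kept whole.  Three outcomes per trial: a
time (censor bins after it), `None` (no entry — keep the whole trial), or
`nan` (entry without a prior sub-threshold sample — exclude the trial from
filtered analyses; the count is logged).  A visit to the area is counted
from the first position sample inside the polygon; single-sample dwells
count.

**Reward-seeking bias.**  Per day, set 1 minus set 2 of: percent time in
the outcome area during the 20 s after auditory-cue offset (inference
test); percent time in the area during the visual cue before outcome
delivery (conditioning); percent of trials with any visit; or lick rate.
Percent measures are bounded in [0, 100], biases in [−100, 100].

**Effect sizes.**  Group differences are reported as the mean difference
with its bootstrap sampling distribution and a bias-corrected-and-
accelerated (BCa) 95% interval (10,000 resamples by default), the
estimation-statistics convention.  The interval computation is delegated to
`scipy.stats.bootstrap(method="BCa")`; paired designs resample
index-aligned pairs.  Identical degenerate groups yield a point interval
with a `degenerate` flag.

## Cue ensembles

Rates are counted in 100 ms bins spanning each trial, censored at the
decision point, converted to Hz and Z-scored per unit across all included
bins of the fitted period (the normalization window is all
decision-filtered bins — a convention, chosen so trials stay comparable
within a day; zero-variance units are flagged and excluded downstream).
Trial-averaged Z rates are regressed by OLS on six cue indicators plus the
standardized mean trial speed.  Because each trial presents exactly one
cue, the indicators span the intercept and no intercept is fitted; in a
balanced design with constant speed each cue weight equals the per-cue mean
response (the oracle equivalence used in the tests).  A constant speed
regressor is dropped rather than kept as a zero column.  OLS (not Poisson)
is appropriate because the response is already a Z-scored rate.

A unit joins the ensemble of cue *c* when its weight exceeds the cross-unit
mean by 2 sample standard deviations and is positive.  Ensemble assignment
is invariant to positive affine rescaling of a cue's weights.  Units
belonging to more than one ensemble are retained in summaries but excluded
from SWR tuple construction, so each tuple member represents one cue
non-overlappingly.  Ensembles are fitted per day by passing `day=`, or
pooled (the default used for the multi-day SWR analyses, since the
generator's tuning is stationary; with real drifting ensembles the per-day
fit is the safer choice).

**Performance regression.**  For each 100 ms bin in a ±15 s peristimulus
window around auditory-cue onset, each unit's Z rate across inference-test
trials is regressed on the correct(1)/incorrect(0) flag with trial speed
and cue set as covariates; the per-bin average weight across units is
tested with a one-sample t-test across units.  Days lacking one of the two
outcomes are dropped with a warning.  Calibration caveats: the t-test is
slightly heavy-tailed when few units are recorded (low-count weights are
skewed; with ~100 units the empirical per-bin false-positive rate is
≈ 0.056 at α = 0.05), and trials must be spaced beyond the window length or
overlapping windows correlate observations.

## Representational similarity

Population vectors are per-condition means of the included Z-scored bins
(one entry per unit; trials weighted equally; bins overlapping SWRs can be
excluded; conditions without included bins and constant feature rows are
dropped with a log message).  The cross-stage RSM correlates test-stage
patterns (auditory cues in the inference test, decision-point filtered,
split by correctness) with training-stage patterns (visual or outcome cues
in conditioning): rows and columns index different condition sets, so the
matrix is not symmetric.  The association map (X1→Y1, X2→Y2, or X→Z) marks
"within" cells; the statistic is mean(within) − mean(between), which is
invariant to adding a constant to every cell.  Correlations need ≥ 3 shared
features.

Group inference runs two ways: (1) a one-sided Wilcoxon signed-rank test
across days/subjects (exact for n ≤ 25 without ties); (2) a permutation
test that permutes the identities of the *test-stage* labels within each
day independently, re-averages across days, and uses the add-one rule
p = (1 + #{null ≥ observed}) / (1 + n_perm).  With only two auditory cues a
single permutation shared across days would admit just two null values;
the per-day scheme yields 2^days sign patterns and a usable null
resolution.  For label sets of ≤ 5 the statistic is pre-evaluated for every
distinct permutation and the null assembled by index sampling — the same
distribution, much faster.  Model-RSM regression Z-scores the vectorized
cells (optionally Fisher-transformed; the transform is on by default for
model regression and off for the neuron-pipeline averaging, where the
original analysis averages raw r) and regresses them on the vectorized
model matrices plus an intercept; collinear models raise with the design's
condition number.

## Spike timing

For a directed (trigger, target) pair, both trains restricted to the
relevant cue windows, target spikes are histogrammed in 1 ms lag bins over
±100 ms around every trigger spike.  Joint probability per bin is the mean
target count per contributing trigger; the correlogram reports its change
from the mean over the 50 ms pre-trigger baseline.  Triggers within 100 ms
of a cue-window edge keep a truncated window and each bin is normalized by
the number of triggers whose window covers that bin — this removes edge
bias and makes counts exactly equal to a double-loop oracle.  The STA is
the per-bin rate Z-scored against the mean/SD of the same STA's 200 bins
(the parsimonious reading; a Poisson-expectation alternative is available
as `zscore="poisson"`, and the asymmetry conclusions on synthetic data do
not depend on the choice).  Pairs whose target fires < 20 spikes across all
trigger windows are returned with `included=False`, never silently
dropped.  The 5 ms moving average is display-only.  The after-minus-before
asymmetry (mean Z over (0, +100] minus [−100, 0)) flips sign exactly under
time reversal; its group effect uses the same BCa bootstrap as the
behavioral effects.

## Sharp-wave/ripples

Detection: 4th-order Butterworth band-pass (135–250 Hz, zero-phase) of the
detection channel minus the band-passed reference (the subtraction cancels
common-mode noise; filtering and subtraction commute), RMS envelope in a
20 ms window, background mean/SD over immobility samples (speed
< 1.5 cm/s) only.  Events are envelope excursions above mean + 7 SD during
immobility, extended to the 2 SD crossings, merged when closer than 10 ms,
and dropped when shorter than 20 ms.  The 7 SD and 2 SD thresholds and the
immobility criterion follow the standard pipeline; the minimum-duration,
merge-gap and RMS-window values are field-standard conventions exposed as
parameters.  Detection is invariant to uniform amplitude scaling because
all thresholds are in SD units.

Coactivation of a tuple across SWRs: `p̂ = (n/N)/f̄` with `n` the SWRs of
the epoch in which every member fired (optionally only SWRs where no
excluded-ensemble unit fired — the "in absence of Yn" doublet variant),
`N` all SWRs of the epoch, and `f̄` the mean of the members' mean firing
rates over that epoch's recording days (whole-day rates by default;
task-epoch rates via `scope="task"`).  Early = days 1–4, late = days 5–8.
Tuples never coactive in any SWR, or with a zero-rate member, are skipped
and logged.  Awake-rest and sleep-box events carry a context label and are
analyzed separately.

Group statistics: BCa bootstrap of the mean `p̂_diff = p̂_late − p̂_early`
per set; a set × day-epoch two-way ANOVA on per-tuple p̂ values with
Tukey HSD post hoc contrasts (statsmodels); an optional permutation-F
alternative (group labels permuted) for users unwilling to assume ANOVA
residual normality.  A caveat inherent to the design (shared with the
original analysis): tuples drawn from the same ensembles share SWR events,
so per-tuple observations are not independent and between-tuple variance
understates the sampling noise of epoch-level counts — a planted *flat*
schedule can still show a small but "significant" within-set contrast.
The package therefore judges flatness of a control set by effect magnitude
relative to the planted set, not by the within-set test alone.

The X-shuffle control reassigns, within each epoch, which SWRs contain the
X unit's spikes (count preserved, so both units' rates are preserved)
while holding Z participation fixed, and recomputes the early→late change
in joint probability; one-sided add-one p.  A unit firing in every SWR
makes the null a point mass and is flagged.  First-spike order: per SWR in
which both units fire, Δt = t_first(Z) − t_first(X); exact ties are
dropped and counted; the fraction of pairs with median Δt < 0 is tested
against 0.5 with a two-sided binomial test (Bonferroni α = 0.025 when both
sets are tested).

## Synthetic sessions

Each day is laid out as: sleep/rest block — reconditioning (Yn 8 s → Zn
10 s) — inference-test blocks (Xn 10 s + 20 s reward-seeking window)
interleaved with awake-rest gaps — observational re-exposure — sleep/rest
block.  Spike trains are inhomogeneous Poisson generated by thinning
(exact and seedable): rate = baseline × (1 + gain during the preferred
cue) + coupling × speed.  Baselines are lognormal clipped to 0.5–5 Hz (a
convention — per-unit rate distributions are not calibrated to any
dataset); the tuned fraction assigns non-overlapping preferred cues.

The position model is a piecewise-linear waypoint walk: wandering hops at
6–15 cm/s that never cross the outcome area, stationary rest blocks, and
scripted dispenser visits — a sub-5 cm/s pause of 0.6 s (the planted
decision point) followed by a 12 cm/s approach entering the area at a
scheduled time, a dwell calibrated to the configured occupancy (defaults:
expected 30% of the post-cue window for set 1, 10% for set 2), and an
exit.  Licking is Poisson at 7 Hz while dwelling at the dispenser.  A
trial is labelled correct when visiting matches the rewarded set.

Ripples are planted in rest epochs as Poisson events (0.3 /s, 60 ms);
configured coactivation sets participate per event with an early/late
probability schedule, each participant receiving one injected spike at a
uniform time — or in a fixed order with a configured lag, which makes
first-spike ground truth controllable.  Millisecond cue lags are planted
by echoing trigger spikes into a target unit at a fixed lag (±0.2 ms
jitter) during auditory cues, by default only on correct inference trials
(so pattern similarity appears on correct trials only).  The LFP is pink
noise plus a shared common-mode channel and, inside each true ripple, a
Hann-windowed 180 Hz burst at SNR × background RMS; the reference channel
carries the common mode but no bursts.  Spike times are rounded to 0.1 ms;
position is 25 Hz; LFP 1 kHz (sufficient for a 250 Hz band at desk scale).
All randomness derives from named child streams of one seed;
equal seed and config give byte-identical sessions.

What the generator does *not* emulate: spatially tuned (place-field)
firing, bursting/refractory spike statistics, ensemble drift across days,
theta or other non-ripple LFP structure, behavioral extinction, and
multi-region interactions.  Passing the benchmarks therefore shows the
analysis chain is correct and calibrated under Poisson-like firing with
the planted effect structure — not that it is robust to every property of
real recordings.

## Benchmark problem sizes

Chosen for single-CPU desk scale and stated here as the package's own
conditions: ensemble recovery uses the reference condition (100 units, 8
planted per cue, gain 5, 50 trials/cue) over a 100-seed bank in the test
suite (40 seeds in the reproduction script); lag recovery ~10 sessions × 10
planted pairs; ripple detection ~500 planted events at SNR 10; RSA null
calibration 500 runs at n_perm = 1000; performance-GLM calibration 100
shuffles pooled over 10 sessions; first-spike and ANOVA nulls 150–200 runs;
pattern reproduction uses a 75-unit, 8-day session (~6 units per ensemble,
coactivation 0.02 → 0.10 for set 1, flat 0.02 for set 2, 2 ms
reversed-order lags).

## Known limitations

* The per-tuple pseudo-replication noted above.
* The per-bin performance t-test is mildly anticonservative for small unit
  counts (see above).
* The cue GLM assumes a single response level per cue per trial; it does
  not model within-trial dynamics (the peristimulus regression does).
* `nan`-decision trials are excluded rather than partially censored; with
  pathological tracking this can discard many trials (the count is logged).
* BCa intervals can degenerate when the jackknife variance vanishes; such
  estimates are flagged rather than silently widened.
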