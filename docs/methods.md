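# Methods

## Scope

`actisleep` implements a desk-scale analysis pipeline for objective
toddler sleep measurement: accelerometer epoching, linear sleep/wake
scoring, night-level parameter extraction, caregiver-diary parameters,
and diary-vs-actigraphy agreement statistics, together with a synthetic
cohort generator that stands in for device data.  It does not model
sleep physiology (stages, circadian dynamics), alternative published
scoring algorithms (Sadeh, Cole–Kripke), or daytime naps.

## Epoching and the intensity scale

Raw acceleration magnitudes sampled at a fixed 0.125 s period are binned
into 2-minute windows (960 samples); the *activity value* of a window is
the number of samples **strictly** exceeding a configurable reference
threshold.  The device units and threshold magnitude of real hardware
are not public, so the threshold is an explicit parameter with an
arbitrary default of 1.0 device unit.  The activity-value → intensity
compression is likewise not public; the default is linear,
`floor(value / 15)` clipped to [0, 63] (15 = ⌈960/64⌉, so a fully
active window spans the whole 64-level range), with the divisor
configurable.  This mapping is a declared choice, not an inference about
real firmware; it is monotone, sends 0 → 0 and saturates at 63, which is
all the downstream scorer relies on.  Epochs are aligned to the series
start time; no clock-boundary snapping is applied.

## Sleep/wake scoring

Each epoch is scored from the five-epoch window centred on it:

z = 0.24669·x₋₂ + 0.2562·x₋₁ + 0.408771·x + 0.155046·x₊₁ + 0.136728·x₊₂,

wake iff z ≥ 1 (threshold configurable, boundary inclusive).  All
coefficients are positive, so z is strictly monotone in every input; z
is computed in double precision on integer inputs and reported to six
decimals in file output.  The first and last two epochs of a series have
no full window; by default they are labelled *undefined* and carry NaN z
(nothing is fabricated), with an optional edge-replication padding mode
for users who need every epoch labelled.

**Onset/offset.**  The sources this scorer descends from determined
wake and sleep times manually; an automated, parameterised stand-in is
used here: sleep onset is the start of the first run of at least
`sustained_epochs` (default 5 = 10 min, a common actigraphy convention)
consecutive sleep epochs inside the night window, and the final waking
is the end of the last such run.  A qualifying run touching the window
end means sleep continued past the analysed night and is reported as an
error.  A night with no qualifying run raises a no-sleep error; no
partial summary is emitted.

**Night-time sleep** is 2 min × (sleep epochs between onset and final
waking) — intra-night wake epochs are excluded, so the value is bounded
by the elapsed span and satisfies the conservation identity
sleep + 2·(wake epochs in span) = elapsed minutes.  Whether real
analyses exclude intra-night wake is not always stated; the exclusion is
a documented definition here.

**Awakenings** are maximal wake runs of ≥ 3 epochs (≥ 6 min; a 6-min
run counts) between onset and final waking.  Undefined labels inside the
analysed span are refused by default (`error`), or may be recoded as
sleep or wake explicitly.

The actigraphy "bedtime" reported in summaries is the detected sleep
onset: a movement sensor cannot distinguish lying quietly in bed from
pre-bed quiet wakefulness, so onset is the honest proxy, and the
diary–actigraphy bedtime comparison inherits the true sleep-onset
latency as a systematic component.

## Diary parameters

A night is keyed to its bedtime's calendar date; all clock quantities
are unrolled onto a minutes-since-noon axis (21:00 → 540, 06:30 next
morning → 1110), which makes cross-midnight spans monotone and clock
means meaningful (mean of 23:50 and 00:10 is 00:00).  Diary night-time
sleep is the bed-to-wake span minus the reported sleep-onset latency
(integer minutes); latency exceeding the span is a validation error.
Reported awakenings are copied verbatim — they are the caregiver's count
of episodes longer than about five minutes, not a re-derivation.
Lifestyle fields (nap, screen, outdoor, bath, dinner, pre-bed activity,
caregiver sleep, stress) are carried through I/O losslessly but not
analysed.  Weekend nights are, by default, those whose bedtime falls on
Saturday or Sunday (configurable rule).

## Agreement statistics

Nights are first averaged within participant (per source, measure,
month, optional weekday/weekend stratum; sample n−1 SD; a single night
leaves the SD undefined rather than silently zero).  The two sources are
then compared across participants with a two-tailed paired t test,
t = mean(d)/(sd(d)/√n), df = n−1, implemented from the formula (the
p value uses the t distribution from `scipy.stats`).  Zero-variance
differences degenerate to t = 0, p = 1 (identical pairs) or t = ±∞,
p = 0.  Participants missing one source are dropped with their count
reported, so df shrinks by exactly one per dropped child.

Pearson correlations between the sources are computed, by default, over
pooled child-nights matched by night date: with ~10 participants,
participant-level correlations cannot resolve the magnitudes of
interest, while ~80–160 pooled nights can.  Participant-level pooling is
available as an option; the choice is recorded in each result.  r is
the product-moment formula with a two-tailed t-transform p value;
constant inputs raise an error at the statistic level, and the
experiment driver records NaN for a degenerate measure (e.g. zero
awakenings everywhere in a noise-free run).  No multiple-testing
correction is applied — the analysis mirrors small-cohort agreement
practice where each measure is read on its own.

## The synthetic cohort

The generator emulates the study design end to end with three layers,
all driven by one global seed that fans out to per-stage, per-child,
per-night substreams (partial re-renders are reproducible).

**Ground truth.**  10 children × 8 consecutive nights (starting a
Monday, so each block holds one Saturday and one Sunday night) × 2
months.  Bedtime = 21:00 + child habit (SD 25 min) + nightly variation
(SD 27 min) — cohort spread ≈ 37 min; wake-up = 06:30 + habit (SD 15)
+ nightly (SD 20) + a 15-min weekend lie-in.  True sleep-onset latency
averages 5 min (toddlers settle quickly once lights are out; the large
latencies parents report are part of the reporting model below).  True
awakenings are Poisson (mean 1.5/night) with shifted-exponential
durations (2 min minimum + mean 6 min extra — so the diary's >5-min and
the scorer's ≥6-min thresholds bite differently), placed uniformly
without overlap inside the sleep interval.

**Movement.**  Wake spans draw intensities ≈ N(35, 10) clipped to
[5, 63]; sleep is intensity 0 except for Poisson-placed single-epoch
motor bursts (1.0/h, intensity ≈ N(20, 8)).  Because the scoring window
spans five epochs, one burst epoch of intensity ≥ 8 drags its four
neighbours over the z ≥ 1 threshold, producing a ≥ 6-min scored
awakening — this is the mechanism by which actigraphy over-counts
awakenings in motorically restless sleepers, and it yields ≈ 8.5–9
scored awakenings and ≈ 455–465 min scored sleep per night.

**Diary noise.**  Reported clocks are truth + per-caregiver offset +
nightly Gaussian error, rounded to 5 min: bedtime bias +13 min (the
entry is logged after the settling routine ends) with small errors
(child SD 10, nightly SD 10); wake-up bias −8 min (caregivers tend to
log the child's first morning stirring, while the scorer, conversely,
trims the final waking a few minutes early) with much larger nightly
error (SD 35).  Reported latency is truth + 15 min (parents
over-estimate settling time), so diary night-time sleep lands near
550 min.  Reported awakenings are a binomial thinning of the > 5-min
true events with notice probability 0.45, giving ≈ 0.4 reported
awakenings per night.

**Calibration, not validation.**  These defaults were set so the
synthetic cohort reproduces the qualitative agreement pattern of
published toddler diary-vs-actigraphy comparisons — clock times agreeing
within minutes with non-significant paired tests, diaries over-crediting
sleep by roughly 1.5–2 h, diaries missing ~95% of scored awakenings, and
bedtime correlating more strongly than wake-up — and the calibration was
checked on seed blocks disjoint from any test seeds.  Passing tests
therefore show the pipeline is internally consistent and recovers known
truth; they do not validate the movement or reporting models against
real families, nor identify the true awakening frequency of toddlers
(which diaries and actigraphy bracket from opposite sides by design).
The generator also omits real-data features such as naps inside the
night window, device non-wear, artefactual spikes, and night-to-night
dependence, so real recordings should be expected to be messier than the
synthetic ones.

## Numerical and design choices

- **Wake-epoch spillover.**  A wake span of intensity W leaks
  0.50289·W and 0.24669·W into the first two sleep epochs after a
  transition, so under daytime-level W (≥ 5) the detected onset lags the
  gridded truth by up to two epochs and the detected final waking leads
  it.  The noise-free recovery experiments therefore use the
  `MovementModel.noiseless()` preset (constant quiet-wake intensity 3),
  for which spillover beyond one epoch stays below threshold; recovery
  is asserted against the epoch-gridded truth, since sub-epoch timing is
  unobservable at 2-minute resolution.  Recovery experiments report a
  maximum onset error ≤ 4 min (one epoch of gridding + one of lag) and
  offset error ≤ 2 min.
- **Problem sizes.**  Recovery uses 10 children × 8 nights; robustness
  sweeps use 50 independent replicates of the full default cohort; the
  statistics oracles use 100 random paired datasets and the classifier/
  event oracles 1,000 random series — sizes at which every check runs in
  seconds while estimates are stable.
- **Strictness.**  Intensity CSVs must be contiguous per child (gaps are
  reported with their missing spans, never bridged); diary times are
  strict HH:MM with row-numbered errors; all validation happens before
  any computation, and the CLI distinguishes validation (exit 1) from
  runtime (exit 2) failures.
- **Determinism.**  Identical config + seed reproduces every artifact
  byte for byte; the pipeline manifest records the package version,
  seed, and all parameter values.

## Known limitations

The onset/offset rule is a declared convention, not a reimplementation
of any manual scoring procedure; the intensity compression is a declared
stand-in for undocumented firmware; clock-time SDs are aggregated on the
minutes-since-noon axis (real reports sometimes print H:MM SDs whose
aggregation axis is unknown); and the agreement analysis assumes one
night window per series (18:00–10:00 in simulation) with no nap scoring.
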