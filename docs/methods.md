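# Methods

## Data model

A recording is a time-ordered sequence of annotated beats — sinus (`N`) or
premature ventricular complex (`V`) — with timestamps in seconds from
record start, plus a noise mask of discarded segments.  All windows are
half-open `[start, end)`, so a beat on a boundary belongs to exactly one
window.  The noise mask consists of non-overlapping 30-second segments
aligned to the record-start grid (free-form masks are rejected at load);
beats inside masked segments are dropped at load time with a logged count.
Whether the 30-s grid should be anchored to clock time or to record start
is not observable from the data we model; we anchor to record start, and
the same anchor is used for interval segmentation and 24-hour sections.

Annotation labels other than N/V (artifact and rhythm codes in WFDB-style
exports) are dropped and counted: the analysis concerns only the sinus/PVC
dichotomy.

## Interval metrics

Records are segmented into consecutive intervals of 1 hour, 10 minutes, or
1 minute.  Per interval:

* `mean_hr = 60 * n_beats / valid_seconds` — **all** beats count, sinus and
  PVC.  Under the blocked-compensatory-pause assumption every PVC replaces
  exactly one sinus beat, so total beat rate equals the underlying sinus
  rate; this choice makes the measured HR agree with the HR entering the
  analytical rate law (below).
* `pvc_per_hour = pvc_count * 3600 / valid_seconds` — the hourly-scaled
  PVC count used on every scatter axis, making interval durations
  comparable.
* An interval is *valid* when its un-masked fraction reaches a threshold
  (default 0.5) and it contains beats.  Counts in partially-masked
  intervals are rescaled by valid time rather than discarded; setting the
  threshold to 1.0 reproduces the drop-partial behaviour, so both readings
  of "noisy segments were excluded" are available.

Heart-rate aggregation assigns valid minutes to integer-bpm bins by
round-half-even (deterministic, unbiased at .5 boundaries) and emits a bin
only when **strictly more than 10** minutes fall in it, with rate
`60 × mean(per-minute PVC count)` — at most one point per heart rate.

On the log-linear scale the regression uses `log10(pvc_per_hour)`;
zero-count intervals are undefined there and are dropped, with the dropped
count carried into the result because it changes `n` and hence the
p-value.

24-hour sections are anchored at record start.  A trailing partial section
is flagged and excluded from per-day classification by default; a section
must contain at least 10 valid intervals to be classified (the regression
needs degrees of freedom; both knobs are configuration).

## Classification

Pearson `r = Cov(X,Y)/(σX σY)` and OLS slope `B = Cov(X,Y)/σX²` are
computed with the sample (n−1) convention (the ratios are
convention-independent); the p-value is the two-sided Wald test with
`t = r√(n−2)/√(1−r²)` on `n−2` df.  Labels: positive (`r>0, p<.05`),
negative (`r<0, p<.05`), neutral (`p≥.05`).  The boundary atom `p = .05`
is assigned to neutral — the conservative completion of a rule whose
strict inequalities leave it uncovered.  Degenerate sections (fewer than 3
points, zero variance — e.g. a day with no PVCs at all) yield an explicit
UNUSABLE result with a reason, never a silent neutral.

Regression on aggregated bins is unweighted (one bin, one point); a
minute-count-weighted variant was considered and rejected as default
because the aggregated methodology's defining property is "at most one
data point per heart rate".

## Consistency metrics

The daily label list (usable days only; UNUSABLE days are omitted, keeping
the class set at exactly three) is summarised by:

* normalized Shannon entropy `H = −Σ p(c) log2 p(c) / log2 3`, with
  `0·log 0 = 0`.  The divisor is `log2 3` — the entropy of the uniform
  three-class distribution — irrespective of the day count.  For day
  counts not divisible by 3 the attainable maximum is below 1 (for 7 days,
  the most even split 2/2/3 gives 0.98214); `normalize="max_attainable"`
  divides by that attainable maximum instead, for sensitivity analysis.
  Entropy is exactly 0.0 (not merely small) for a one-class list, so
  zero-entropy fractions use exact comparison safely.
* pairwise agreement `Σc C(nc,2) / C(n,2)` — the probability that two
  *distinct* 24-hour sections agree, i.e. sampling without replacement.
* ternary coordinates (fraction positive, negative, neutral), a point on
  the 2-simplex for the classification-set density plots.

## NIB rhythms

The NIB of a consecutive PVC pair is the number of sinus beats strictly
between them.  Per minute: `no_pvc` (zero PVCs), `fixed_nib` (at least two
NIB values, all equal), `mixed` (unequal values), `insufficient` (one or
two PVCs — fewer than two NIB values cannot evidence repetition, so such
minutes are neither stable nor mixed).  NIB pairs are confined to a single
minute and never span noise-masked gaps: missing beats make the
intervening count undefined.  Stable NIB-k minutes are compared against
the analytical law `PVCs/min = HR/(k+1)`, which follows from one PVC per
`k+1` beat slots when each PVC blocks the following sinus beat; for
bigeminy (k = 1) the law has slope 0.5 PVCs per minute per bpm.

## Synthetic generator

The generator exists because the multi-day Holter recordings behind this
kind of analysis are individual patient health data; it produces records
whose generating mechanism — hence whose true PVC-HR relationship — is
known, so every downstream stage can be validated against ground truth.

**Sinus clock.** Instantaneous heart rate is precomputed on a 1-second
grid: a circadian cosine (default base 75 bpm, amplitude ±15 bpm, peak at
15:00 from record start) plus AR(1) jitter on a 1-minute grid (default sd
3 bpm, correlation time 10 min), clamped at 30 bpm.  Beats are emitted
event by event with period `60/HR(t)`.  Defaults emulate the 40–120 bpm
circadian range and minute-scale HR fluctuation of ambulatory recordings.
An explicit linear-ramp profile exists for controlled sweeps (slope
recovery, parasystole direction), and a record may carry one profile per
day for day-flip experiments.

**Mechanisms.** Every expressed PVC is placed a coupling interval
(default 0.45 s) after its preceding sinus beat and suppresses the next
scheduled sinus beat; interpolated PVCs (no blocked beat) are not
generated, matching their rarity in practice.

* `FIXED_NIB k`: a PVC after every k-th expressed sinus beat — the stable
  rhythm, rate `HR/(k+1)`, burden `1/(k+1)`.
* `LOGISTIC_HR`: after each expressed sinus beat a PVC follows with
  probability `p(HR) = logistic(intercept + slope·HR)`.  Because each PVC
  occupies one blocked slot, the expected rate is `HR·p/(1+p)` per minute,
  not `HR·p` — the blocked-pause correction matters at high burden.  Note
  that even at slope 0 the *rate per minute* rises with HR (more beats per
  minute, same per-beat probability); a negative per-beat slope must
  exceed the cancellation point `≈ (1+p)/HR` in magnitude before the net
  rate-HR dependence turns negative.
* `HUMP_HR`: Gaussian per-beat probability peaking at a configurable HR —
  the inverted-parabola phenomenology whose linear classification flips
  sign with the day's HR range.
* `PURE_PARASYSTOLE`: an ectopic clock of fixed period, unreset by sinus
  activity; a firing is expressed iff the time since the last expressed
  beat exceeds the refractory parameter, and expressed PVCs block the next
  sinus beat.  The non-refractory fraction `1 − refractory·HR/60` falls
  with HR, so the mechanism generates a negative PVC-HR correlation; no
  closed-form rate is exposed — the expected-rate helper returns a
  constant-HR simulation estimate flagged as simulated.

Noise dropouts are Bernoulli per 30-s segment (default probability 0.01 in
the cohort preset).  A seed fully determines a record; identical specs
give byte-identical CSVs.

**Cohort preset.** 48 records (two days each by default) cycling through
the four mechanisms with deterministic parameter grids chosen so attained
PVC burdens span roughly 1%–44%: fixed-NIB k ∈ {2…99} covers 33% down to
1%, and logistic mechanisms with per-beat probabilities up to ~0.8 at the
circadian midpoint reach ~44% (`p/(1+p)`).  Circadian parameters are drawn
per record from ranges typical of ambulatory adults (base 62–88 bpm,
amplitude 8–18 bpm).

**What the generator does not emulate** — and therefore what passing tests
do not show about real data: beat-detection error, PVC morphology classes,
modulated (phase-reset) parasystole, interpolated PVCs, rate-dependent
coupling intervals, atrial arrhythmia, and non-stationary mechanism
switching within a day.  Tests on synthetic cohorts validate the *method's
behaviour under known mechanisms*, not clinical prevalences; cohort-level
proportions reported in clinical studies depend on their patient mix and
are not reproducible from simulation.

## Problem sizes and numerical choices

The test suite and the acceptance script run on desk-scale problems chosen
to make each property measurable with margin: 4-hour ramps (240 minutes)
for slope recovery, 20 seeded replicates for stochastic sign-recovery
claims (pass bar 19/20), 2-day records for day-flip and methodology-shift
experiments, and a 7-day record for the entropy floor.  Tolerances: slope
0.5 ± 0.02 (minute-boundary effects on a finite ramp), brute-force oracle
agreement at 1e-12 (pure floating-point reorderings), entropy floor exact.
Ties in HR binning break half-to-even; `|r| = 1` maps to p = 0 explicitly;
empty inputs raise rather than return sentinels.
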