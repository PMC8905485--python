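# Methods

This note documents the statistical procedures implemented in `sleepspan`,
the defaults they ship with, the model behind the synthetic cohort
generator, and the limits of what the test suite demonstrates.

## Night scoring

A night is a per-minute stage sequence over one in-bed interval
(WAKE/LIGHT/DEEP/REM; minute 0 = bed entry).  Scoring rules:

* **Sleep onset** = first non-WAKE minute.  Devices may require N
  consecutive sleep minutes before declaring onset; the threshold is
  unknown for the reference hardware, so the simplest rule is the default
  and `onset_run_min` makes it configurable.
* **Final wake** = the minute after the last non-WAKE minute (half-open
  intervals throughout).
* **TST** spans onset → final wake and therefore *includes* intra-sleep
  wake; consequently `deep + rem + light ≤ tst` holds exactly at scoring
  and is enforced (with a one-minute rounding tolerance) at data
  validation.
* **Awakenings** = maximal WAKE runs strictly inside the sleep period, any
  length ≥ 1 minute (`min_awakening_min` configurable, same rationale).
* **Sleep midtime** = clock time of the midpoint of the onset→wake
  interval, wrapping midnight.  A night is keyed by the calendar date of
  the evening of sleep onset, which keeps the night of a clock change
  unambiguous.

Circular statistics use the resultant-vector definitions on the
1440-minute circle: mean = direction of the mean resultant, SD =
`sqrt(-2 ln R)` rescaled to minutes.  A zero resultant raises rather than
returning an arbitrary direction.

Outside the explicitly circular summaries, sleep midtime is *linearized*
as minutes after 18:00 before averaging or testing.  Midtimes concentrate
deep in the night, far from the 18:00 cut, so ordinary statistics are safe
on the unfolded scale; results are folded back to clock time for
reporting.  A circular two-sample test (Watson–Williams) was deliberately
left out of scope.

## Variability and measurement-duration sufficiency

All windows are **calendar** windows; a missing night reduces the
observation count instead of stretching the window (available-case SDs).
How the reference analysis handled missing nights is not stated; this
choice is ours, with a floor `min_obs` (default 5 of 7 for the rolling
window) below which the window is reported missing.  Sample SDs use the
n−1 denominator everywhere; midtime routes to the circular SD.

* **Rolling SD**: trailing 7-day window, stepped one day at a time,
  emitted once a full window has elapsed.
* **Cumulative SD**: expanding windows anchored at the first observation
  (by default the first days of October), lengths 3, 4, …, 83 days.
* **Stabilization day**: smallest window length L such that every
  consecutive pair of lengths in [L, L+hold] changes by less than
  `rel_tol` relative to the earlier value, with `ε = 1e-9` guarding
  zero-SD stretches.  Defaults `rel_tol = 0.05`, `hold = 14` days.  The
  flattening of the cumulative-SD curve is usually judged by eye; this
  rule makes the judgement explicit and testable.

A calibration fact worth knowing: for i.i.d. Gaussian noise the relative
step of the expanding-window SD at size n behaves like |z²−1|/(2n), so a
14-pair quiet run starting as early as L = 14 still succeeds with
probability near 0.3.  On stationary series the stabilization day
therefore exceeds 14 days in roughly three quarters of replicates (median
≈ 20 days), not in nearly all of them.  Only drifting or serially
correlated noise — which the generator deliberately does not include —
pushes that fraction higher.  `scripts/acceptance.py` reports the measured
fraction.

* **Weekly summaries**: calendar weeks (Mon–Sun) with ≥ `min_days`
  observations; normalization divides by the participant's maximum over
  the whole collection period (so nonnegative variables land in [0, 1]);
  midtime gets circular weekly statistics and no normalized value.
* **Daily cohort stats**: per-date cross-participant mean/SD plus a
  centered moving-average smoother (default 14 days) — a deliberate,
  documented stand-in for a local-polynomial fit, used for display only
  and never in statistics.

## Clustering

Features are per-participant means of the 11 variables over a trailing
window (weeks back from the trial end, so staggered enrollment and
seasonality do not distort the comparison), z-scored per column.
Standardization is a consequential choice: unscaled Euclidean distance
would be dominated by step counts (~5000) against hours (~7).  Columns
whose spread is at floating-point rounding level are treated as degenerate
and standardized to zeros rather than having rounding noise inflated to
unit variance.

K-means (scikit-learn, 10 restarts, fixed seed) supplies the partitions.
The elbow statistic is the ratio of the mean within-cluster distance to
the mean between-center distance; for K = 1 the between term is absent and
the within dispersion itself is recorded.  `select_k` maximizes the second
difference of the **log** ratio: log-curvature is scale-free and keeps the
differently-scaled K=1 entry from dominating, and it reproduces the
intended choice on both reference shapes (a 10/4/3.8/3.7 curve elbows at
2; three well-separated clouds elbow at 3).  A curve with no positive
log-curvature has no elbow and returns the smallest K with a warning.

Clusters below `min_size` (default 8, ≈ 15 % of a 54-person cohort,
motivated by the reference analysis discarding a 6-member cluster) are
excluded from contrasts; members are flagged unassigned.  Contrasts use
the classical pooled-variance Student t test (not Welch, matching the
reference analysis), two-tailed, α = .05, on **participant-level** means —
nights are averaged per participant first, so the sampling unit is the
participant and nights are not pseudo-replicated.  Whether the reference
tests used participants or nights as the unit is unstated; this is our
documented choice.  Window-to-window stability is scored by the adjusted
Rand index between consecutive windows' assignments on common
participants.

## DST effects

Windows are half-open and symmetric: before = [DST−h, DST), after =
[DST, DST+h), so the clock-change day itself belongs to "after" (the
convention is ours; either reading is defensible).  Horizons 15/30/60
days; α = .05; no multiple-testing correction across the grid, matching
the reference analysis.  Within a participant, nights are treated as
independent observations; serial correlation is ignored — a real
limitation that inflates significance for strongly autocorrelated
variables.

## Synthetic cohort generator

For participant i, variable v, date t:

    y_ivt = μ_v + cluster_offset_v + b_iv + slope_v (t − t0) + δ_v 1[t ≥ DST] + ε_ivt

with `b_iv ~ N(0, σ_between,v)` and `ε ~ N(0, σ_within,v)`, i.i.d. across
nights.  Defaults:

| variable | μ | σ_between | σ_within | slope/day | δ (DST) |
|---|---|---|---|---|---|
| steps | 4895.97 | 2772.25 | 1500 | −6 | 0 |
| diurnal HR (bpm) | 58.89 | 5.91 | 3.0 | 0 | 0 |
| nocturnal HR (bpm) | 61.10 | 6.02 | 2.5 | 0 | 0 |
| time in bed (h) | 7.81 | 0.82 | 0.30* | +0.0015 | 0 |
| TST (h) | 6.86 | (implied) | (implied) | 0 | 0 |
| SOL (min) | 10.22 | 5.25 | 6.0 | 0 | +5 |
| awakenings | 2.03 | 0.93 | 1.2 | 0 | 0 |
| deep (h) | 2.18 | 0.68 | 0.40 | 0 | 0 |
| REM (h) | 1.54 | 0.34 | 0.35 | 0 | −0.20 |
| light (h) | 3.13 | 0.56 | 0.50 | 0 | 0 |
| midtime (min after 00:00) | 187.5 | 44.1 | 40 | 0 | +20 |

Means and between-SDs are the reference cohort's summary values (midtime
reported there in seconds after midnight; 11 249.91 s ≈ 03:07).
Within-night SDs, the step-count decline, the time-in-bed rise, and the
DST effect sizes (SOL jump, later midtime, reduced REM after the change —
directions as observed around the autumn change) are our choices of
realistic magnitudes; they are single knobs, set once.  The DST effect is
a step function — the simplest form consistent with the observed SOL
"leap" — with a linear-decay option stubbed but off by default.

Hard record invariants hold *by construction*, and configured means stay
exact in expectation:

* counts (steps, awakenings) are rounded Gaussians floored at zero, with
  the latent mean analytically corrected (inverting
  `E[max(N(m′,σ),0)] = m` by interpolation) so flooring does not bias the
  mean;
* SOL is log-normal — strictly positive and right-skewed, as latencies
  are — with its mean set exactly;
* TST is **derived** as deep + REM + light + intra-sleep wake (mean 0.01 h,
  matching the near-equality of stage sum and TST in the reference
  summary).  Its between/within SDs are implied by the stage SDs rather
  than set directly — the price of making the stage-sum invariant
  structural;
* time in bed = TST + SOL + a nonnegative terminal-slack term whose mean
  targets the configured population path; its between-participant
  variation is inherited from TST and SOL (an independent between-effect
  would force the slack negative for many participants and bias the mean);
* midtime is generated on the circle (mod 1440);
* nights and days are deleted independently at the MCAR missingness rate
  (default 10 %); no informative-missingness mechanism is modeled;
* enrollment dates are uniform over the enrollment window (June 7 –
  September 25, 2017 by default), with a common stop (December 28, 2017).

A second cluster (default half the cohort) is offset by +1.03 awakenings,
the between-cohort gap in the reference summary; `cluster_sd_within`
optionally gives second-cluster members a different night-level SD, which
the planted-recovery experiment uses (0.93 vs 1.27).  In that experiment
all other variables are identical constants across participants: with ten
additional noisy-but-null variables, the probability that no null variable
is falsely flagged at α = .05 would be 0.95¹⁰ ≈ 0.60, and cluster
structure would no longer live only in the awakening count.

`generate_hypnogram` synthesizes a per-minute sequence realizing exact
night targets (SOL, awakenings, stage totals) by shuffling stage minutes
into awakening-separated blocks — scoring it reproduces the targets
exactly, which is the round-trip property the scoring tests rely on.

What the generator does **not** emulate: ultradian sleep-cycle
architecture, night-to-night serial correlation, informative missingness,
weekday/weekend structure, and weather or photoperiod covariates.  Passing
tests therefore demonstrate the pipeline's correctness and calibration
under clean parametric conditions, not robustness to every feature of real
self-tracker data.  Seasonal drift and a DST step are separate knobs here;
in observed data the two are confounded and cannot be disentangled.

## Problem sizes and numerical choices

Simulation experiments use: 100 cohorts (n = 50, 30 nights) for
planted-cluster recovery; 1000 independent participant series for the
type-I calibration of the DST test and 200 for the power-by-horizon
comparison; 200 series of ~89 days for the stabilization-day
distribution.  These sizes give binomial standard errors of 0.7–3
percentage points on the reported rates.  Determinism: every experiment
flows from one integer seed; K-means uses fixed seeds with 10 restarts;
t tests on two zero-variance samples are defined as t = 0, p = 1 when the
means agree (and ±∞, p = 0 otherwise) instead of 0/0.
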