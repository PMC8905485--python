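# sleepspan

**How many nights of consumer sleep-tracker data are enough?**

Clinical sleep assessment traditionally uses one night of polysomnography,
and free-living actigraphy studies typically collect 3–14 days.  Consumer
wearables (a smartwatch logging steps and heart rate) and nearables (an
under-mattress sensor scoring sleep stages per minute) make months of
unattended recording cheap — and once you look at months of data, the
3–14-day standard starts to look thin: per-night sleep metrics fluctuate
strongly from week to week, show seasonal trends, and shift visibly around
the autumn daylight-saving-time (DST) clock change.

`sleepspan` packages the analysis pipeline for this question, aimed at
sleep and digital-health researchers working with longitudinal self-tracker
panels:

* **Night metrics** — derive the standard per-night variables from a
  per-minute hypnogram: total sleep time (TST, onset → final wake), sleep
  onset latency (SOL), number of awakenings, stage durations
  (deep/REM/light), and the circular *sleep midtime* (clock time halfway
  from onset to final wake), with proper circular mean/SD
  (`sd = sqrt(-2 ln R)` on the 1440-minute circle).
* **Variability / duration sufficiency** — the core machinery: a rolling SD
  over 7-day windows moved one day at a time, and a *cumulative SD* over
  expanding windows (3 days, then 4, … up to 83).  An explicit
  stabilization rule marks the first window length from which successive
  relative SD changes stay below a tolerance (default 5 %) for a holding
  period (default 14 days): the measurement duration after which an
  individual's summary has settled.
* **Cohort clustering** — participant-level means over trailing windows
  (last week, last 2 weeks, …), z-scored and partitioned with K-means; K
  chosen by the elbow of the within/between distance-ratio curve; small
  clusters excluded; pooled-variance Student t tests comparing the retained
  clusters variable by variable; adjusted-Rand-index stability of the
  partition across window lengths.
* **DST effects** — two-tailed before/after t tests for all 11 variables at
  15-, 30- and 60-day horizons around a clock change (default
  2017-10-29), per participant or cohort-wide.
* **Synthetic cohorts** — a generator with participant random effects,
  seasonal trends, a DST step effect, planted clusters, MCAR missingness
  and metric-consistent hypnograms, so the whole pipeline is testable with
  known ground truth.  Model: `y = μ_v + cluster offset + b_iv +
  slope_v·t + δ_v·1[t ≥ DST] + ε`.

## Worked example

```python
import pandas as pd
import sleepspan as ss

panel, truth = ss.generate_cohort(ss.SyntheticConfig(), seed=42)
pid = panel.participants[0]

# duration sufficiency for one participant's TST
s = panel.get_series(pid, "tst_h")
s = s[s.index >= pd.Timestamp("2017-10-01")]
cum = ss.cumulative_sd(s, start_days=3, max_extra=80)
stab = ss.stabilization_day(cum, rel_tol=0.05, hold_days=14)

# cohort clustering over the last six weeks
feats = ss.build_features(panel, weeks_back=6, min_days=5)
k = ss.select_k(ss.elbow_curve(feats, range(1, 8), seed=42))
run = ss.cluster(feats, k, min_size=8, seed=42)

# DST before/after for one participant's sleep-onset latency
r = ss.dst_test(panel.get_series(pid, "sol_min"), horizon_days=60)
```

Output:

```
participants: 54, nights: 7544, days: 7499
p001 TST cumulative SD: starts 0.84 h, ends 0.73 h; stabilizes at a 27-day window
elbow K=2, cluster sizes {1: 36, 0: 18}
p001 SOL before 13.1 min vs after 19.2 min: t=-4.96, p=0.0000
```

Reading this: p001's cumulative TST SD keeps moving until a 27-day window —
four times the one-week convention — before satisfying the 5 %/14-day
stabilization rule.  The cohort splits into two clusters at the elbow
(K=2), and p001's sleep-onset latency is significantly longer after the
clock change (13.1 → 19.2 min at the 60-day horizon), the planted DST
effect recovered from the data.

The same pipeline runs from the shell:

```bash
sleepspan generate --out cohort/ --seed 42
sleepspan run --out results/ --seed 42       # variability + clustering + DST
```

outputs land as `variability_profile.csv`, `stabilization.csv`,
`cluster_run.json`, `contrasts.csv`, `dst_grid.csv` plus a reproducibility
manifest.

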