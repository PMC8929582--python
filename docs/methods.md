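# Methods

## The estimation problem

Static acoustic monitors record a daily detection metric (clicks/day,
detection-positive minutes/day) at fixed sites over several years. The
series have three properties that break naive trend estimation: strong
seasonal (and diel) structure, irregular gaps that can drift across the
season from year to year, and a metric that is non-negative with
occasional zeros. The paired-ratio method estimates the year-on-year
proportional change using only information that is immune to the first two
properties: day positions within the annual cycle that were fully logged
in *both* members of a pair of successive cycles.

## Model and assumptions

The method is descriptive and nonparametric: no distribution is assumed
for the daily values. Its implicit model is that the detection rate at
day-of-cycle `d` in cycle `j+1` relates to the rate at the same `d` in
cycle `j` by a common proportional factor — the quantity being estimated.
What must hold for the estimate to be meaningful:

* **Cycle alignment.** Day positions are comparable across cycles.
  Cycles are anchored at the first record's date (deployments start
  mid-year), 29 February is removed before indexing so every cycle is
  exactly `C = 365` days, and a missing day is an absent record, never a
  zero. A recorded zero is a real observation and contributes to sums.
* **Whole units only.** A day enters pairing only if its
  `logged_fraction` reaches `full_log_threshold` (default 1.0; lower it
  for clocks that log 1439/1440 minutes). Partial days would otherwise
  alias the diel pattern into the trend.
* **Stable observation process.** Within a site, detector sensitivity,
  position and ambient conditions are assumed constant; a changed rig is a
  new site.
* **Pooling convention.** Regional estimates sum detections across sites
  (year-1 sums and year-2 sums separately) — sites are aligned by
  day-of-cycle, *not* calendar date, so all sites must share the anchoring
  convention. High-detection sites dominate the pooled ratio by design;
  no effort weighting is applied.

## Estimators

For pairs `(y*_k, y*_{k+C})` at positions `k`:

* **Point ratio** (`I = 0`): `y*_{k+C} / y*_k`; undefined when the
  denominator year recorded zero. Under the default "missing" policy such
  points are dropped; an opt-in "epsilon" policy computes
  `(y2 + ε)/(y1 + ε)` with `ε = 1`, the additive adjustment familiar from
  `log(1+x)` transforms.
* **Windowed ratio** (`I = C` by default): windows `[k, k+C)` advance one
  unit at a time over the span of pair positions. Within a window the
  ratio of forward moving means is computed as the ratio of *sums* over
  the identical pair set (the counts cancel), which avoids asymmetry when
  pairs are missing. Each value is reported at `k + ⌊C/2⌋`, removing the
  half-cycle lag of a forward window; plot axes are labelled in fractional
  cycles. Windows with fewer than `min_pairs_per_window` pairs (default
  30, ≈8% of an annual window) are reported missing rather than unstable —
  the ratio degrades badly near zero counts and no principled threshold
  exists, so the cutoff is exposed configuration.
* **Summary statistic**: `P̂_T = Σ y2 / Σ y1` over all pairs, all sites.
  Two percent-change readings are reported side by side, because both
  conventions circulate: `percent_change_over_span = 100 (1 − P̂_T)` (the
  primary field) and `percent_change_per_cycle`, the same quantity divided
  by the span `T` in cycles. Neither is silently chosen.
* **Windowed summary**: the mean over pair-sequence windows of length `I`
  of their sum ratios; with `I = K` it reduces exactly to `P̂_T` (tested).

The ratio estimator is biased O(1/Σy1) for a ratio of noisy sums; with a
few hundred pairs at realistic detection rates this is far below the
sampling noise.

## Uncertainty: moving block bootstrap

Daily detections are serially correlated at short range, so i.i.d.
resampling understates variance. The overlapping-block scheme draws
`⌈K/w⌉` blocks of `w` consecutive pairs uniformly with replacement from
the `K − w + 1` overlapping blocks, concatenates and truncates to `K`.
`(y1, y2)` tuples stay together — resampling years independently would
destroy the pairing. Defaults: `w = 21` days for daily pairs, 3 for
monthly — `w` should exceed the correlation scale of the data, which is
documented guidance rather than an enforced check; `B = 1000` resamples
(5000 for publication-grade intervals); percentile interval at
`alpha = 0.05`.

Numerical notes:

* Per-point bands on the trend series resample blocks *within each
  window's own pairs*; windows with fewer than `w` pairs keep a missing
  band.
* Percentile intervals need not contain the point estimate at every
  window: the within-window distribution of a ratio of sums is skewed and
  overlapping blocks under-sample window edges. In no-trend simulations
  ≈1% of windows show the point just outside the band; the raw quantiles
  are reported unadjusted.
* Resamples with a zero year-1 sum are dropped and counted in a
  diagnostics field (`n_boot_undefined`).
* Coverage is approximate: across 200 simulated no-trend data sets the
  95% interval covered the true ratio ≈94–95% of the time (the acceptance
  suite asserts the wide band [0.88, 0.99]).

## Randomisation trend tests

Four permutation tests with `B` random reorderings (default 5000) and the
add-one correction `p = (1 + #extreme)/(B + 1)`, so `p ≥ 1/(B+1)`:

| id  | statistic                           | tail (default)            |
|-----|-------------------------------------|---------------------------|
| RT1 | OLS slope of value on time          | two-sided on \|slope\|    |
| RT2 | runs above/below the median         | lower                     |
| RT3 | count of positive differences       | two-sided about (n−1)/2   |
| RT4 | runs of same-sign differences       | lower                     |

Tie handling follows standard runs-test practice: values equal to the
median are removed for RT2 (this commutes with permutation, so the
permutation engine drops them once up front); zero differences are removed
for RT4. RT3's two-sided distance is measured from the *exact*
exchangeability mean `(n−1)/2` rather than the empirical permutation mean:
with an integer statistic and half-integer centre, a Monte-Carlo-estimated
centre makes the "at least as extreme" rule unstable (equidistant
opposite-side values flip in or out), and exact enumeration then disagrees
with the sampled p-value by large margins at small `n`. All tails can be
overridden per call.

The permutation engine evaluates all four statistics on row-permuted
matrices (vectorised run counting via forward-filled sign changes), which
makes thousand-replicate calibration studies cheap. Because the counting
statistics are integer-valued, their permutation tests are exactly valid
but conservative at small `n` — attainable p-values can skip past a target
level; calibration simulations in the test suite use series long enough
(n = 1000) that this granularity effect no longer masks the nominal rate.

## Synthetic scenario generators

The generators reproduce the two benchmark designs with known truth:

* **Scenario 1 (seasonal, no trend)**: mean falls linearly within each
  cycle from `start_mean = 100` to `end_mean_within_cycle = 50`, resetting
  each cycle; identical every year.
* **Scenario 2 (uniform decline)**: mean falls linearly across the whole
  span from 100 to `100 × (1 − total_decline_fraction)`, default fraction
  0.75 — which puts the closed-form paired summary ratio at ≈0.754 over
  four cycles.

Daily values are Normal(μ, σ) draws truncated at zero (detection counts
are non-negative). The gap design retains in cycle `j` only day-of-cycle
positions `[1 + (j−1)·30, (j−1)·30 + 100]` — a 100-day window shifting
+30 days per cycle, starting at day 1 (the combinatorial counts are
invariant to the start day). Over 4 × 365 days this yields 400 logged
days (27%), 70 paired positions per successive cycle pair (K = 210), 340
distinct paired days (23%) and 10 positions logged in all four cycles —
all asserted exactly in the acceptance suite.

Noise presets are scenario-specific. Scenario 1 uses
low/moderate/high σ = 5/15/30 against its 50-unit seasonal amplitude.
Scenario 2 uses σ = 1/2/4: its defining property is a decline that
*dominates* the daily noise — the paired series then splits cleanly into
an above-median first half and below-median second half (runs statistic
2). With a 75-unit total decline, the inter-annual gap between
consecutive chunks of paired days near the median is ≈15 units, so clean
separation requires daily noise of only a few units; larger σ would make
the scenario a different (and weaker) benchmark than the one it emulates.

What the generators do *not* emulate: diel structure (the method consumes
whole days only), overdispersed or zero-inflated count distributions,
serial correlation in the noise, detector sensitivity drift, and
multi-site heterogeneity. Passing tests therefore demonstrate
correctness of the estimator machinery and its behaviour under seasonal
confounding with drifting gaps — not robustness to every property of real
acoustic data.

## Problem sizes used in the checks

The acceptance suite runs entirely on simulated data at the study's
natural scale: 4 × 365-day series; 100 seeds for the no-trend summary
stability check; 1000 replicates × B = 499 permutations (n = 1000) for
type-I calibration; 200 data sets × B = 500 resamples for bootstrap
coverage; exhaustive 720-ordering enumeration at n = 6 for permutation
exactness. The whole suite completes in a couple of minutes on a single
core.

## Known limitations

* A zero year-1 sum leaves the summary undefined (reported as an error);
  sparse data with many zero-detection days push the estimator toward its
  unstable regime — the per-window `min_pairs` guard hides, but cannot
  repair, a fundamentally thin pairing.
* Pairs are formed only between consecutive cycles; a year-long outage
  breaks the chain rather than bridging it (no imputation is attempted).
* The block bootstrap assumes `w` exceeds the correlation scale; nothing
  enforces it.
* Percent-change readings interpret the ratio causally as population
  change; changes in behaviour, ambient noise or detector performance are
  indistinguishable from abundance shifts within a site.
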