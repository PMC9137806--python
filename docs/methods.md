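# Methods

## The Displacement-Index family

The pipeline works on raw tri-axial acceleration sampled at frequency
`f` (Hz). For consecutive readings the displacement is the Euclidean norm of
the difference vector; the Displacement Index `D_i` of second `k` is the
mean of the `f` distances in that second, and the trial mean `D̄x` averages
the per-second values. Three structural properties follow directly and are
property-tested: non-negativity, positive scale equivariance, and
translation invariance (a constant gravity vector, or any constant bias in
the sensor, cancels exactly — the statistic needs no gravity compensation).

**Windowing.** Distances are grouped into non-overlapping blocks of exactly
`f` consecutive distances aligned to the first distance; a trailing block
with fewer than `f` distances is dropped, because the index divides by `f`
and a partial block would be biased low. A 60 s trace at 50 Hz (3000
samples, 2999 distances) therefore yields 59 per-second values. Sample-block
alignment is used rather than wall-clock alignment; with an integer `f` the
two coincide up to the one-sample offset of the first distance.

**Quality classes and bins.** Road quality is good for `D_i <= 1`, moderate
on the open interval (1, 1.5), bad for `D_i >= 1.5`; the boundary at 1.5 is
assigned to "bad" so the bad class is the closed half-line. The intensity
distribution uses bin edges 0, 1, 2, 3, 4, 5, ∞ with the first bin closed
at 1 and all later bins left-open (`<=1`, `>1-2`, ..., `>5`); absolute time
per bin is the second count, frequencies are percentages of the series
length. Binning is per second, not per minute.

## Logger text format

One record per line, `key=value` pairs separated by `;`, record type first
(`rec=hdr|acc|aux|gnss|ann`). The header carries `f` and free metadata
(date, device); acceleration records carry a 0-based strictly increasing
index and three float channels; aux/gnss/ann records are timed in seconds
from trace start. Floats are serialized with 6 significant digits and round
trips compare at that precision; writing is deterministic (same trace, same
bytes). Units are passed through unchanged (g by default) — every
downstream statistic is unit-covariant, so nothing depends on the choice.
Values may not contain `;`, `=` or newlines; the writer rejects them rather
than escaping, keeping the format trivially greppable. Exports: CSV
(header + one row per second) for series, GPX 1.1 (stdlib XML) for tracks
and segment-endpoint waypoints, JSON for reports.

## Synthetic traces

The generator emulates the statistical structure of standardized road
trials and deliveries, not vehicle physics.

**Noise model and calibration.** Samples are i.i.d. Gaussian per axis
around a constant gravity vector with per-axis scale `sigma_a`. Consecutive
differences are then Gaussian with SD `sigma_a*sqrt(2)` per axis, the
distance `D` follows a 3-d chi distribution, and
`E[D] = (4/sqrt(pi)) * sigma_a`. Inverting this gives
`sigma_a = target * sqrt(pi)/4`, which makes the calibration exact in
expectation and linear in the target (verified by Monte Carlo against the
chi-mean and by parameter-recovery tests within 5%). Differences of i.i.d.
samples have an MA(1) correlation; this affects the variance of the
per-second average (empirically ~0.06 x target), not its mean, and is
accepted. An i.i.d. model was chosen over a random walk because it is
stationary and bounded and matches the "continuous strong vibration"
character of rough pavement.

**Per-trial variation and impulses.** Each trial draws its intensity from
Normal(target, between_trial_sd) truncated at zero before calibration.
Impulse events are Poisson-placed bursts (rate per minute; default 0 on
smooth asphalt and cobblestone, 2/min on rough asphalt, 6/min on dirt
roads, mimicking irregular single impacts), each shorter than 0.2 s, adding
extra noise at `impulse_scale` (default 8) times the base scale.

**Reference design.** A packaged CSV holds the 12 observed surface×speed
categories with their target means and between-trial SDs (A 30-150 km/h,
B 30-120, C 30-60, D 30); the default design simulates 10 replicates per
cell, 120 trials of 60 s at 50 Hz. Deliveries are ordered route segments,
each a surface model with a duration and lat/lon endpoints; GNSS fixes are
linearly interpolated at 1 Hz and segment boundaries are annotated.

**Randomness.** All entry points take a single integer seed; multi-trial
runs split it with `SeedSequence(entropy=seed, spawn_key=(counter,))` so
every trial is independently reproducible and fixtures are portable.

**What the generator does not model.** Driving behavior (braking,
steering), vehicle suspension, spectral content, non-Gaussian per-second
distributions, and GNSS noise. Passing tests therefore demonstrate the
correctness of the pipeline's computations and calibration, not that real
roads produce Gaussian accelerations.

## Trial statistics

**Summaries.** Per category: mean and sample SD (n−1) of `D̄x` across
trials, CV = SD/mean x 100, and `D_i` extremes pooled over all of the
category's seconds. Single-trial categories report SD 0 and carry a flag.

**Two-way ANOVA.** The design is incomplete (no cobblestone above 60 km/h,
no dirt road above 30, no rough asphalt at 150), so the analysis fits
nested least-squares models — intercept, +speed, +surface, +cell means over
observed cells only — and attributes sum-of-squares increments sequentially
(Type I, speed first, matching the conventional row order). Degrees of
freedom are design-matrix rank increments, which handles empty cells
without imputation: the 12-cell x 10-replicate design yields speed df 4,
surface df 3, interaction df 4, residual df 108, and total SS is conserved
to 1e-9 relative. Sums of squares below a 1e-12 relative floor are reported
as zero and their F/p as not applicable (constant data would otherwise
produce F from round-off noise).

**Tukey HSD.** The family is all 66 pairwise comparisons of the 12 cell
means, adjusted with the studentized range over the pooled within-cell mean
square (identical to the cell-means ANOVA residual); computation is
delegated to statsmodels and independently cross-checked in the tests
against `scipy.stats.studentized_range`. Mean differences are reported as
group I minus group II with confidence limits ordered `lower <= upper` on
that orientation. A single-factor view filters the family to pairs
differing in exactly one of surface/speed — 17 speed-varying and 11
surface-varying pairs for the default design — for table-style display;
the adjustment is still family-wide, which is flagged in the report. With
zero residual variance the test degenerates: p = 0 for unequal means, 1 for
equal. Stars: `*` p < 0.05, `***` p < 0.001.

## Delivery analysis

A delivery report combines the overall `D̄x`, the binned distribution, and
quality-class shares of seconds (each summing to 100% up to rounding).
High-vibration segments are maximal runs of consecutive seconds with `D_i`
strictly above the threshold (default 3), kept if at least `min_duration`
(default 30 s) long. A configurable gap tolerance (default 0) merges runs
separated by at most that many below-threshold seconds; with the synthetic
generator the per-second index fluctuates around its target (SD ≈ 0.06 x
target), so a sustained stretch only ~0.5 above threshold shows occasional
one-second dips, and a tolerance of a few seconds recovers it as the single
contiguous section it models. Merged segments may have a mean below the
threshold. Segment endpoints are annotated with the nearest-in-time GNSS
fix; with no fixes the segments are returned unannotated with a warning.

## Problem sizes and determinism

The test suite and the acceptance script simulate at the study's native
scale — 120 trials of 60 s at 50 Hz for the design, 200 trials for the
calibration-recovery check, deliveries of a few minutes for the segment
tests — which completes in seconds with the vectorized pipeline. All
stochastic tests are seeded; hypothesis runs derandomized. CLI runs embed
their configuration and seed in a manifest and are byte-identical on rerun.

## Known limitations

* The quality-class thresholds and bin edges are fixed conventions of the
  reporting stage, not fitted quantities.
* The ANOVA's sequential decomposition makes the speed and surface SS
  order-dependent on unbalanced data; the order is fixed (speed first) and
  documented rather than exposed.
* No frequency-domain analysis or standardized whole-body-vibration
  weighting: the index is deliberately a time-domain statistic.
* GPX export writes tracks/waypoints without timestamps (the format wants
  absolute time; the logger keeps only relative time outside the header).
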