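# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `actimetrics`, in the order data flow through the
pipeline.

## Signal model and synthetic data

A worn accelerometer at rest reads the reaction to gravity, a unit
vector in device coordinates; movement adds a dynamic component. The
synthetic generator renders each scheduled bout as

```
a(t) = ĝ · (1 + A sin(2πft + φ) + B) + ĥ₁ p₁(t) + ĥ₂ p₂(t) + ε(t)
```

with ĝ the bout's gravity orientation, A/f the vertical sinusoid, B a
sustained vertical offset, p₁/p₂ low-amplitude sinusoids on the two
perpendicular axes, and ε white Gaussian noise (default 5 mg per axis —
small against the 13 mg nonwear threshold, so wear/nonwear truth is
preserved). Scheduling works at 1-min granularity: sleep is split into
a 60-min pre-midnight block plus the remainder after midnight so
per-day totals equal the profile exactly; waking bouts are chunked
(LPA 8–17, MPA 8–15, VPA 5–10 min) and shuffled per day from a single
seed.

**Waveform calibration.** The per-class parameters are frozen design
constants, chosen once by running candidate waveforms through the metric
code and solving for values that put each class inside the intended
intensity band of *all four* metrics simultaneously:

| class | A (g) | B (g) | f (Hz) | ENMO (mg) | MAD (mg) | counts/5 s (VA≈VM) |
|-------|-------|-------|--------|-----------|----------|--------------------|
| sleep/SB | 0 | 0 | — | ~2 | ~4 | 0 |
| LPA | 0.110 | 0.040 | 0.9 | ~58 | ~70 | ~104 |
| MPA | 0.471 | 0 | 2.1 | ~150 | ~299 | ~329 |
| VPA | 1.257 | 0 | 2.4 | ~400 | ~729 | ~898 |

Three mechanisms make the joint calibration possible: a pure vertical
sinusoid fixes MAD = 2A/π while the offset B raises ENMO independently
(the band-pass removes B from the counts); the bout frequency moves the
counts through the filter's gain curve without touching the mg metrics;
and motion perpendicular to gravity affects the vector magnitude only to
second order, so sleep/SB bouts can carry enough per-axis variance to
stay "worn" while remaining sedentary under every metric. One margin is
structurally narrow: the ENMO LPA band [47, 69) mg is only 22 mg wide,
so the LPA target sits at its midpoint (11 mg margins) rather than the
≥ 20 mg margin used elsewhere; epoch-level noise is ~0.2 mg, so
classification remains deterministic. Sleep and SB bouts embed 30-s
stationary interludes every 10 min at per-bout tilted orientations;
these feed the autocalibration. Ground-truth behaviour codes are
attached per sample.

The generator emulates bout structure, gravity orientation, calibration
error and nonwear gaps. It does **not** emulate gait harmonics,
device-specific filter responses, posture transitions, or wrist-vs-hip
placement differences, and the real cohort's bout structure is unknown
— so passing recovery tests shows the pipeline's internal consistency
on controllable signals, not fidelity to any particular population.

Cohort tables are generated from `outcome = β·ilr(composition) +
γ·covariates + N(0, σ)` (optionally on the log scale), with covariate
distributions matching the descriptive table of the study population
(68.5% female, age ≈ N(45.8, 10.8), education 24/43/33%, smoking
78/16/7%, medication 10–18%). Between-metric composition correlation in
the cohort-level feature generator comes from a shared person-level ILR
deviation plus smaller metric-specific noise.

## Preprocessing

* **Autocalibration** assumes `recorded = truth·scale + offset` per
  axis. Stationary 10-s windows (all-axis SD < 13 mg — the nonwear SD
  threshold reused as the stillness criterion) should have unit norm;
  offset and scale are estimated by iterated per-axis least squares onto
  the closest point on the unit sphere, to 1e-12 convergence. With
  < 10 stationary windows or < 0.15 g orientation spread the fit is
  skipped and flagged. The post-calibration error is the mean absolute
  deviation of corrected stationary magnitudes from 1 g; > 0.01 g marks
  the file for exclusion. Calibration is idempotent to < 1e-4.
* **Nonwear**: 60-min windows slid in 15-min steps; a window is
  off-body if ≥ 2 of 3 axes have SD < 13 mg *or* ≥ 2 of 3 axes have
  range < 50 mg (the range rule's axis count is an assumption — the
  protocol leaves it unstated — applied symmetrically with the SD
  rule). Flags resolve to 5-s epochs, so detected nonwear matches
  scheduled nonwear within one window step per transition. Diary
  off-body intervals always override the signal; diary *sleep*
  intervals never change the wear mask.
* **Validity**: calendar days with ≥ 960 min wear are valid
  (boundaries inclusive); files need ≥ 4 valid days, ≥ 3 weekdays and
  ≥ 1 weekend day (Sat/Sun), and a passing calibration.

## Epoch metrics

Working epoch is 5 s (cut-points printed per minute are scaled by
epoch/60, e.g. 2020 CPM → 168.33 per 5 s; mg thresholds are intensity
averages and pass through unchanged). ENMO truncates negative residuals
to zero; MAD centres within the epoch. The counts pipeline is an open
replication of the classic device algorithm: resample to 30 Hz
(polyphase), order-3 Butterworth band-pass 0.29–1.63 Hz in
transfer-function form with steady-state initial conditions (a DC input
yields exactly zero counts), clip at ±2.13 g, rectify, subtract the
0.068 g deadband (floored at zero), quantize at 2.13/127 g per step
(8-bit over ±clip), and sum per epoch. The coefficients are exposed as
data so an independent recursion can reproduce the output bit-for-bit;
none of the constants are asserted against the closed-source vendor
implementation, and all are configurable. Vector-magnitude counts are
the per-epoch Euclidean norm of the three axis counts, rounded
half-away-from-zero to keep the integer contract.

## Features

Classification is lower-inclusive (value ≥ threshold enters the higher
class) and applied to waking wear epochs; precedence per epoch is sleep
window > nonwear > intensity class, so sleep + SB + LPA + MPA + VPA +
nonwear = 1440 each full day. Sleep windows come from the diary when
present; otherwise a z-angle heuristic is used: angle = atan2(z,
√(x²+y²)) on 5-s medians, candidate blocks where successive changes
stay ≤ 5° for ≥ 5 min, blocks merged across gaps ≤ 30 min, longest
merged run wins. (The full adaptive-percentile variant of the published
heuristic is not implemented — only the fixed 5°/5-min rule; the merge
gap is a design choice.) Average acceleration is the mean epoch value
over the day's wear epochs, in each metric's native units — the counts
metrics are reported in counts, not mg, since no counts→mg mapping is
defined. The intensity gradient regresses ln(minutes in bin) on ln(bin
midpoint) over non-empty bins from zero upward; the default bin width
is 25 mg for mg metrics, and for counts it is 25 mg scaled by the
recording's mean-counts/mean-ENMO ratio so occupancies stay comparable
(the binning is undocumented in the protocol; both are configurable).
Nonwear epochs are excluded rather than imputed — conservative and
testable. The average day weights weekdays 5/7 and weekend days 2/7 and
re-closes the 4-part composition to 1440 min.

## Compliance

Sleep 420–540 min, SB ≤ 480 min, MVPA ≥ 30 min, all inclusive ("limited
to 8 hours" and "between 7 and 9 hours" read as inclusive; the
guideline's "and/or" is treated as independent criteria). The eight
categories partition the cohort.

## Agreement

ICC(2,1): two-way random-effects ANOVA, absolute agreement, single
measure, with McGraw–Wong F-based 95% CIs (reproducible without
resampling); estimates < 0.5 read "poor", 0.5–0.9 "moderate to good".
Bland–Altman uses the 1.96 normal quantile for limits of agreement (not
t-based) and the pairwise mean as the MAPE denominator (the standard
conventions; the protocol names the statistics without formulas). Pairs
with zero pairwise mean are excluded from MAPE and counted. The grid
covers the six metric pairs × {SB, LPA, MVPA, avg accel, IG slope};
sleep is excluded because every metric shares one sleep algorithm.
Complete cases per pair.

## Compositional models

Pivot ILR with documented part order (sleep, SB, LPA, MVPA by default;
the focal behaviour is pivoted first for reallocation reading, though
predictions are invariant to the partition — asserted numerically).
Zeros are replaced additively at 1 min with proportional re-closure
before transforming. Outcome models are OLS on the 3 ILRs plus
reference-coded covariates, complete cases only, with a global F test
of the ILR block and residual-based diagnostics (Shapiro, Breusch–
Pagan, Cook's distance, VIF); simulation-based residual checks replace
posterior-predictive checks, which presuppose a Bayesian fit.
Reallocation moves δ minutes into the focal part and rescales the rest
by (S−δ)/S; predictions hold covariates at estimation-sample means,
back-transform log-model predictions before differencing, and divide
absolute differences by the raw-outcome SD of the estimation sample for
the standardized effect size.

The metric-comparison question — do the four metrics produce different
mean compositions within participant? — is ambiguous as a mixed-model
specification ("random slopes at the log-ratio level" does not name the
regressor). Two routes are provided: the default `method="mm"` is an
exact repeated-measures MANOVA (Hotelling T² on the stacked
within-person ILR differences against the reference metric; F with
(q, n−q) degrees of freedom, q = 9 for four metrics), which is exactly
calibrated under normality and fast enough for simulation studies;
`method="mixedlm"` fits the stacked ILRs with a random intercept per
participant and a variance component per ILR index and Wald-tests the
metric × ILR interaction, falling back to the exact test on singular
fits. Neither is claimed to be the original specification.

## Problem sizes and numerical choices

The end-to-end recovery experiment uses a 7-day recording at 30 Hz
(the counts working rate; ~18 M samples) — the package's chosen
simulation size, with identical code paths at 100 Hz. Calibration
experiments use 500 null replicates at n = 200 and 300 planted-effect
replicates at n = 500; a ±2 SE recovery check has true hit probability
≈ 95.4%, so with 300 replicates the Monte-Carlo SE of the observed rate
is ≈ 1.2% and the test bound sits 2 MC-SE below 95%. All simulation
randomness flows from named integer seeds through
`numpy.random.default_rng`. Ties at cut-point boundaries go upward by
the lower-inclusive rule; degenerate inputs (all-zero compositions,
< 2 intensity bins, zero between-subject variance) return flagged
undefined values rather than raising mid-pipeline.

## Known limitations

* Bout waveforms are stationary sinusoids; real accelerometry has
  harmonic-rich, autocorrelated, posture-dependent signals. Counts
  magnitudes are therefore internally consistent but not comparable to
  vendor counts on real data.
* The cohort-level feature simulator draws volume/gradient features
  around the printed descriptive means rather than deriving them from
  raw signals; it supports agreement/compliance machinery tests, not
  claims about real cohorts.
* Sleep detection implements the fixed-threshold heuristic only, and
  the diary is trusted entirely when present.
* The real study's cohort-specific coefficients are not reproducible
  from synthetic data and are not targeted.
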