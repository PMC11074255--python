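# Methods

## Setting and assumptions

The package analyses two kinds of chronobiological data collected under
constant darkness after an entrainment phase:

* **Expression time courses**: one TPM value per gene per timepoint on a
  uniform grid, by default 17 timepoints at Δt = 3.1 h (49.6 h, i.e. four
  circatidal or two circadian cycles).  Samples are pooled per timepoint, so
  there are no within-timepoint replicates; replication comes from folding
  the repeated cycles.
* **Locomotor traces**: hourly total travel distance per individual, derived
  from 30-s position frames, observed for ≥ 72 h.

Two period windows are fixed throughout: circatidal 12.4 ± 3.1 h and
circadian 24.8 ± 3.1 h.  The design constant Δt = 3.1 h makes both window
centres exact multiples of the sampling interval (12.4 = 4Δt, 24.8 = 8Δt),
which is what makes phase folding exact.

## Rhythm detection

### Statistic family

For a candidate period `T = m·Δt`, timepoint `k` joins phase group
`k mod m`.  Rhythmicity is an ordered alternative on the groups.  The
building block is the Mack–Wolfe umbrella statistic: the sum over an ordered
set of group pairs of Mann–Whitney counts (ties counted 1/2).  Because the
alternative is periodic, each peak phase `h` is tested with two pair sets:

* **cyclic umbrella** — groups reordered trough → peak → trough, where the
  trough sits half a cycle from the peak; the classical linear umbrella on
  the fixed order 0..m−1 (kept as the public `umbrella_statistic`
  primitive) cannot represent peaks near the fold boundary;
* **crest contrast** — the ⌊m/2⌋ groups nearest the peak against the rest,
  all cross pairs.  A cosine peaking midway between two sampled phases
  produces a two-group plateau on the m = 4 fold that the umbrella matches
  only weakly but the crest matches exactly.

On simulated study-condition data (peak/trough 2.0, CV 0.1, uniform phases)
the symmetric umbrella alone recovers ~76% of planted circatidal genes at
p < 0.01; adding the crest raises recovery to ~99% while the null false
positive rate stays near 0.7% (threshold 1%).  A richer asymmetric
rise/fall-length family was evaluated and rejected: its larger multiplicity
cost outweighed the shape gain.

### Null distributions

All p-values are one-sided (upper tail) under the permutation null, which is
exact given the observed value multiset:

1. **Rank-insertion dynamic program** (default).  The null law of each
   statistic depends only on fold geometry and the tie pattern, so it is
   computed exactly once per (n, m, shape, tie-pattern) and shared across
   genes: distinct values are placed smallest-first, each tie class
   distributed over phase groups in every composition; states are per-group
   placement counts.  The doubled statistic stays integral, so tail
   comparisons are exact.  A table-size guard (5·10⁷ cells) bounds cost.
2. **Multiset enumeration** for tied series whose distinct-arrangement count
   is ≤ 10⁶, when the DP guard trips.
3. **Normal approximation** otherwise, with mean and variance computed
   exactly for the observed tie pattern from permutation moments of the
   pairwise comparison kernel (this reduces to the classical Mack–Wolfe
   variance when values are distinct).  The normal tail is conservative — at
   the statistic's maximum on the m = 4 fold it overstates p by roughly two
   orders of magnitude — which is why the DP is the default.

All three routes are cross-validated against brute-force enumeration over
all n! permutations in the test suite.

### Multiplicity and calling

The window p-value is the minimum over (period, phase, shape) alternatives
times their count (Bonferroni, capped at 1) — conservative, since the
alternatives are positively correlated; null calibration tests document the
conservatism.  p-values are floored at 1e-300 so downstream logs are finite.
Genes are called oscillating at p < α (strict), default α = 0.01.

## Expression filters

A gene enters rhythm analysis only if mean TPM > 1 *and* max/min TPM > 1.3
(both strict; a zero trough with positive peak counts as infinite ratio; an
all-zero gene is removed as low expression).  The low-expression rule is
tallied first.  These thresholds are configurable; the defaults reflect the
bulk pooled-sample design.  Note two distinct amplitude notions: the filter
uses the peak/trough *ratio*; S_DR uses the max − min *difference*.

## Differential rhythmicity (S_DR)

ΔP = log p_ctrl − log p_trt (natural log, circatidal window);
ΔR = log2 of the amplitude ratio (amplitude = max − min TPM).  Both are
standardized across included genes with the sample SD (ddof = 1) and
combined as S_DR = (Z_P + Z_R)/√2.  Genes are included when their circatidal
p is < 1 in at least one condition ("either", default): with
Bonferroni-capped p-values many uninformative genes sit exactly at 1, and a
gene *gaining* rhythmicity under entrainment has p = 1 in control — the
stricter "both" rule (selectable) would exclude exactly the genes the score
targets.  Genes with zero amplitude in either condition are excluded with a
logged reason.

The null is a Gaussian fitted to the empirical S_DR distribution by maximum
likelihood (plain moments, ddof = 0); p is the one-sided upper tail
(increased circatidal rhythmicity; the lower tail is selectable), adjusted
by Benjamini–Hochberg.  Because the null is empirical, the score flags
*sparse* differential rhythmicity; a transcriptome-wide regime shift widens
the fitted null instead of producing hits — by design, and worth remembering
when interpreting zero-hit runs.

## Dominance log-ratio

Per gene, log(p_circadian/p_circatidal) (natural log); summaries report the
across-gene mean ± SEM per condition.  Positive mean ⇒ circatidal dominance.
Genes lacking a result in either window are skipped with a log message.

## Activity analysis

Position frames are averaged in consecutive non-overlapping triplets (90-s
effective spacing) to damp tracking jitter; Euclidean steps between
consecutive averaged points are summed within each 1-h bin (40 points, 39
steps per full hour) and trailing partial hours are dropped.  An optional
maximum-step filter (off by default) zeroes residual tracking-error jumps.

The periodogram is the least-squares spectral estimate with a floating mean:
power(T) = 1 − SSR(T)/SStot of the intercept+cosine+sine fit on the first
72 h, so power ∈ [0, 1], a noise-free sinusoid approaches 1, and power is
invariant under shifting/scaling the trace.  The per-period 3×3 normal
equations are solved with a pseudoinverse because the Gram matrix is
singular at the Nyquist period (the sine column vanishes on integer
sampling).  The default grid is 2–36 h in 0.1-h steps; a constant trace gets
power 0 everywhere and a flag.  Band max powers use closed bands 20–28 h and
10.4–14.4 h.

Group comparison fits a Gamma GLM (canonical inverse link by default, log
selectable) and tests the group term with the deviance chi-square on 1 df
scaled by the full model's Pearson dispersion.  Band powers must be strictly
positive (the error message suggests an epsilon floor for zero powers).
Chi-square values below 1e-10 are clamped to exactly 0 so identical groups
report χ² = 0, p = 1.  Calibration under equal-mean Gamma samples (n = 30
per group) is verified by a KS uniformity test.

## Synthetic data

The expression generator draws per-gene lognormal baselines
(`baseline_log_mean` 2.0, `baseline_log_sd` 1.0 — TPM medians near 7 with a
realistic right tail), multiplies rhythmic genes by
`1 + a·cos(2π(t − φ)/T)` with `a = (r−1)/(r+1)` so the noiseless
peak/trough ratio equals `r`, and applies multiplicative lognormal noise
with a configured CV (mean exactly 1).  Phases are uniform by default; a
fixed phase is available for worked examples.  Circatidal genes default to
12.4 h (the endogenous period; the timer-driven tank cycle itself is 12.0 h
and available by configuration).  Default noise CV is 0.1: the pooled
design offers no replicate variance to calibrate against, so this is a
choice — moderate technical-plus-pooling noise relative to a
peak/trough-2.0 signal.  Baselines, phases and noise use separate seeded
substreams, so paired configs sharing a seed differ only where intended.

The activity generator superposes cosine components on a positive mean
level, applies an optional exponential decay envelope (emulating the
activity decline seen after tidal entrainment), adds Gaussian noise and
clips at zero.  The tide schedule is a pair of alternating drain/supply
clock timers with instantaneous level switches — a phase reference, not
hydrodynamics.

What the generator does *not* emulate: read-level sequencing noise and
library-size effects, gene–gene correlation, non-sinusoidal waveforms,
inter-individual variability in the pooled samples, and
salinity/temperature covariates.  Passing tests therefore demonstrate
correctness and calibration of the statistics under the stated stochastic
model, not performance on real transcriptomes.

## Pipeline and reproducibility

All randomness flows from one config seed through `SeedSequence` children
spawned per population × group in sorted order.  Tables are written with 12
significant digits, making write→read→write byte-stable and same-seed reruns
byte-identical.  The run report records thresholds, per-stage counts, the
package version and a hash of all analysis-relevant config fields (the
output directory is excluded from the hash).

Problem sizes used by the test suite and the acceptance script — 2000 genes
for calibration/recovery, 1000 genes × 10 replicates for S_DR recovery, 600
genes per dominance condition, 1000 Gamma-GLM replicates — are chosen so
each check has tight Monte-Carlo error while the whole suite completes in a
few minutes on one CPU.

## Known limitations

* The Bonferroni correction over correlated alternatives makes window
  p-values conservative (null fraction below 0.01 is ~0.007, not 0.01); the
  original RAIN adjustment is not re-implemented.
* Candidate periods are restricted to multiples of Δt; periods off the grid
  (and RAIN's longitudinal mode) are out of scope.
* With a single series per condition, S_DR has no within-gene replication;
  its p-values are relative to the empirical gene population, not an
  absolute null.
* Periodogram normalization matches the least-squares definition; absolute
  power values are comparable within a run, not across tools with other
  normalizations.
* Activity χ² values depend on the periodogram grid and normalization, so
  cross-tool numerical agreement is not expected even on identical traces.
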