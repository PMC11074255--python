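# tiderhythm

Inference of circadian (~24.8 h) and circatidal (~12.4 h) rhythms in
locomotor activity and time-course gene expression, built for experiments in
which animals from tidal and non-tidal habitats are entrained to a simulated
tidal cycle and then sampled under constant darkness.  The motivating system
is a freshwater snail whose downstream populations experience both the
day–night cycle and a 12.4-h tidal cycle; the package asks, per gene and per
individual, *which clock dominates, and how does entrainment shift it?*

It is aimed at chronobiologists with bulk RNA-seq time courses (one pooled
sample per timepoint, e.g. 17 timepoints at Δt = 3.1 h spanning 49.6 h) and
hourly locomotor distance traces, who need rhythm detection in two period
windows, differential-rhythmicity scoring between conditions, and
transcriptome-level dominance summaries — plus a seeded synthetic-data
module so every stage can be exercised and validated without external data.

## What it computes

**Rhythm detection (RAIN-style umbrella rank test).**  A gene's series is
folded at each candidate period `T = m·Δt` inside a window (circatidal
12.4 ± 3.1 h → {9.3, 12.4, 15.5} h; circadian 24.8 ± 3.1 h →
{21.7, 24.8, 27.9} h) into `m` phase groups.  For each peak phase the
Mack–Wolfe umbrella statistic counts pairwise orderings concordant with a
rise–peak–fall profile (cyclic, with a complementary "crest" contrast for
waveforms peaking between sampled phases).  One-sided p-values come from the
exact permutation null — computed by a rank-insertion dynamic program, or by
multiset enumeration for tied series — with a normal approximation using an
exactly tie-corrected variance as fallback; the minimum over
(period, phase, shape) is Bonferroni-corrected.  Oscillating genes are
called at p < 0.01.

**Differential rhythmicity.**  For genes tested in the circatidal window in
control and treatment, with amplitude `R = max TPM − min TPM`:

    ΔP = log p_control − log p_treatment        ΔR = log2(R_trt / R_ctrl)
    S_DR = (Z_P + Z_R) / √2

where Z_P, Z_R standardize ΔP, ΔR across genes.  A Gaussian fitted to the
empirical S_DR distribution gives upper-tail p-values (increased circatidal
rhythmicity), adjusted by Benjamini–Hochberg.

**Dominance.**  Per gene, `log(p_circadian / p_circatidal)`; a positive
transcriptome mean says the circatidal rhythm dominates.

**Activity rhythms.**  Position tracks (30-s framing, coordinates averaged
in triplets) become hourly travel distances; a normalized least-squares
Lomb–Scargle periodogram over the first 72 h yields max power in the
circadian (20–28 h) and circatidal (10.4–14.4 h) bands, compared between
groups with a Gamma-GLM likelihood-ratio test.

## Worked example

A two-condition simulation of one population: the control transcriptome is
circadian-dominated (25% circadian genes, 2% circatidal), the
tidal-entrained treatment is the reverse.  `demo.yaml`:

```yaml
seed: 11
outdir: demo_out
populations:
  tidal:
    control:
      n_genes: 400
      frac_circatidal: 0.02
      frac_circadian: 0.25
      peak_trough_ratio: 2.0
      noise_cv: 0.1
    treatment:
      n_genes: 400
      frac_circatidal: 0.25
      frac_circadian: 0.02
      peak_trough_ratio: 2.0
      noise_cv: 0.1
```

```
tiderhythm run --config demo.yaml
```

prints (abridged):

```json
{
  "tidal": {
    "control":   {"filter": {"n_input": 400, "n_retained": 368},
                  "n_significant": {"circadian": 102, "circatidal": 9}},
    "treatment": {"n_significant": {"circadian": 7, "circatidal": 96}},
    "dominance": {"control":   {"mean": -2.17, "sem": 0.24},
                  "treatment": {"mean":  1.95, "sem": 0.20}},
    "n_circadian_to_circatidal": 88,
    "sdr": {"n_included": 273, "n_hits_fdr": 0}
  }
}
```

Reading the numbers: the filters drop 32 of 400 genes (low mean TPM ≤ 1 or
peak/trough ≤ 1.3).  In the control, 102 genes oscillate in the circadian
window versus 9 in the circatidal window at p < 0.01; after entrainment the
counts invert (7 vs 96).  The dominance log-ratio flips sign accordingly
(−2.17 → +1.95, both beyond 2 SEM), i.e. the dominant transcriptome rhythm
follows the entrainment regime, and 88 genes switch from circadian-only to
circatidal-only rhythmicity.  `n_hits_fdr = 0` is expected here: S_DR
standardizes against the empirical across-gene distribution, so a shift this
widespread *is* the background and no single gene stands out — the score is
built to flag sparse differential rhythmicity (a handful of genes among
thousands), not global regime changes.

All artifacts (matrices, truth tables, per-gene rhythm results, S_DR and
dominance tables, transition gene lists, `report.json`, log) land in
`demo_out/`; rerunning with the same seed reproduces them byte-for-byte.

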