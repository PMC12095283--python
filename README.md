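# msdyn — resting-state EEG microstate dynamics

`msdyn` segments multichannel resting-state EEG into **microstates** —
brief (tens-to-hundreds of ms) periods during which the scalp topography
stays quasi-stable — and compares their temporal statistics between two
groups. It is written for EEG researchers who want a transparent,
fully-tested Python implementation of the classical microstate chain:

* preprocessing: 0.5–80 Hz FIR band-pass, 50 Hz notch, 2 s epochs,
  spherical-spline channel interpolation, amplitude-based epoch rejection,
  average reference, 2–20 Hz microstate band;
* polarity-invariant **T-AAHC** clustering of GFP-peak topographies, with
  a seven-index battery (Davies–Bouldin, silhouette, Dunn, point-biserial,
  Gamma, Krzanowski–Lai, cross-validation) for choosing the number of
  classes, and canonical A–D labeling;
* **backfitting** by global map dissimilarity, window-penalized smoothing
  ("Besag factor"), sub-30 ms segment removal, and the canonical
  parameters — mean duration, occurrence rate (Hz), time coverage (%),
  GEV, and the 12-cell transition-probability matrix;
* two-group inference: pooled/Welch/auto independent-sample t-tests,
  Cohen's d (raw and small-sample corrected), Bonferroni families
  (α/4 for parameters, α/12 for transitions), within-group Pearson
  correlations with scale scores — plus a **summary-statistics mode** that
  recomputes published t values exactly from printed means, SDs and group
  sizes;
* a seeded **synthetic-EEG generator** (semi-Markov state path, oscillating
  templates with per-segment polarity flips, controlled SNR, two-group
  cohorts with known dwell-time contrasts) so the entire chain is
  validated by parameter recovery, not by eyeball.

The key quantities, for maps **u**, **v** and sample maps **x**ₜ on C
channels under average reference:

* GFP(t) = spatial SD of **x**ₜ;
* GMD(**u**, **v**) = min over polarity of RMS(**u**/GFPᵤ ∓ **v**/GFPᵥ),
  with GMD² = 2(1 − |r|);
* GEV = Σₜ (GFPₜ rₜ)² / Σₜ GFPₜ², rₜ the spatial correlation between
  **x**ₜ and its assigned template.

See `docs/methods.md` for the full model description and design choices.

## Worked example

Recompute a published two-group comparison from its printed summary rows
(`examples/04_recompute_published_tables.py`):

```text
comparison                    t     df         p  d (corr.)
LSAS total               13.791   39.0   0.00000      4.256
state-C duration (ms)     5.577   39.0   0.00000      1.721
state-D duration (ms)    -3.189   20.2   0.00457     -0.984
```

The pooled rows carry df = n₁ + n₂ − 2 = 39; the Welch row carries its
Satterthwaite df. A C-duration effect of d ≈ 1.7 is a very large group
difference.

Segment one synthetic subject end to end
(`examples/02_segment_single_subject.py`):

```text
cleaned: 60 x 2 s epochs retained (120 s)
template |correlation| with generative truth: [1. 1. 1. 1.]

state  duration_ms  occurrence_hz  coverage_pct  gev
    A        94.59           2.29         23.38 0.93
    B        89.31           2.33         22.12 0.93
    C        85.57           2.08         19.22 0.93
    D       126.65           2.58         35.27 0.93
```

The four templates recovered from the data alone match the generative
maps at |r| ≈ 1.0; durations preserve the generated ordering (D longest,
C shortest) and sit above the raw generative dwell means because segments
shorter than 30 ms are dissolved — exactly what the analysis convention
prescribes. 93% of the GFP-weighted topographic variance is explained by
four maps.

Run a whole simulated cohort (`examples/03_group_statistics.py`) to get
tidy per-subject parameter and transition tables plus the Bonferroni-
flagged group statistics, or `run_pipeline(PipelineConfig(), "simulate",
"out/")` for the same thing as an on-disk run directory (qc/, templates/,
params/, stats/, resolved config, log).

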