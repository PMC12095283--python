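# Methods

## The microstate model

Resting-state EEG spends most of its time in one of a small number of
quasi-stable scalp potential topographies ("microstates"), classically
four, labeled A–D: two mirrored oblique dipolar maps (A, B), an
anterior-central maximum (C), and an anterior–posterior gradient (D). A
segmentation assigns every sample to one template map; the temporal
statistics of that assignment — mean duration, occurrence rate, time
coverage, transition probabilities — summarize large-scale brain-network
dynamics and are compared between groups.

Two conventions run through everything:

* **Polarity invariance.** The generating dipoles oscillate, so a map and
  its sign-flip are the same state. All similarity computations use the
  absolute spatial Pearson correlation |r|, or equivalently the global map
  dissimilarity GMD = min over polarity of the RMS difference between
  average-referenced, unit-GFP maps, with GMD² = 2(1 − |r|).
* **GFP weighting.** The global field power (spatial SD of the
  instantaneous map; equal to the map RMS under average reference) indexes
  topographic signal-to-noise. Clustering operates on maps at local GFP
  maxima only, and explained variance is GFP²-weighted:
  GEV = Σₜ (GFPₜ·rₜ)² / Σₜ GFPₜ², with rₜ the correlation between the
  sample map and its assigned template.

## Pipeline

1. **Preprocessing** (`msdyn.preprocess`): 0.5–80 Hz zero-phase FIR
   band-pass plus 50 Hz notch on the continuous signal; segmentation into
   2 s epochs; spherical-spline interpolation of bad channels (MNE's
   implementation; at most 5 channels, more flags the subject for
   exclusion); rejection of epochs in which more than 10 channels exceed
   80 µV absolute amplitude (peak-to-peak optional); average reference;
   2–20 Hz band-pass per epoch for the microstate analysis. An external
   ICA hook can be inserted before re-referencing; the package does not
   implement component rejection itself and the synthetic data is
   generated artifact-free. Filters are Hamming windowed-sinc FIR kernels
   (symmetric, applied once with reflection padding, hence zero net
   phase); transition widths follow the usual adaptive rule (¼ of the edge
   frequency, minimum 2 Hz), and the notch uses a 4 Hz-wide stop band with
   a 1 Hz transition. Measured responses: −64 dB residual at 50 Hz, unit
   gain ±0.1% at 10 Hz, −70 dB at 30 Hz for the 2–20 Hz band.

2. **Clustering** (`msdyn.clustering.taahc`): topographic
   atomize-and-agglomerate hierarchical clustering of the GFP-peak maps.
   Every map starts as its own cluster; the cluster contributing least GEV
   is dissolved and each freed map joins the cluster whose centroid it
   best matches in |r|; centroids are each cluster's first principal
   pattern (the leading eigenvector of the member scatter, which is the
   GEV-optimal representative and is inherently sign-agnostic; the
   polarity-aligned member mean is available via `centroid_mode="mean"`
   but its iterated sign alignment can settle on poor fixed points for
   heterogeneous clusters and is not the default for that reason). The
   agglomeration is nested, so one run yields
   solutions at every intermediate k. On 12 maps from three noisy template
   families the k = 3 solution reaches the exhaustive-partition GEV
   optimum to within a fraction of a percent (the test enumerates all
   86 526 partitions with optimal-eigenvector centroids).

3. **Cluster-number selection** (`k_selection_criteria`): Davies–Bouldin,
   silhouette, Dunn, point-biserial, Goodman–Kruskal Gamma
   (pair-subsampled), Krzanowski–Lai, and a predictive-residual
   cross-validation criterion, all on the distance d = 1 − |r|; a modal
   vote over the per-criterion optima picks k (ties go to the smaller k).
   The exact formulas behind some proprietary variants of these indices
   are not public; the implementations here follow the standard
   cluster-validity literature and are labeled accordingly.

4. **Canonical labels** (`canonical_labels`): templates are matched
   one-to-one against built-in A–D archetype maps by a Hungarian
   assignment maximizing total |r|; the correlation matrix is kept as
   provenance and templates are sign-aligned to their archetype for
   display. For k ≠ 4 labels stay generic (M1…Mk).

5. **Backfitting and temporal parameters** (`msdyn.segmentation`): every
   sample takes the label of the template with minimal GMD; zero-GFP
   samples are unassigned. Smoothing re-scores each sample's misfit
   (1 − r²) minus besag/(2(C − 1)) per same-labeled neighbour within a
   30 ms window and iterates to a fixed point, never increasing the switch
   count. Interior segments shorter than 30 ms are then dissolved,
   shortest first: their samples join the better-fitting adjacent state
   under a single left/right cut (the contiguity-constrained version of
   sample-wise reassignment — unconstrained per-sample choice can
   interleave states and fail to terminate). Epoch-edge segments are
   exempt from the minimum and excluded from duration means and occurrence
   counts (their dwell is censored by the epoch boundary) but included in
   coverage. Coverage is normalized over assigned samples only. Transition
   probabilities count ordered segment adjacencies within epochs, pooled
   over all K(K − 1) = 12 cells in a single denominator — the cells sum to
   exactly 1, matching the printed-table convention in which all 12 cells
   sum to ≈ 1 rather than each row.

6. **Group level** (`analyze_study`): subject-level T-AAHC, then a second
   T-AAHC across the pooled subject templates of each group, canonically
   labeled; each subject is backfit with their group's templates. A
   pooled-peaks alternative can be had by concatenating recordings before
   `fit_subject_templates`.

7. **Statistics** (`msdyn.stats`): independent-sample t-tests per
   parameter/state and per transition cell. The default `auto` variant
   gates pooled vs Welch on Levene's test at 0.05 — published tables of
   this design are internally consistent only if some rows are pooled and
   others Welch, so both degrees of freedom are reported honestly rather
   than forcing df = n₁ + n₂ − 2 everywhere. Cohen's d is recovered from t
   as d = t·√(1/n₁ + 1/n₂), with the small-sample (Hedges) factor
   1 − 3/(4·df − 1) available; published effect sizes in this literature
   mix both conventions, so both are emitted. Bonferroni families:
   α/4 = 0.0125 for the four-state parameter tests, α/12 ≈ 0.0042 for the
   twelve transitions, strict inequality. Pearson correlations between
   scale scores and microstate features are computed within each group
   (pooling groups would inflate r through the group difference) and are
   uncorrected by default with optional Benjamini–Hochberg.
   `t_from_summary` applies the identical formulas to printed means/SDs/n,
   enabling exact recomputation of published tables; it equals the
   raw-data path to floating precision on empirical moments.

## Synthetic ground truth

`msdyn.synthetic` generates the data every claim is tested on:

* **Templates**: smooth archetype topographies evaluated on the true
  sensor geometry (64-channel extended 10-20 montage, azimuthal
  equidistant projection): A/B oblique dipoles tilted 55° from the
  midline, C an anterior-central Gaussian, D an anterior–posterior
  gradient, plus three extra patterns for k up to 7. Zero-mean, unit-norm,
  pairwise |r| ≤ 0.54.
* **State path**: a semi-Markov chain — gamma(shape 2) dwell times
  (sub-exponential, avoiding implausible 1-sample dwells; the shape is a
  modeling choice, since empirical dwell distributions are characterized
  only by their means) with per-state means, and an explicit zero-diagonal
  jump matrix (uniform by default).
* **Signal**: at sample t, template[stateₜ] × 50 µV × sin(2π·10 Hz·t + φ),
  with a fresh uniform phase φ per dwell segment so polarity flips
  randomly across segments — downstream code *must* be polarity-invariant
  to pass. Additive Gaussian sensor noise, zero-mean across channels, is
  scaled so clean-signal RMS / noise RMS = snr (default 4). Everything is
  driven by `numpy.random.default_rng` seeds; runs are bit-reproducible.
* **Cohorts** (`make_group_study`): defaults emulate a high/low
  social-anxiety design — n = 23/18; baseline dwell means
  A/B/C/D = 71/70/62/110 ms (the comparison group's published durations);
  the high group shifted by +20 ms on C and −25 ms on D; between-subject
  dwell SD 10 ms; anxiety-scale totals at 82 vs 28 (SD 12.5) with a
  configurable within-group correlation (default 0.5) between the score
  and the subject's true C-dwell deviation; fear ≈ half of total,
  avoidance the remainder. With `synthesize=False` only truth parameters
  and scores are generated, which is what large-replicate calibration of
  the statistics layer uses.

What the generator deliberately omits: ocular/EMG artifacts, bad
channels, line noise (beyond an optional test sinusoid), 1/f background,
spatially correlated noise (flag reserved), and any dependence of
topography on frequency. Passing tests therefore demonstrate correctness
of the algorithms under the model's own assumptions — not robustness to
real-world artifacts, which the preprocessing hooks exist for.

## Numerical choices and problem sizes

* Durations recovered through the analysis chain are compared against the
  generative label path *processed with the same 30 ms minimum-duration
  convention*: the convention right-censors the dwell distribution
  (E[X | X > 30 ms] alone is +16% at an 80 ms gamma-2 mean), so raw
  generative means are not the correct reference for the segmentation's
  output. Agreement on that like-for-like comparison is within a few
  percent at snr 4.
* GFP peaks: strict local maxima, ≥ 10 ms apart (larger kept; earlier kept
  on exact plateaus), epoch boundaries excluded. By default every peak map
  enters clustering; `max_peak_maps` enables deterministic even thinning
  for speed. At a few hundred maps the greedy atomization can occasionally
  lose a rare class for a single subject, which the group-level second
  clustering absorbs — full peak sets were robust across seeds.
* Replicate-based validation runs at reduced problem sizes chosen to keep
  the whole suite desk-scale: power replicates use 41 subjects × 20 s at
  250 Hz with `max_peak_maps=300` (sign recovery of the C/D duration
  contrast ≥ 90% over 100 seeded replicates); type-I calibration uses 500
  zero-effect cohorts at the truth-parameter level; single-subject
  recovery uses 120 s at 250 Hz. The study-standard acquisition values
  (1000 Hz, 300 s eyes-closed) remain the generator defaults for `make_ground_truth` /
  `synthesize_recording`.
* Degenerate inputs: zero-GFP maps raise; all-identical maps warn and flag
  duplicate templates; a state that never occurs reports NaN duration and
  zero occurrence/coverage; epochs consisting entirely of sub-30 ms
  segments collapse to the single best-fitting state and are flagged by
  construction.

## Known limitations

* T-AAHC is greedy; it does not globally optimize GEV (no k-means polish
  is applied by default — modified k-means exists in the field as an
  alternative, and `centroid_mode="pc1"` is the closest knob here).
* The smoothing penalty scale (besag/(2(C − 1))) reproduces the intended
  qualitative behaviour of the conventional "Besag factor = 10" but the
  proprietary reference implementation's exact scaling is unpublished.
* Transition statistics use segment adjacencies; sample-to-sample
  counting would differ mainly through dwell lengths (the published
  near-unit cell sums are consistent with either).
* EDF/BrainVision reading is provided but untested against vendor files in
  this repository (no real recordings are distributed); the on-disk
  format for generated data is `.npz` + JSON truth sidecars.
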