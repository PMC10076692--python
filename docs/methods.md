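# Methods

This note documents the models and procedures implemented in `connectogrip`,
the parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical conventions that make runs reproducible.

## Grip-performance extraction

A precision-grip trial records thumb and index forces against two parallel
surfaces as 3-vectors (normal component Fₙ toward the surface, tangential
components Fₜ₁, Fₜ₂), sampled uniformly (500 Hz default), with the grip and
rest cue times known.  The scalar *grip force* is the mean of the two
digits' normal components: with parallel surfaces the opposing normal forces
are ideally equal, and the mean keeps the units of a single digit's force
(`digit_combine: sum` is available).

* **Baseline**: sample mean and SD (ddof = 1) over the 0.5 s ending at the
  grip cue (`baseline_window_s`; 250 samples at 500 Hz give stable
  statistics).  The SD is floored at 1 mN (`sd_floor_N`) so noiseless traces
  do not produce a zero-width threshold.
* **Grip initiation / termination**: first time after the cue at which the
  grip force exceeds (returns to within) baseline + 3 SD and stays there for
  20 ms (`sustain_s`, 10 samples).  A single-sample crossing rule is fragile
  under sensor noise; the sustain window rejects isolated spikes while
  shifting detection by at most the window onset, and the independent
  linear-scan oracle used in tests applies the identical rule.  If no
  crossing occurs within 5 s (`max_latency_s`) the metric is invalid for
  that trial and is excluded from the repetition average — the analog of
  discarding an unusable trial during visual quality screening.
* **Hold window**: from onset + 0.5 s (`transient_s`) to the rest cue.  The
  rise transient is excluded because mean-force and direction estimates are
  otherwise dominated by the ramp; `transient_s: 0` reproduces a literal
  "during grip" reading.
* **Force-direction error**: per digit and sample,
  θ = atan2(√(Fₜ₁² + Fₜ₂²), Fₙ) in degrees (∈ [0°, 180°], rotation-invariant
  about the normal axis and scale-invariant); samples with force magnitude
  below 0.01 N (`force_floor_N`) define no angle and are skipped; digit
  means are averaged unweighted.
* **Normalization**: each measure is averaged over valid repetitions per
  hand and expressed as paretic/(paretic + nonparetic).  The ratio is 0.5
  under symmetric performance, monotone in the paretic value, and undefined
  (with a warning) only if both hands are exactly zero.

Units are fixed: seconds, newtons, degrees; time is seconds from recording
start and cues are absolute in that frame, so all metrics are invariant to
a joint time shift.

## Connectome construction

Directed streamline counts are symmetrized by averaging the two directions.
Probabilistic tracking attenuates with path length and scales with seed
counts, so the corrected weight is

    w(i, j) = s(i, j) · d(i, j)^α / (vᵢ + vⱼ)^β ,  α = β = 1 by default,

with d the inter-region centroid distance (mm) and v the region volumes
(mm³).  The exponents are configurable and (α, β) = (0, 0) reproduces the
raw symmetric counts; the formula lives in one function so alternatives
(e.g. mean instead of summed volume) are one-line swaps.  The default region
set has 20 nodes: bilateral precentral, Rolandic, postcentral, SMA, putamen,
caudate, pallidum and thalamus, plus corticospinal-tract and
corticoreticular-pathway nodes at medulla and midbrain.  Regions are stored
lesion-relative (ipsilesional/contralesional); input files use anatomical
left/right names and a per-participant lesion side, remapped at load time so
"ipsilesional precentral" is a single variable in cohorts with mixed lesion
sides.  Undirected edges are ordered lexicographically by region index and
the cohort edge table (participants × 190 edges) round-trips to matrices
bit-exactly.

## Two-level factor analysis

Edge weights derived from streamline counts are heavily right-skewed
(approximately log-normal), and Pearson correlations of log-normal variables
are attenuated relative to the latent scale; the factor stage therefore
applies log1p to the edge weights before column standardization
(`edge_transform`, `none` available).

**Level 1.** For each region i, a factor model of the 19 edges incident to i
over participants.  **Level 2.** All retained first-level factor scores are
pooled and factored again; the second-level factors are the latent networks,
ordered by explained variance.

* **Extraction**: principal components via eigendecomposition of the sample
  correlation matrix.  No matrix inverse is assumed anywhere — cohorts with
  fewer participants than variables (n = 22 vs p = 19 is the realistic
  regime) yield singular correlation matrices, handled by eigendecomposition
  and pseudoinverse scoring.  Iterated principal-axis extraction is
  available.
* **Retention**: Horn's parallel analysis by default — a factor is kept
  while its eigenvalue exceeds the 99th permutation percentile of the
  same-rank eigenvalue under independently column-shuffled data (30
  permutations, seeded).  The classical Kaiser eigenvalue > 1 rule is
  available but not the default: whenever p/n is non-negligible, the bulk of
  the sampling-noise eigenvalue spectrum sits above 1 (its upper edge is
  ≈ (1+√(p/n))²), so Kaiser retains many noise factors per region and the
  pooled second level then "discovers" dozens of spurious networks.
  Parallel analysis estimates that noise spectrum from the data themselves
  and retains only factors that beat it.  The 99th percentile (rather than
  the conventional 95th) controls the *cohort-wise* false-positive rate:
  retention runs once per region, i.e. 20 tests per cohort, so a 5% per-test
  rate would plant spurious factors in most cohorts.  Permutations shuffle a
  column-sorted copy, so thresholds depend only on each column's value
  multiset and the retention decision is invariant to participant order.
  Shuffled-data cohorts (structure destroyed) retain no second-level factor
  in ≥ 90% of runs; with a data-driven rule the number of networks is an
  *outcome*, and `fixed_k` exists for controlled experiments.
* **Rotation**: varimax with Kaiser row normalization; orthogonal, so each
  variable's communality and the total explained variance are preserved
  exactly.  Cross-checked in tests against the statsmodels rotation
  routines.
* **Scores**: regression (Thurstone) method, F = Z R⁺ Λ, column-standardized;
  for principal components this reproduces exact (rotated) component scores.
* **Determinism**: within each factor the largest-|loading| entry is made
  positive, factors are ordered by explained variance, and all randomness
  (parallel-analysis permutations) derives from the run seed, so the whole
  pipeline is bit-reproducible given (data, config, seed).

**Composite edge weights.** Each edge appears in the models of both its
endpoint regions, possibly in several factors.  For network g the candidate
contribution through first-level factor p is
loading(edge → p) · loading(p → g); the candidate of largest absolute value
(sign kept) is the edge's composite weight — the dominant pathway by which
that edge expresses the network.  Summation over paths is available
(`composite_combine: sum`).  Edges with |weight| ≥ 0.4 are reported, at most
the top 6 per network, ties broken by edge label.

## Association analysis

For every (network, measure) cell an OLS fit on z-scored variables:

    measure ~ network_score + network_lesion_percent

The reported partial correlation uses the closed form
(r_xy − r_xz·r_yz)/√((1−r_xz²)(1−r_yz²)) and always carries the same sign as
the standardized slope; because everything is standardized, β is on the
correlation scale and β ≈ r when the covariate is weak.  Variance inflation
factors (1/(1−R²) of each predictor on the other) are reported with a
warning above 10; perfect collinearity yields ∞, not an exception.  The
lesion covariate of network g is the volume-weighted lesioned percent over
its nodes, with continuous node memberships m_r = max over incident edges of
|composite weight| — unthresholded, so every network has a nonzero
denominator (a thresholded variant is configurable):

    percent = 100 · Σ_r m_r·v_r·l_r / Σ_r m_r·v_r .

Per measure, the network with the largest |partial r| is flagged (ties go to
the lowest network index, logged); the flags are recomputed on the
uncontrolled grid and the agreement of the two is reported.  p-values are
emitted descriptively; no multiple-testing correction is applied and
p-values never drive model selection.

## Synthetic cohorts and what passing tests show

The generator plants K standard-normal latent network scores per participant
and derives everything else from them:

* **Counts**: log-count(e) = base + base_e + Σ_g pattern_g(e)·z_g + ε with
  ε ~ N(0, 0.3); counts are rounded exponentials (right-skewed, like real
  streamline counts; `base_log_count` 5.0 ≈ 150 streamlines, per-edge
  heterogeneity SD 0.5), split into two directions with ≤ 5% jitter so
  symmetrization is exercised.  `pattern_g` is uniform on [0.4, 0.9] over
  within-group edges of disjoint region groups and 0 elsewhere.
* **Lesions**: per-network lesion latents ℓ_g = −b·z_g + √(1−b²)·η, region
  fractions expit(−2.44 + ℓ_g + 0.5·noise) (≈ 8% mean).  b
  (`lesion_score_coupling`, default 0.4) makes lesions erode connectivity;
  c (`lesion_performance_effect`, default 0.3) adds a direct lesion →
  performance path, so the simple correlation overstates the true effect by
  ≈ c·b and the lesion covariate is genuinely needed — mirroring the
  clinical situation the pipeline is built for.  b = c = 0 gives an
  unconfounded cohort.
* **Measures**: a standardized latent deviate per measure,
  u = Σ_g E[m,g]·z_g − c·ℓ̄ + σε with σ chosen so Var(u) = 1; the ratio is
  clip(0.5 + 0.1·u, 0.2, 0.8).  The clip keeps back-computed paretic metric
  values physically realizable in a trial (it binds at ±3σ and costs ~1.5%
  of the planted correlation).  The 5 × K effect matrix E is the planted
  analog of the association grid.
* **Trials**: 3 maximum grips and 3 target grips per hand at 500 Hz, cues at
  1 s and 3 s.  Nonparetic metrics are normative values (30 N, 0.25 s,
  0.30 s, 0.3 N, 8°) with 5% log-normal participant jitter; paretic values
  are backed out of the planted ratios.  Traces use a piecewise-linear
  envelope — baseline, 0.15 s rise starting one sample before the (grid-
  quantized) initiation instant, hold at 4 N ± the planted magnitude offset
  with shear set so atan2(shear, Fₙ) equals the planted angle, 0.02 s fall
  ending at the quantized termination instant.  The one-sample-early rise
  start makes the 3 SD threshold crossing land exactly on the planted
  instant, so extraction recovers latencies to within half a sample; a
  smooth sigmoid with zero initial slope would push the crossing ~2 samples
  late and break that guarantee.  Trace noise (`trial_noise_sd`, 0.01 N) is
  white; real sensor noise and physiological tremor are not modeled.

One top-level seed expands into fixed-offset child seeds per component, so
cohorts are bit-reproducible and components independently regenerable.

**What passing tests do and do not show.**  The recovery experiments
demonstrate that *if* connectivity carries a low-rank latent structure with
effects of the planted kind, the pipeline finds the networks, estimates
effects nearly without bias (mean recovered partial r ≈ 0.46–0.48 for a
planted 0.5; the residual attenuation is the ~0.95 reliability of estimated
factor scores at n = 100 and the ratio clip), keeps the nominal type-I error
of the β test at 5%, and assigns the correct best network per measure with
and without lesion adjustment.  They do not validate the biological
assumptions — that streamline counts measure connectivity, that the
correction formula removes geometry, or that grip measures load linearly on
network scores — and a 22-participant cohort remains underpowered for
definitive network identification regardless of pipeline quality.

## Experiment sizes

The test suite runs the recovery experiments at: 204 noiseless trials
(round trip), 20 seeds × n = 300 (network recovery), 500 replicates × n = 100
(effect calibration), 1000 replicates × n = 50 (type-I error), 100 runs
(confounding control, b = 0.6, c = 0.5), 50 seeds × n = 150 with full trial
synthesis (end-to-end assignment).  `scripts/acceptance.py` reruns the same
experiments at 10/200/400/50/15 replicates respectively, which reproduces
every quantity to well within its tolerance in a few minutes on one CPU.

## Known limitations

* Everything upstream of streamline counts (tractography, atlas
  registration, lesion segmentation) is out of scope; counts are inputs.
* The geometry correction formula is one defensible choice among several;
  exponents are configurable but there is no data-driven way to pick them
  here.
* Factor scores are standardized within-cohort; scores are not comparable
  across separately fitted cohorts.
* With parallel-analysis retention at n ≈ 22, weakly measured regions often
  retain no first-level factor (logged); their edges still enter the
  networks only through their partner regions' models.
* The association model is linear with a single covariate; no mediation,
  interaction, or nonlinearity is modeled.
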