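# connectogrip

Different aspects of hand-grip performance after stroke — strength, reaction
and relaxation time, force-magnitude and force-direction control — may be
supported by *different* structural brain networks.  `connectogrip` is a
tested pipeline for investigating that question.  It turns raw digit-force
recordings and diffusion-tractography streamline counts into a grid of
lesion-adjusted network–performance associations:

1. **Grip performance** (`connectogrip.grip`). From 3-axis thumb/index force
   recordings (500 Hz, two parallel grip surfaces): peak grip strength over
   maximum grips; reaction time (grip cue → first sustained rise of grip
   force more than 3 SD above the pre-cue baseline); relaxation time (rest
   cue → sustained return to within 3 SD of baseline); force-magnitude
   control (|4 N target − mean grip force| over the hold); force-direction
   control (mean angular deviation θ = atan2(√(F²ₜ₁+F²ₜ₂), Fₙ) of each
   digit's force from the surface normal).  Repetitions are averaged and
   each measure is normalized as paretic/(paretic + nonparetic) ∈ [0, 1].

2. **Connectome construction** (`connectogrip.connectome`). Directed
   streamline counts n(i→j) over a 20-region sensorimotor set (bilateral
   precentral, Rolandic, postcentral, SMA, putamen, caudate, pallidum,
   thalamus, plus corticospinal-tract and corticoreticular-pathway regions
   at medulla and midbrain) are symmetrized, s = (n(i→j)+n(j→i))/2, and
   corrected for geometry: w(i,j) = s·d(i,j)^α / (vᵢ+vⱼ)^β with α = β = 1.
   Per-participant matrices become a cohort table of 190 undirected edges.

3. **Two-level factor analysis** (`connectogrip.factor`). For each region, a
   factor model of its 19 incident edge weights across participants; the
   pooled first-level factor scores are factored again, and the second-level
   factors are the latent *networks*.  Principal-component extraction on the
   correlation matrix (no invertibility assumed — small clinical cohorts
   have n < p), parallel-analysis retention, varimax rotation, regression
   scores.  Each network is summarized by composite edge weights (products
   of first- and second-level loadings); edges with |weight| ≥ 0.4 (top 6)
   are reported.

4. **Association analysis** (`connectogrip.association`). For every
   (network, measure) pair, OLS on standardized variables of
   `measure ~ network score + network lesion percent`, reporting the partial
   correlation r, standardized slope β ± SE, the uncontrolled correlation,
   and variance inflation factors.  The network with the largest |partial r|
   per measure is flagged, and flags are compared with vs. without the
   lesion covariate.

5. **Synthetic cohorts** (`connectogrip.simulate`). Because clinical
   recordings of this kind are rarely shareable, a first-class generator
   plants known ground truth — latent network scores, log-normal streamline
   counts with two-level factor structure, lesion profiles optionally
   confounded with the scores, and raw force trials whose extracted metrics
   recover the planted values — so the entire pipeline is testable end to
   end with parameter-recovery guarantees.

## Worked example

```python
from connectogrip import CohortSpec, generate_cohort, run_pipeline, RunConfig

spec = CohortSpec(n_participants=22, seed=7)   # study-scale synthetic cohort
cohort = generate_cohort(spec)                 # counts, lesions, raw trials
result = run_pipeline(cohort, RunConfig(seed=7))

print("networks retained:", result.second.network_names)
for m, n in result.association.best_network.items():
    cells = result.association.cells
    row = cells[(cells.network == n) & (cells.measure == m)].iloc[0]
    print(f"  {m:<16} -> {n}  (r = {row.partial_r:+.2f}, beta = {row.beta:+.2f} +/- {row.se:.2f})")
```

prints

```
networks retained: ['N1', 'N2', 'N3']
  strength         -> N2  (r = +0.52, beta = +0.45 +/- 0.17)
  reaction_time    -> N3  (r = -0.57, beta = -0.50 +/- 0.16)
  relaxation_time  -> N1  (r = -0.72, beta = -0.69 +/- 0.15)
  magnitude_error  -> N2  (r = +0.46, beta = +0.42 +/- 0.19)
  direction_error  -> N3  (r = -0.23, beta = -0.23 +/- 0.22)
```

The generator planted three latent networks with the default effect pattern
(strength and magnitude driven by network G1, the time measures by G2 and
G3, direction by G2); the pipeline retains exactly three networks and each
measure's flagged network is the recovered counterpart of its planted
driver.  Because all variables are z-scored, β ≈ r in every cell.  A
`NetworkDefinition` lists each network's strongest edges, e.g.
`result.networks["N1"].reported` — for this seed a brainstem/thalamus
centered network (CST/CRP at medulla and midbrain, thalamus, pallidum) with
composite weights ≈ 0.91–0.93.

The same pipeline runs from the shell on directories of CSV/TSV inputs:

```bash
connectogrip simulate --seed 7 --out cohort/
connectogrip run-all --cohort cohort/ --seed 7 --out results/
connectogrip grip-metrics --trials cohort/trials --meta cohort/trials/trial_meta.csv --out results/
```

See `config/default.yaml` for every tunable (baseline window, 3-SD rule,
correction exponents, retention rule, 0.4/top-6 reporting thresholds, …).

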