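# Methods

## The model

`connfit` quantifies how well a brain location's *connectivity fingerprint*
— the vector of its resting-state functional-connectivity values to every
target region — explains its expected task activation. For one region *R*
and one cognitive domain *d*, every vertex *v* of *R* contributes one
observation: its fingerprint row **x**ᵥ (Fisher-z correlations to all
targets) and its activation scalar yᵥ (a meta-analytic z statistic). The
model is ridge regression with an unpenalized intercept,

    min over (w, b) of  Σᵥ (yᵥ − xᵥ·w − b)²  +  λ‖w‖² ,

fit separately for each (region, domain) cell. The emulated design has 82
modeled regions (41 per hemisphere, mirroring 34 cortical + 7 subcortical
structures) × 33 domains in 7 categories = 2,706 models, with 89
connectivity targets (the 82 modeled regions plus 7 connectivity-only
targets).

Because the intercept is unpenalized, the in-sample coefficient of
determination R² = 1 − SSres/SStot is guaranteed to lie in [0, 1]: the
penalized objective at the solution is no worse than at w = 0, so
SSres ≤ SStot. This bound is asserted on every fit.

### Penalty selection

λ is chosen by 5-fold cross-validation (seeded shuffle, contiguous blocks)
over a deterministic 100-point log-spaced grid. The grid spans relative
bounds [1e−6, 1e4] scaled by the mean diagonal of the centered Gram matrix
XcᵀXc, so the search window tracks the scale of the design. A deterministic
grid within the same evaluation budget was preferred over a stochastic
black-box search: it makes selection exactly reproducible and testable.
Exact ties in CV error resolve toward the larger (more regularized) λ. If a
region has fewer than 2 × 5 vertices the fold count drops to
max(2, ⌊n/2⌋) with a warning; fewer than 4 vertices is an error. The
reported fit statistic is the *in-sample* R² of the refit at the selected λ
on all of the region's vertices — there is no held-out activation map to
predict, so in-sample fit with a permutation null is the appropriate
goodness-of-fit design.

Columns are *not* standardized by default (fingerprints already share the
Fisher-z scale); a `standardize` flag centers and unit-scales columns and
maps coefficients back.

### Permutation null

Significance of each fit comes from a within-region permutation null:
activation values are shuffled across the region's vertices (each vertex
keeps its fingerprint; the multiset of activations is conserved) and the
model is refit at the true model's λ — hyperparameters are reused, not
re-optimized — 1,000 times by default. The empirical p-value is the
strict-inequality count, `#(perm R² > true R²)/n` (a smoothed
(k+1)/(n+1) variant exists behind a flag, off by default), and the chance
level is summarized by the nearest-rank 99th percentile (the ⌈0.99 n⌉-th
order statistic) of the permuted fits.

Refits use an SVD identity: with centered Xc = U S Vᵀ and shrinkage
dᵢ = sᵢ²/(sᵢ² + λ), the in-sample R² of any permuted response is
Σ dᵢ(2 − dᵢ) zᵢ² / ‖yc‖² with z = Uᵀyc, so one SVD serves all
permutations at O(nk) each; dᵢ ∈ [0, 1) re-derives the [0, 1] bound for
every permuted fit. The identity is cross-checked in the tests against the
direct normal-equations solve.

Per-permutation seeds derive from (master seed, region, domain,
permutation index) via `numpy.random.SeedSequence`, so the null
distribution is independent of evaluation order and worker count, and
extending the permutation count leaves earlier draws unchanged.

The permuted-fit mean is not zero: it measures the in-sample optimism of
ridge at the fixed λ, which grows with the ratio of targets to vertices.
Regions barely larger than the 89-target fingerprint therefore have an
inflated chance level; the tests assert the optimism ordering over region
sizes 100/400/1600.

### Group-level statistics

R² is arcsine-square-root transformed (asin√x, variance stabilizing on
[0, 1]) before parametric tests. Across the 2,706 model cells:

* medians by domain, category and lobe, with IQR and a seeded
  1,000-resample bootstrap SE of the median (the dispersion convention for
  "error bars" on a median);
* one-way ANOVA across the 7 domain categories with
  η² = SS_between/SS_total (η² also satisfies df₁F/(df₁F + df₂),
  asserted numerically);
* all C(7,2) = 21 pairwise two-tailed t tests, pooled-variance Student by
  default with Welch behind a flag, Holm step-down correction over the full
  family, and Cohen's d with pooled SD;
* paired left-vs-right tests over the 41 homologous region pairs for a
  configurable set of lateralized domains (df = 40 at full design), Holm
  correction over that family, with d_z = mean(diff)/sd(diff) as the
  primary paired effect size and d_av as a secondary convention (the two
  paired-d conventions are not mutually derivable, so both are reported).

No clustering correction is applied across the 33 domains sharing a region
(or vice versa); the observational unit is the model cell. This matches the
analysis being emulated and is a documented limitation.

Degenerate paired data: an all-zero difference vector yields t = 0, p = 1
(no evidence of asymmetry); a constant *nonzero* difference has zero
variance and is an explicit error rather than an infinite statistic.

## Connectivity preprocessing

Per subject and run: optional nuisance regression (top 5 temporal principal
components of each noise compartment — white-matter-like and CSF-like —
extracted separately, concatenated with an intercept, removed from every
vertex by least squares), region mean timecourses (unweighted), Pearson
correlation of every vertex with every region mean, Fisher z = atanh(r)
with |r| clipped at 1 − 1e−7 (keeps downstream regression finite), then a
two-stage mean: runs within subject, subjects across the group, entirely in
z-space with no inverse transform. Nuisance regression includes an
intercept and operates per run. Own-region connectivity is retained as a
predictor. Zero-variance timecourses are a hard error, never silently
dropped.

Connectivity targets that carry no vertices (the 7 extra targets) are
structures outside the modeled vertex domain; their reference timecourses
are supplied alongside the vertex data and stacked under the vertex-derived
region means, giving the full vertices × 89 fingerprint.

## The synthetic generator

The generator replaces access-controlled resting-state data and
meta-analytic maps with a construction that has the same statistical shape
and a known truth:

* **Latents.** Each of the 89 targets gets a stationary unit-variance AR(1)
  timecourse per (subject, run), autocorrelation 0.6 by default — the
  simplest controllable model of smooth regional dynamics.
* **Vertices.** Vertex v in region r follows
  own_loading·latent_r + Σⱼ Mᵥⱼ·latent_j + compartment terms + white noise,
  with dense mixing loadings M (SD 0.2) drawn once per dataset and shared
  across subjects and runs. The fixed per-vertex loadings make fingerprints
  heterogeneous *within* a region and stable across the group — the two
  properties the regression needs. Compartment terms load each vertex (SD
  0.3) on a small set of AR(1) sources shared with the observed WM-/CSF-like
  compartment matrices, so compartment-PC regression measurably reduces
  vertex–compartment correlation.
* **Activation.** For each (region, domain), a weight vector w over all 89
  targets is drawn and scaled so the signal s = Xw on the region's vertices
  has variance ρ·c² (c = 3, a z-statistic-like scale), and i.i.d. Gaussian
  noise with SD √(1−ρ)·c is added, making the generative
  R² = var(s)/(var(s)+σ²) equal the planted ρ exactly. Planted values can
  be a scalar, an explicit map, or a (low, high) range filled with a
  shuffled linspace so the planted distribution spans the bounds exactly
  (default 0.2–0.95). The ground-truth record (w, σ, achieved R²) is the
  recovery-testing surface.

Desk-scale defaults: 1,640 vertices (20 per modeled region), 4 subjects,
4 runs, 200 timepoints per run. The single-region helper
`make_region_dataset` uses 300 timepoints: the emulated acquisition has
4 × ~1,200-timepoint runs, and below ~200 samples the fingerprint sampling
noise itself (not the activation noise) dominates coefficient
identifiability. All randomness flows from one master seed through named
substreams (parcellation, timeseries, mixing, weights, activation noise,
folds, permutations, bootstrap), so identical (config, seed) reproduce any
stage bit for bit.

What the generator does **not** emulate: cortical mesh geometry and spatial
autocorrelation of activation maps (activation noise is i.i.d. per vertex),
hemodynamics, subject-level idiosyncratic fingerprints (group-average
regime only), and realistic parcel-size dispersion (near-equal sizes by
default; a log-normal dispersion parameter is available). Passing tests
therefore certify the estimation and inference machinery, not robustness to
spatially structured noise.

## Numerical and design choices

* Ridge solve: centered normal equations with a Cholesky-backed solver
  (λ > 0) or least squares (λ = 0, full rank only); CV and permutations via
  SVD. OLS agreement at λ ≤ 1e−8 is tested to 1e−6.
* Correlation clipping at |r| = 1 − 1e−7 bounds Fisher z at ≈ 8.4.
* Nearest-rank percentile (not interpolated) for the permutation q99.
* Strict ">" in the empirical p — a true fit tied with a permuted fit does
  not count against it.
* Determinism over resumability: a run is fully determined by its config
  and master seed (the manifest records config hash and stage checksums),
  so re-running is equivalent to resuming; no partial-restart machinery is
  kept.
* Bootstrap SE of group medians: 1,000 resamples, seeded per group.

## Problem sizes used by the test and acceptance runs

The test suite exercises the full machinery at reduced scale (8–82 regions,
60–1,000 permutations). The acceptance script runs: design arithmetic on
the full 82 × 33 grid; fit recovery at 2,000-vertex regions for planted
R² ∈ {0.2, 0.5, 0.8}; a 50-replicate detection study (planted 0.5, 1,000
permutations); a 300-replicate type-I-error study (planted 0, 200
permutations); and a full 2,706-model end-to-end run at 200 vertices per
region with 200 permutations. Regions are kept larger than the 89-target
fingerprint in the end-to-end run so the permutation null's in-sample
optimism stays well below the planted signal — the regime the emulated
study operates in.

## Known limitations

In-sample R² with k = 89 predictors is optimistic for small regions; the
permutation null absorbs this but the *fitted* R² of a small region
overstates its planted value. The ANOVA treats the 2,706 cells as
independent observations. Activation maps lack spatial autocorrelation, so
the permutation null here is exactly exchangeable — with real, spatially
smooth maps it is mildly anti-conservative (spin/variogram nulls would be
the stricter alternative and are out of scope).
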