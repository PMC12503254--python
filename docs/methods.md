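# Methods

This note documents the statistical model, the numerical conventions, the
synthetic-data generator that stands in for the restricted-access cohort,
and the design choices made where more than one reasonable convention
exists.

## Canonical decomposition

The two phenotype blocks are column-centered and reduced by economy QR;
the SVD of `Q1' Q2` gives the canonical structure, and weights are
back-solved through the triangular factors so scores are exact linear
images of the data.  This is algebraically the classical CCA solution (the
singular values of the whitened cross-covariance); the QR route is used
because it is numerically stable at n ≫ p, q and makes the permutation
shortcut below exact.  Equivalence with the generalized-eigenproblem
formulation is asserted to 1e-8 over randomized instances in the tests.

Conventions:

* **Centering** is part of the fit.  Residualization against an
  intercept-bearing confound design already centers, so the second
  centering is a no-op in the standard pipeline.
* **Rank rule.**  The number of components is the numerical rank of
  `Q1' Q2` at tolerance `max(p, q) · eps · S[0]`.  A rank-deficient block
  (duplicated or collinear columns) triggers a fallback to an SVD basis
  with a warning and a reduced component count.
* **Explained covariance** is `S_i² / Σ S_j²`: the squared singular values
  of the basis cross-product are the only fitted quantities whose
  proportions decompose the cross-block covariance.
* **Sign orientation.**  SVD axes have arbitrary sign; each component is
  flipped so its largest-|loading| sleep variable loads positively, with
  U, V, weights and loadings flipped coherently.  The operation is
  idempotent and leaves all paired correlations unchanged.
* **Composite scores** average the z-scored canonical variates of the two
  sides; population (ddof 0) standard deviations are used throughout.

## Family-restricted resampling

Subjects in twin cohorts are not exchangeable.  All resampling treats
whole families as units:

* **Permutation.**  Families swap positions only with families of the same
  structure signature (relatedness class + size); members additionally
  shuffle within their family.  Permutations are sampled uniformly (shuffle
  family order within each signature group, then members within each
  family), not enumerated.  Only the rows of Y are permuted — equivalent in
  distribution to permuting either block, and half the bookkeeping.
* **Permutation shortcut.**  Row-permuting an orthonormal basis leaves it
  orthonormal, and centering is permutation-invariant, so the refitted
  canonical correlations for a permuted Y are exactly
  `svdvals(Q1' Q2[perm])`.  No per-permutation QR is needed; equality with
  a literal refit is asserted in the tests.
* **Per-component null.**  The i-th observed correlation is compared with
  the i-th permuted correlation across permutations;
  `p = (1 + #{null ≥ obs}) / (1 + n_perm)` so p is never zero.  Joint
  (Wilks-type) statistics are out of scope.
* **Bootstrap** resamples whole families with replacement.  Each
  replicate's components are matched to the original model by greedy
  maximum |correlation| between concatenated weight vectors (deterministic
  lowest-index tie-break, injective by construction) and sign-aligned
  before loadings are recorded.  Axis reordering and reflection are the
  dominant failure modes of naive CCA bootstraps; the matching step is
  tested by shuffling and flipping a fitted model's own weights.
  Replicates with a zero-variance column (possible with ordinal sleep
  columns) are discarded and redrawn, with a count kept.
  `z = loading / bootstrap sd`; two-sided normal p-values are BH-FDR
  corrected within each component.
* **Cross-validation** assigns whole families to folds (shuffled, then
  greedily balanced by subject count).  The confound regression and the
  CCA are refit on training subjects only; held-out blocks are
  residualized with training coefficients and projected through training
  weights.  Significance uses 1,000 block-valid permutations of held-out
  rows against the across-fold mean correlation.  A degenerate
  train-equals-test single-fold mode exists for testing and reproduces the
  in-sample canonical correlations exactly.

BH-FDR is a hand-implemented step-up (`q_(i) = min_{j≥i} m p_(j) / j`,
monotone, capped at 1); it is checked exactly against both a brute-force
oracle and statsmodels on randomized p-vectors.

## Connectome stage

* **Censoring.**  A frame is an outlier if FD > 0.2 mm or DVARS > 75; one
  frame before and two after are censored too; surviving segments shorter
  than 5 contiguous frames are dropped; a run with more than 50% censored
  frames is excluded.  The 12-frame single-outlier worked example (5 kept
  frames, run excluded) is asserted exactly.  Correlation matrices are
  Fisher z-transformed and averaged element-wise over retained runs.
* **Edge GLM.**  Confounds are regressed out of the edge responses first,
  then each unique upper-triangle edge is regressed on the standardized
  composite score ([intercept, score] design).  The reported F is the test
  of the score coefficient (intercept excluded), so F = T² with
  (1, n − 2) degrees of freedom.  Pre-residualizing the edges is
  equivalent to including the confounds as covariates in one model
  whenever the score is also orthogonalized to the confounds — which holds
  in the standard pipeline because the composite is built from
  residualized blocks.
* **Network aggregation.**  Cortical parcels carry their fine (17-network)
  label; all subcortical parcels collapse to one group, giving an 18 × 18
  matrix whose diagonal holds within-network means (off-diagonal edges
  only).  BH-FDR runs across the 171 unique network pairs; edge-level
  betas are reported unthresholded.  A singleton group's within value is
  undefined and recorded as missing with a warning.

## Graph metrics

Computed on each LC's signed edge-beta matrix.  Weights are taken in
absolute value and scaled by the maximum magnitude (a signed variant is
exposed as a flag but untested — participation is ill-defined for negative
strengths).  Module-degree z uses the population (n) standard deviation,
matching the reference toolbox convention; modules of size 1 or zero
spread get z = 0 with a warning.  The integration/segregation ratio
min-max normalizes both per-parcel vectors and forms
`(norm within_z + ε) / (norm participation + ε)` with ε = 1e-6 — the
within-z is signed, so ratio-of-raw-values would be undefined; the ε keeps
the extremes finite and preserves the ordering.

## The synthetic generator

The generator emulates the study conditions rather than the cohort's
marginals: a 770-subject default with 7 ordinal sleep columns and 118
biopsychosocial columns; families 20% MZ pairs, 20% DZ pairs, 20% sibling
pairs, 40% singletons (chosen to keep pair counts even at the default
sizes; a 60% paired fraction is typical of twin-enriched cohorts); age
uniform [22, 36] years, sex Bernoulli(1/2), education integer [11, 17].

Planted structure: per component, a sleep-side latent and a
biopsychosocial-side latent correlated at the planted value; both carry an
equicorrelated within-family component (one rho, default 0.5 — the
simplest structure that makes naive permutation invalid).  Blocks are
`latents @ unit-norm weights' + linear confound effects + iid noise`, and
sleep columns are then discretized to 0–3 at the quartile cut-points of
the standard normal, mimicking PSQI sub-component coding.  Connectivity
matrices are symmetric zero-diagonal noise with designated edges equal to
`beta × composite score + noise`.

Default noise levels are (0.2, 0.3) for the sleep/biopsychosocial blocks,
calibrated once so the planted structure is detectable but not trivially
strong.  All generators are pure functions of (config, seed); planted
weights draw from a separate `planted_weights_seed` so replicate cohorts
can share ground truth.

**What the generator does not emulate:** the real measures' marginal
distributions, item-level missingness, any nonlinear sleep–outcome
relationships (e.g. the U-shape in sleep duration), BOLD time series,
hemodynamics or realistic motion (frame traces are threshold fixtures
only).  Passing tests therefore demonstrate correctness of the machinery
under the planted linear-Gaussian-ordinal model, not robustness to real
phenotype distributions.

## Problem sizes and two estimation-floor effects

Two finite-sample properties of CCA shaped the validation design; both
are visible in the tests and neither can be removed by tuning:

* **Null inflation.**  Sample canonical correlations between independent
  blocks concentrate near `sqrt(p/n) + sqrt(q/n)`-scale values, not zero
  (≈ 0.46 for p = 7, q = 118, n = 770).  A planted correlation of 0.4
  cannot be recovered unbiasedly below that floor, so the planted-truth
  recovery study runs at a biopsychosocial width of 30, where the floor
  sits safely below both planted values.  This inflation is also why
  explained-covariance concentration (> 0.99 for one dominant component)
  is demonstrated on small blocks at large n, and why the permutation
  null "not centered at zero" is the correct reference.
* **Weight noise.**  Individual-replicate weight estimates for a weak
  component are noisy in proportion to `(1 − ρ²)/ρ · sqrt(q/n)`; weight
  directions are therefore validated on the average of sign-aligned
  fitted weights across 20 replicate cohorts sharing the same planted
  weights, where replicate noise cancels and systematic bias would
  remain visible.

Calibration studies use deliberately scaled problem sizes chosen for tight
Monte Carlo error at reasonable cost: type-I error with 200 replicates ×
500 permutations at n = 200 with the family dependence spanning the whole
sleep block (three zero-correlation latents, rho = 0.8 — a family effect
confined to one latent direction is diluted by the noise dimensions and
barely moves the maximal canonical correlation); FDR null discoveries with
50 replicates of 100 subjects × 40 parcels.

## CLI surface

The pipeline runner exposes `simulate`, `run` and `report`; the individual
analysis stages (CCA, permutation, bootstrap, cross-validation, brain
maps, graph metrics) are addressed through `run --stages …`, which re-runs
any subset against the same on-disk artifacts, rather than as separate
subcommands.  All randomness flows from named seeds recorded in the run
manifest; reruns with identical config and seeds are byte-identical.

## Known limitations

* Loadings' bootstrap significance uses a normal approximation on
  `loading / sd`; percentile intervals are not implemented.
* The PCA pre-reduction control variant is exposed as a config flag but
  untested.
* Post hoc association tests use pooled-variance t-tests (the classical
  t² = F identity); Welch corrections are not offered.
* The edge GLM assumes pre-computed per-run correlation matrices; nothing
  upstream of them (time-series preprocessing) is in scope.
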