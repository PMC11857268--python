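# Methods

## Model

`matlm` fits the bilinear model

```
Y = X B Zᵀ + E,     y_ij = Σ_k Σ_l x_ik z_jl b_kl + e_ij
```

for an n × m response `Y` (samples × metabolites), sample design
`X` (n × p), metabolite design `Z` (m × q) and coefficients `B` (p × q).
Rows of `E` are independent with mean zero and a common m × m covariance
Σ, i.e. `Var(vec(E)) = Σ ⊗ I`: metabolites may be arbitrarily correlated
within a sample, samples are exchangeable given X. Least squares gives
the closed form

```
B̂ = (XᵀX)⁻¹ Xᵀ Y Z (ZᵀZ)⁻¹
```

which simultaneously aggregates over samples (left factor) and over
metabolites sharing annotations (right factor). With `Z = I` the model
collapses to one ordinary regression per metabolite; `matlm` exploits
this both as a fast mass-univariate mode (`univariate_stats`) and as a
correctness oracle in the tests.

Implementation notes: the Gram matrices XᵀX and ZᵀZ are factorized by
Cholesky (a singular factor is reported with its rank and the offending
design named); explicit inverses are formed only for the p × p and q × q
matrices needed by the variance formula. Results agree with the
explicit-inverse formula to ~1e-12 on well-conditioned designs.

## Variance, tests, intervals

The coefficient covariance is the Kronecker-structured sandwich

```
Var(vec(B̂ᵀ)) = (XᵀX)⁻¹ ⊗ (ZᵀZ)⁻¹ ZᵀΣZ (ZᵀZ)⁻¹.
```

Only its p·q diagonal entries are ever materialized (as
`outer(diag((XᵀX)⁻¹), diag((ZᵀZ)⁻¹ZᵀΣ̂Z(ZᵀZ)⁻¹))`); with m ~ 10³ the
full (pq)² matrix would be large and is never needed for per-coefficient
inference.

Σ is estimated as `Σ̂ = RᵀR/(n − p)` from the residual matrix R. The
divisor n − p is chosen so that in the `Z = I` case the implied
per-metabolite variance is the classical unbiased OLS estimate
RSS_j/(n − p). An optional ridge term ε·I (default 0) is available for
near-singular Σ̂ when m approaches n; note that only ZᵀΣ̂Z (q × q) enters
the variance, so rank deficiency of Σ̂ itself is harmless for q « n.

t statistics are `t = b̂/se`, referred to the standard normal by default;
a `df` argument substitutes a Student-t reference (the package makes no
claim that n − p is the exact finite-sample df of this statistic, since
Σ̂ enters the sandwich). Two-sided p-values, `b̂ ± z·se` confidence
intervals. Degenerate cases: se = 0 with b̂ = 0 gives t = 0, p = 1;
se = 0 with b̂ ≠ 0 gives p = 0 and a logged warning.

Because the normal reference ignores the sampling noise of Σ̂, inference
is mildly anticonservative at small n: in the calibration experiments
below, 95% CIs cover at ~94% and the 5% test rejects at ~4–6%.

## Multiple testing

`adaptive_bh` implements the Benjamini–Hochberg linear step-up
(`variant="standard"`) and a two-stage adaptive variant: the number of
true nulls m₀ is estimated by the lowest-slope rule — scan
S_i = (1 − p_(i))/(m + 1 − i) over the sorted p-values until the first
decrease, then m̂₀ = min(m, ⌈1/S⌉ + 1) — and the step-up is applied at
level α·m/m̂₀. Whenever m̂₀ ≤ m the adaptive rejection set contains the
standard one; the adaptive variant is by construction more liberal, and
its q-values can fall below the raw p-values when m̂₀ « m. By default
q-values are computed across the full reported coefficient set of a run;
callers can restrict the scope (e.g. to one X covariate's row).

A subtlety worth documenting: appending an extra p = 1 to a p-vector
scales every step-up threshold by m/(m+1), so q-values weakly *increase*
and rejections can only be lost, never gained. Monotonicity in that
direction is what the tests assert.

## Permutation test

`permutation_pvalues` permutes whole rows of Y against the fixed X
(equivalent to permuting X's rows), refits, and uses the add-one
estimator `p = (1 + #{|t*| ≥ |t|})/(1 + n_perm)`, so the smallest
attainable p is 1/(n_perm + 1) and p is never zero. This scheme tests
the *global* null of no X effect; it does not condition on nuisance
covariates, so with confounded covariates in X a residual-permutation
scheme (not implemented) would be required. All draws flow through one
`numpy` generator seeded by the caller; results are bitwise reproducible
per seed.

## Design construction

* **X**: optional intercept first; categorical covariates contribute one
  indicator per non-reference level (reference = first level in sorted
  order, overridable); continuous covariates one column, optionally
  centered. Full column rank is verified at build time and the first
  linearly dependent column is named on failure.
* **Z**: numeric annotations are binned with half-open, left-closed
  intervals `[e_b, e_{b+1})` matching the conventional "a ≤ x < b"
  notation, with an optional open top bin `[e_B, ∞)`. An *unadjusted*
  Z is a single cell-means block (one 0/1 column per category, rows
  summing to 1, no intercept), so each coefficient is that category's
  effect. An *adjusted* Z codes the first variable as cell means and
  every later variable against its lowest bin / first level — two
  cell-means blocks would be singular since each row-sums to 1. The
  original studies' exact coding is not recoverable from their text;
  both codings are exposed, the block structure is recorded on the
  object, and `per_level_effects` re-expresses reference-coded blocks as
  per-level effects (reference ≡ 0) for comparability with cell-means
  output. Empty categories are dropped with a warning. The intercept
  lives in X only, keeping B entries interpretable as X-covariate ×
  Z-category interactions.

## Preprocessing

Pipeline order is impute → PQN → log; the CLI composes steps explicitly.

* **Imputation**: `half_min` fills a missing cell with half the
  metabolite's minimum observed value (a left-censoring heuristic);
  `knn` uses the mean of the k nearest samples by Euclidean distance on
  per-metabolite-standardized, co-observed values, normalized by overlap
  size, ties broken by sample order for determinism. Quantile-regression
  imputation of left-censored data (QRILC) is deliberately not
  reimplemented; half-min is the closest simple stand-in and this is a
  known fidelity gap for left-censored LC-MS missingness.
* **PQN** follows the full probabilistic-quotient recipe: spectra are
  first brought to a common integral, the reference spectrum is the
  per-metabolite median of those integral-normalized spectra, and each
  sample is divided by the median of its quotients against that
  reference. Computing the reference on integral-normalized spectra is
  what makes PQN *exactly* invariant to per-sample dilution and exactly
  idempotent — properties the tests check to 1e-10; a reference taken on
  raw columns satisfies neither.
* **Log transform**: base 2 (default), e or 10, with a nonnegative
  offset; any nonpositive shifted value is an error naming the cell.
* Batch correction is out of scope; batch labels can be included as X
  covariates instead.

## Synthetic data

`simulate_dataset` draws Y exactly from the model: X columns are binary
(given level probability) or Gaussian; annotations come from a plan that
also defines the generating Z (so `build_z` on the emitted annotation
table reproduces `Z_true` bit for bit); E has one of three covariance
families — diagonal, compound symmetry (sampled exactly via a shared
factor: √ρ·g_i + √(1−ρ)·noise), or AR(1) (stationary recursion along the
metabolite index). σ² = 0 is the noiseless limit. An optional scaled-t
row multiplier produces heavy-tailed errors for robustness demos.
Replicate r of any experiment uses seed + r.

The `TriglycerideZPlan` mimics lipidomics annotation structure: (total
carbon, double bond) integer pairs from a discretized Gaussian copula
with rank correlation 0.7 (defaults: carbon 40–81 binned at
40,45,…,70 with an open top; double bonds 3–14 binned at 3, 6, 9), so
the two binned designs are collinear the way chain length and
unsaturation are in real triglyceride panels. What the generator does
*not* emulate: batch drift, censoring at the detection limit,
mean–variance coupling, and outliers — so passing tests demonstrate
correctness of estimation and inference under the model's assumptions,
not robustness to every LC-MS artifact.

## Validation experiments (sizes as run by the tests and acceptance script)

* **Estimator**: 50 random small instances (n ≤ 8, m ≤ 6, p, q ≤ 3)
  against brute-force least squares on the vectorized Kronecker system
  (agreement ≤ 1e-9); normal-equation orthogonality on every fit;
  `Z = I` reduction against per-column OLS (≤ 1e-10).
* **Calibration**: global null with n = 100, m = 50, five annotation
  categories, Σ = I, 200 replicates — mean per-coefficient rejection at
  α = 0.05 within [0.03, 0.07]; entrywise 95% CI coverage under compound
  symmetry ρ = 0.3, n = 60, 500 replicates — within [0.92, 0.98]. The
  replicate counts make a single coefficient's Monte-Carlo rate noisy
  (sd ≈ 0.015), so the bands are asserted on the mean across
  coefficients.
* **Confounding separation**: 100 replicates of the triglyceride plan
  (n = 98, m = 770, true fish-oil effects (0, 0.5, 0.8) on the
  double-bond bins, none on carbon, CS ρ = 0.3). In the adjusted basis
  the carbon-block population coefficients are exactly zero (the true
  signal lies in the span of the double-bond block and the full-rank
  representation is unique), so the meaningful checks are marginal:
  each adjusted carbon 95% CI covers zero at its nominal rate (observed
  ~94%), while the unadjusted carbon-only model flags at least one
  spurious carbon category in ~100% of replicates. Joint all-six-CIs
  coverage and FDR-based call rates are reported alongside for
  transparency; note that six simultaneous uncorrected 95% intervals
  cannot jointly cover in ≫80% of replicates, which is a property of
  simultaneous inference, not of this estimator.
* **FDR / permutation**: standard BH against a brute-force O(m²) step-up
  on 1000 random vectors (exact agreement); adaptive ⊇ standard whenever
  m̂₀ ≤ m; permutation p-values under the global null (n = 40, m = 20,
  200 permutations, 100 replicates) have mean within 0.5 ± 0.05 and are
  bitwise reproducible per seed.
* **PQN**: dilution invariance and idempotence to ≤ 1e-10 on random
  positive matrices.

## Known limitations

* Missing responses must be imputed before fitting; there is no
  missing-data likelihood.
* Squared-error loss: sensitive to outliers; no robust or shrinkage
  estimation of B.
* The permutation scheme tests only the global null.
* The adaptive FDR variant's m₀ estimator is one defensible choice among
  several; the standard step-up is always available and the variant used
  is recorded in run manifests.
* Real published enrichment tables from the original cohort studies
  depend on access-controlled data and unstated modeling choices; the
  package validates against its own generative model and the published
  contingency tables instead.
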