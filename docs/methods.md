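# Methods

## The estimation model

`farmbayes` fits, by single-site Gibbs sampling,

    y = 1 m + X b + V f + Z g + e,

where `y` holds one adjusted phenotype per cow (the average of her
fixed-effect-corrected test-day milk records, L/d), `m` is the overall mean,
`X b` optional extra fixed effects (e.g. a three-level production-environment
factor), `f ~ N(0, I σ_f²)` random farm effects, `Z` the column-standardized
dosage matrix, and `e ~ N(0, E σ_e²)` with `E = diag(1/w_i)`.

Weights address the heteroscedasticity of averaged repeated records: a cow
with `r_i` records and single-record heritability `h²`/repeatability `t`
contributes with

    w_i = r_i (1 − h²) / (1 + (r_i − 1) t − r_i h²),

which is 1 for a single record and rises to `(1−h²)/(t−h²)` as `r_i → ∞`.
Defaults `h² = 0.19`, `t = 0.60` are standing estimates for crossbred Indian
dairy cattle; with `r = 18` records the weight is 1.874. Every full
conditional in the sampler uses `w`-weighted cross-products and the residual
variance scale is `Σ w_i e_i²`, so disabling weights is the special case
`w ≡ 1` of the same code path.

### SNP-effect priors

* **bayesr** — `g_j` belongs to one of four components with variances
  `{0, 1e-4, 1e-3, 1e-2} × σ²`, where `σ²` is a common variance parameter
  updated each iteration from a scaled-inverse-chi-square full conditional
  over the current nonzero effects (`Σ g_j²/γ_k`). Component membership is
  sampled in log space from the marginal-likelihood ratios against the zero
  component; proportions `π` get a Dirichlet(1,1,1,1) prior.
* **bayesc** — the exact two-component restriction `(0, σ²)`, with `σ²`
  interpreted per marker.
* **rrblup** — one normal component, inclusion fixed at 1: ridge regression
  on standardized markers, i.e. GBLUP estimated by the same Gibbs machinery.

Variance components (`σ²`, `σ_f²`, `σ_e²`) carry scaled-inverse-chi-square
priors with df 4; prior scales partition `var(y)` as 15% genetic, 30% farm,
remainder residual (configurable). Fixed effects are sampled with a flat
prior; the overall mean is always a column. Farm effects are conditionally
independent given the residual, so they are drawn jointly in a vectorized
step. Per-chain seeds are fixed offsets of the master seed, making
multi-chain runs reproducible.

### Reported quantities

The additive genetic variance of a draw is the realized variance of the
genetic values, `var(Z g)` — parameterization-free and recoverable in O(n)
from the maintained residual (`Z g = y − X b − V f − e`). Heritability is
`h² = σ_g²/(σ_g² + σ_e²)`; the farm variance is excluded from the
denominator, because with `σ_f² = 3 σ_g²` a heritability of 50% would
otherwise be unreachable. A marker's posterior inclusion probability (PIP)
is the fraction of retained draws in which it occupied a nonzero component.
Retained draws per chain are `floor((iterations − burn_in)/thinning)`.

The SNP sweep is compiled with numba; randomness is pre-generated per
iteration from one NumPy Generator, so a run is a pure function of its
inputs and seed. An invariant enforced in the tests: recomputing
`e = y − Xb − Vf − Zg` from scratch after a run matches the incrementally
maintained residual to 1e-8 relative tolerance.

## GBLUP oracle

`gblup.build_grm` forms `G = Z Z′/m` from standardized dosages;
`gblup.solve_mme` solves the weighted mixed-model equations in the variance
(GLS/BLUP) form `V = σ_g² G + σ_f² F F′ + σ_e² diag(1/w)`, which needs no
`G⁻¹` — a GRM built from sample-centered genotypes is exactly singular along
the all-ones vector. Two identities are enforced in tests: the MME solution
zeroes the gradient of the penalized weighted least-squares criterion, and
SNP-BLUP ridge with `σ_b² = σ_g²/m` reproduces the GRM-based GEBV to 1e-6.
With fixed variance components the rrblup-prior Gibbs posterior mean
converges to the same solution (correlation > 0.99 on 200 × 400 instances),
which is the main correctness oracle for the sampler.

## Test-day pre-adjustment

Raw test-day records are corrected in two stages. Stage 1 fits, by least
squares with reference-level coding: cattle development center (CDC),
season, CDC×season, parity, and third-order Legendre lactation curves
(days-in-milk mapped from [5, 305] to [−1, 1]) nested within parity (all
levels) and within CDC (non-reference levels — the reference curve lives in
the parity block, keeping the design full rank). Rank deficiency beyond the
reference constraints raises an error naming the confounded columns. Stage 2
predicts farm effects by ridge shrinkage of per-farm residual means with
`λ = 1/ratio`, `ratio` defaulting to 3 (the assumed farm-to-residual
variance scale). Adjusted records are `y − (fixed prediction − intercept)`,
averaged per cow; farm effects are deliberately not subtracted, since they
are modeled as random downstream. A cow's production environment is the sum
of her CDC fixed effect and farm prediction; cows are ranked (ties broken by
cow id) and split into low/medium/high terciles whose sizes differ by at
most one.

This module re-implements the *described* adjustment terms as a testable
two-stage procedure; it does not claim to reproduce any particular fitted
adjustment from field data.

## Synthetic data

The generator emulates the features of a smallholder crossbred population
that drive the estimation problem; all defaults are the study conditions:

* **Genotypes** — a two-ancestry Balding–Nichols admixture model: ancestral
  frequencies uniform above a MAF floor (0.05), ancestry-specific
  frequencies Beta-drifted with divergence 0.1, individual admixture
  proportions Beta(6.3, 3.7) (mean 0.63 exotic / 0.37 indigenous), dosages
  Binomial(2, individual frequency). No linkage disequilibrium beyond the
  ancestry-induced correlation is simulated — a documented limitation: real
  chromosomes carry local LD that supports marker-QTL tracking, so absolute
  prediction accuracies here are not comparable to array data.
* **QTL effects** — `n_causal` markers drawn uniformly; effects from the
  mixture 0.80·N(0, 1e-4) + 0.15·N(0, 1e-3) + 0.04·N(0, 1e-2) +
  0.01·N(0, 1e-1) (per-causal variance 1.63e-3). Causal markers stay in the
  estimation marker set by default.
* **Farms** — sizes from a zero-truncated Poisson whose *truncated* mean is
  the target (the rate solves `λ/(1−e^{−λ}) = target`, so a mean of 1 —
  every cow alone — is attainable); grid means 1, 2, 5, 20.
* **Phenotypes** — breeding values `Z a`, with `σ_g²` their empirical
  variance; farm effects `N(0, 3 σ_g²)`; residuals `N(0, σ_e²/w_i)` with
  `σ_e² = σ_g²(1−h²)/h²` and `w_i` from the record-count weights
  (zero-truncated negative binomial counts, mean 18). Heteroscedastic
  residuals are the default because they are the only reading consistent
  with accurate heritability recovery under weighted estimation: generating
  homoscedastic residuals and then fitting with weights (mean weight ≈ 1.85)
  rescales the apparent residual variance and drags the heritability
  estimate far off target. The homoscedastic variant remains available via
  `heteroscedastic=False`.
* **Scenario grid** — 4 farm sizes × 3 heritabilities (10, 20, 50%) × 50
  replicates = 600 datasets; replicate seeds derive deterministically from
  the base seed; a failing fit is recorded as a failed row, not a crash.

## Cross-validation and metrics

Validation blocks on management groups: every animal of a group is entirely
in the reference or the validation set. The default fold rule fills `k−1`
folds to `⌈G/k⌉` groups and gives the last fold the remainder (87 groups in
10 folds → nine folds of 9 and one of 6); a balanced round-robin rule is the
alternative. Reference-set genotype standardization (allele frequencies) is
recomputed per fold and farm effects are re-indexed to reference farms, so
no information leaks from validation animals. Accuracy is the Pearson
correlation of held-out phenotype and GEBV; bias is the OLS slope, by
default of phenotype on GEBV (slope 1 = unbiased) with the reverse
regression available as an option, since both conventions appear in the
field. Fold-level arithmetic means summarize a run.

Analytic benchmarks: mass-selection accuracy on `r` repeated records
`sqrt(r h²/(1+(r−1)t))` (0.55 at r=18, h²=0.19, t=0.60); heritability-
adjusted GEBV accuracy `r/√h²`; and breeder's-equation arithmetic
`100((acc_new/acc_ref)/interval_ratio − 1)` for the relative change in
genetic gain when the generation interval changes.

## Convergence diagnostics

The Brooks–Gelman multivariate PSRF is computed on the variance components
plus fixed effects (SNP effects excluded for dimensionality):
`MPSRF = sqrt((n−1)/n + (m+1)/m · λ_max(W⁻¹B/n))`. The implementation
matches R's `coda::gelman.diag(..., multivariate=TRUE)` to 6 decimals on a
shared fixture (a test runs the comparison through Rscript). Runs above a
1.1 threshold are flagged.

## Problem sizes and numerical choices

The package targets desk scale: the reference experiment in
`scripts/acceptance.py` uses 1,000 animals × 2,000 markers, 200 causal
variants and chains of 3,000 iterations (1,000 burn-in, thinning 5), 10
replicates per scenario; all dense linear algebra is direct (no iterative
solvers). Monomorphic markers are dropped with a logged count; missing PLINK
genotypes are mean-imputed (rounded to a valid dosage) below a configurable
missing-rate ceiling; the GRM Cholesky falls back to a trace-scaled 1e-8
jitter if needed.

## Known limitations

* **Weak-identification floor of the mixture prior.** With m ≈ 2,000
  markers, the smallest nonzero component (1e-4·σ²) is nearly invisible to
  the likelihood: under the uniform Dirichlet prior roughly half the null
  markers occupy it in any draw, propping up `var(Z g)` and hence the
  posterior heritability. On null data the posterior h² floor is ~0.1 at
  n = 300 and falls to ~0.02 by n = 1,500; in the low-signal scenario
  (h² = 0.2, farm size 2) the posterior mean sits ≈ 0.06 above the truth at
  n = 1,000, while an independent REML cross-check on the same data centers
  on the truth with a much wider spread. At realistic marker densities
  (tens of thousands) the component becomes identifiable and the effect
  vanishes. Strong-signal scenarios (h² = 0.5, large farms) are unaffected.
* No LD simulation (above); no breed-of-origin effects; no single-step
  (pedigree + genomic) evaluation; no forward/temporal validation.
* The test-day adjustment is a re-implementation of the described model
  terms, not a refit of any proprietary field dataset.
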