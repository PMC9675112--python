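# Methods

This note documents the statistical machinery in `npbmix`: the models, the
priors and their defaults, the sampler, the exposure-assignment chain, what
the synthetic cohort does and does not emulate, and the numerical choices
made where the design was genuinely open.

## 1. The NPB model and its priors

The outcome model is the Gaussian linear model

y_i | β, ζ, γ, σ² ~ N(y₀ + x_iᵀβ + z_iᵀζ + w_iᵀγ, σ²),

with x the standardized exposure block, z the pairwise-interaction block
(products of standardized/indicator columns), and w the covariate block.
Internally the outcome is centered and scaled by its sample SD for
sampling; all reported draws are back-transformed to native units (grams,
or percentage points of fat mass), so exact zeros stay exact zeros and
coefficients read as outcome units per 1 SD of exposure.

Selection priors. Main effects β and interaction effects ζ each receive
their own zero-spiked Dirichlet process:

- β_j ~ G₁, G₁ ~ DP(α₁, G₀),  ζ_j ~ G₂, G₂ ~ DP(α₂, G₀),
- base measure G₀ = π₀ δ₀ + (1 − π₀) N(0, τ²).

A draw from the spike is exactly 0 (no epsilon thresholding anywhere), so
the posterior inclusion probability of a term is the fraction of retained
draws in which its coefficient is nonzero. The DP's clustering assigns
correlated exposures with similar effects a single shared atom, reducing
variance under multicollinearity. Interactions are selected by their own
DP with no strong-heredity constraint: an interaction can have PIP near 1
while both parent main effects sit in the spike — which is precisely the
qualitative pattern the method is designed to be able to report.

Hyperpriors and defaults (all surfaced in `NPBConfig`):

| parameter | meaning | default | rationale |
|---|---|---|---|
| τ (`slab_sd`) | slab SD of nonzero atoms, standardized-outcome scale | 1.0 | weakly informative: a 1-SD-of-outcome effect per SD of exposure is already enormous |
| (a_π, b_π) | Beta prior on spike mass π₀, per block | (1, 1) | uniform; the data decide sparsity |
| (a₁,b₁), (a₂,b₂) | Gamma priors on DP concentrations α₁, α₂ | (1, 1) | center of the sensitivity grid {0.5, 1, 2, 4} |
| c (`covariate_prior_sd`) | Normal prior SD on γ and intercept, standardized scale | 10 | effectively flat |
| (a_σ, b_σ) | inverse-gamma prior on σ² (standardized scale, s²_y = 1) | (0.5, 0.5) | unit-information-style, weak |
| n_iter / n_burn / thin | chain length | 25 000 / 5 000 / 4 | ≥ 5 000 retained draws, PIP MC error ≈ 0.007 |

## 2. The Gibbs sampler

Every update is conjugate:

1. **Cluster assignment** (per block, per coefficient): collapsed
   Polya-urn. One distinguished spike cluster (slot 0, atom exactly 0) per
   block; the weight for landing on zero pools current spike occupancy with
   the base measure's atom, (n_spike + α π₀)·N(r_j | 0); an existing slab
   cluster k has weight n_k·N(r_j | θ_k x_j); a new slab cluster has weight
   α(1 − π₀) times the closed-form marginal with θ integrated against
   N(0, τ²) (Sherman–Morrison / matrix-determinant-lemma form). A new slab
   cluster's atom is drawn from its single-observation posterior.
2. **Atom updates**: each slab cluster's atom from its Normal full
   conditional given the summed member columns.
3. **Covariates and intercept**: joint Normal full conditional for γ
   (Cholesky of WᵀW/σ² + I/c²).
4. **Error variance**: inverse-gamma full conditional.
5. **Concentrations α₁, α₂**: Escobar–West (1995) auxiliary-Beta mixture
   update, with k = number of occupied clusters in the block (the spike
   counts once when occupied).
6. **Spike masses π₀**: Beta(a_π + #coefficients in spike, b_π +
   #coefficients in slab) per block. In the collapsed single-spike
   representation the exact DP conditional on π₀ is not available in closed
   form (the number of distinct zero draws from G₀ is not tracked);
   counting coefficient memberships is exact in the independent
   spike-and-slab limit and behaves as a slightly data-dominated conditional
   for the DP. The hyperprior sensitivity sweep covers the practical
   consequences.

The per-coefficient inner loops are numba-compiled; a single
`numpy.random.Generator` seeded from `NPBConfig.seed` drives every draw, so
fits are bit-reproducible. Runtime on one CPU is about 1 ms per iteration
for the full 21-main + 210-interaction, n = 897 problem.

`mode="independent_spike_slab"` replaces step 1–2 with the cluster-free
limit (each coefficient independently spike or slab); with σ², π₀, τ fixed
this is the model whose PIPs `exact_spike_slab_pip` computes by exhaustive
enumeration of all 2^p zero/nonzero patterns (closed-form Gaussian
marginals; refused above p = 12). The sampler-vs-enumeration agreement
(±0.02 at ≥ 20 000 retained draws) is the package's core correctness check
for the selection machinery.

Posterior summaries are model-averaged: means include the exact zeros, and
the 95% intervals are equal-tailed empirical quantiles (so an interval can
straddle zero while the PIP is high, and a selected term's interval is the
model-averaged one). `convergence_report` delegates ESS and split-chain
R-hat to arviz, with ESS floored at 1.0 for constant chains.

## 3. Exposure assignment (kriging chain)

Daily monitor readings → biweekly per-monitor metrics → ordinary kriging to
target points → day-weighted pregnancy averages.

- **Metrics**: 24-h means for PM₂.₅ and temperature; for ozone the mean of
  daily 8-h maxima. A day contributes an 8-h max only with ≥ 18 of 24
  non-missing hours; a window mean needs ≥ 6 of its 8 hours (EPA-style
  conventions; the data convention is otherwise unstated). A biweek needs
  ≥ 1 valid day — deliberately lenient to avoid cascading missingness.
- **Calendar**: consecutive 14-day blocks anchored at 2009-01-01.
- **Variogram**: classical binned (Matheron) empirical semivariogram;
  weighted least squares fit (weights = pair counts) of nugget, partial
  sill, and range; exponential family by default (smooth in its parameters
  and the conventional choice for air-pollution fields), spherical
  available.
- **Kriging**: global ordinary kriging with a Lagrange multiplier; weights
  sum to 1 by construction. The semivariance function has γ(0) = nugget, so
  the nugget acts as measurement-error variance (non-exact kriging); with
  nugget = 0 predictions interpolate monitor values exactly. Co-located
  monitors are averaged before solving so the system is nonsingular;
  kriging variance is clamped at 0 (logged) if round-off drives it
  negative.
- **Pregnancy averages** weight each overlapping biweekly prediction by its
  days of overlap with [conception, delivery], and are therefore bounded by
  the contributing biweekly values.

Coordinates are projected planar km with Euclidean distances — adequate at
metro scale, not for continental domains.

## 4. Design matrices

Continuous columns are standardized with the sample SD (n − 1); each
`ScaleRecord` retains center/scale so effects can be reported per SD and
back-transformed. Categorical covariates are reference-coded indicators
(race/ethnicity ref = White non-Hispanic, education ref = less than high
school, season ref = winter, first conception year as reference);
pre-pregnancy BMI enters as continuous; infant sex is included by default;
longitude, latitude, and their product guard against residual spatial
trend; days-to-measurement is appended only for the adiposity outcome.

Interactions comprise every unordered exposure pair once plus every
exposure × interaction-eligible covariate column, where eligible means
every W column except the intercept and the lon × lat product (itself an
interaction). Indicator-level granularity was an open choice; interacting
with each indicator column keeps the design a pure column-product
expansion (21 exposures and 24 eligible covariate columns give
210 + 504 = 714 interaction terms for the birth-weight model). Column
order inside Z is lexicographic by term name, so the layout is independent
of input ordering.

## 5. The synthetic cohort

`simulate_cohort` emulates the data structure the analysis assumes, not any
real family's data:

- **Exposures**: Gaussian copula with Normal marginals matching the
  published per-exposure means/SDs (21 exposures, 12 environmental +
  9 social). Pairwise correlations are drawn uniformly per block —
  environmental–environmental in [−0.5, 0.7], social–social in
  [−0.1, 0.9], cross-block in [−0.3, 0.5], mirroring the published ranges —
  then projected to the nearest correlation matrix (Higham alternating
  projections). The full true correlation matrix of the original cohort is
  not public, so the target is a draw from the stated ranges, held fixed by
  its own seed and exposed via `SimulationConfig.correlation_matrix()`.
- **Covariates**: categorical frequencies matching the published cohort
  table; maternal age, stress and depression scores Normal with the
  published moments; BMI continuous Normal(25.7, 5.6) truncated to
  [15, 55]; conception dates uniform over 2009–2014 with gestation
  Normal(275, 13) days truncated to [196, 301].
- **Outcome**: birth weight = 3208 + Σ effects × population-standardized
  predictors + N(0, 450²) g. Planted defaults reuse the published
  posterior means as simulation truth: ozone −6.4 g/SD, temperature
  +13.1 g/SD, ozone × temperature −162 g/SD·SD. Product predictors are
  centered by their population mean so the planted effects never move the
  cohort mean (the shift would only land in the intercept). Standardizing
  by *configured* rather than sample moments makes the per-SD truths exact
  at any n.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: skewed marginals (real distances and rates
are right-skewed; the analysis standardizes everything, so Normal marginals
exercise the same code paths), spatial autocorrelation of exposures across
real census tracts, missing-data patterns (generated data are complete),
measurement error in exposures, and any nonlinearity in the
exposure–response surface (the NPB model itself is linear; the original
analysis used separate additive models for that question, out of scope
here).

`simulate_monitors` draws i.i.d. daily replicates of a stationary isotropic
Gaussian random field (exponential or spherical covariance plus nugget) at
uniformly placed sites — enough to validate the kriging chain, with no
temporal correlation.

## 6. Problem sizes and numerical choices

- Repeated-seed studies (planted-effect recovery, null calibration,
  sensitivity sweep) run at the published scale n = 897 with all 210
  exposure-pair interactions but exclude the 504 exposure × covariate
  products, and use shortened chains: 2000/500/1 for recovery and the
  sweep-style runs, 6000/1000/2 for null calibration. The longer null
  chains matter: out of a short burn-in the main-effect DP block can
  transiently hold several correlated exposures in a shared weak slab
  cluster, inflating PIPs; the state dissolves with adequate chain length.
  Exposure × covariate interactions and the full chain defaults are
  exercised in unit tests and available in the pipeline config.
- Degenerate inputs: constant columns are rejected by name at
  standardization; all-zero design columns are rejected by name before
  sampling; a slab atom proposing exactly 0 (measure-zero event) stays a
  slab cluster — spike membership happens only through assignment.
- Selection threshold: strictly PIP > 0.5, so a term at exactly 0.5 is not
  reported.
- CV is reported as a rounded whole percent (floor(x + 0.5)), matching how
  such tables are printed.
- Wald 95% CIs in the baselines use the normal 1.96 quantile; at n ≈ 900
  the t correction is < 0.2% of the interval width.
- Stratified runs drop the stratifier's indicators from W, keep the
  geography terms by default (configurable), and skip strata below n = 30
  with a logged warning.

## 7. Known limitations

- The π₀ update in the DP mode is the pragmatic membership-count
  conditional described above, not the (unavailable) exact collapsed-state
  conditional.
- Permutation equivariance of the sampler holds statistically (verified
  within MC error), not bit-for-bit, because one RNG stream serves all
  coefficients in update order.
- Ordinary kriging is global (all monitors in every prediction) with a
  single pooled variogram across biweeks; no universal or space–time
  kriging, no cross-validated model selection.
- Non-Gaussian outcomes, more than two selection blocks, and heredity
  constraints are out of scope by design.
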