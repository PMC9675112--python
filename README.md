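# npbmix

Non-parametric Bayes shrinkage for neighborhood exposure mixtures and
neonatal outcomes.

Environmental epidemiology increasingly asks not "does pollutant X lower
birth weight?" but "which components of a correlated mixture of
neighborhood exposures — air pollution, temperature, built environment,
social stressors — drive an association, and do any act jointly?" Single
exposure regressions are confounded by co-exposures; ordinary
multipollutant regression suffers multicollinearity and variance inflation.
`npbmix` implements the non-parametric Bayes (NPB) shrinkage answer: a
Gaussian linear model whose exposure coefficients carry a **zero-spiked
Dirichlet-process prior**, giving simultaneous variable selection (exact
zeros), shrinkage, and clustering of similar effects, with a second DP
selecting among all pairwise interactions.

The package is aimed at biostatisticians and exposure scientists who want a
tested, reusable implementation of the whole analysis chain: kriging-based
exposure assignment, design-matrix construction, the NPB Gibbs sampler,
single-exposure baselines, stratified (effect-modification) runs, and a
hyperprior sensitivity sweep — exercised end to end on a seeded synthetic
cohort that emulates a Denver-area pre-birth study (n ≈ 897 dyads,
21 census-tract exposures, birth weight in grams as the primary outcome).

## The model

For dyad *i* with standardized exposures *x*ᵢ (p = 21), pairwise
interactions *z*ᵢ, and covariates *w*ᵢ:

```
yᵢ | β, ζ, γ, σ² ~ N(y₀ + xᵢᵀβ + zᵢᵀζ + wᵢᵀγ, σ²)

βⱼ ~ G₁,  G₁ ~ DP(α₁, G₀)        G₀ = π₀ δ₀ + (1 − π₀) N(0, τ²)
ζⱼ ~ G₂,  G₂ ~ DP(α₂, G₀)
γ, y₀ ~ N(0, c²)    σ² ~ Inv-Gamma(a_σ, b_σ)
α_b ~ Gamma(a_b, b_b)    π₀ ~ Beta(1, 1) per block
```

The point mass δ₀ in the base measure lets coefficients be *exactly* zero,
so the posterior inclusion probability (PIP) of term *j* is simply the
fraction of retained MCMC draws with βⱼ ≠ 0; a term is reported as
important when PIP > 0.5 (and flagged when its 95% credible interval also
excludes zero). The DP clusters coefficients with similar effects onto a
shared atom, which stabilizes estimation when exposures are strongly
correlated. The Gibbs sampler is fully conjugate (Polya-urn assignment with
a closed-form zero-spiked marginal, Escobar–West concentration updates) and
numba-accelerated; see `docs/methods.md` for every prior, update, and
default.

## Worked example

```sh
npbmix run -c demo.yaml
```

with `demo.yaml`:

```yaml
seed: 1
outdir: demo_run
stages: [simulate, design, fit-npb, fit-lm, report]
simulate: {n_dyads: 897}
design: {outcome_choice: birth_weight, interactions: exposure_pairs}
npb: {n_iter: 4000, n_burn: 1000, thin: 1}
```

This simulates a cohort of 897 dyads with the default planted truth —
ozone main effect −6.4 g/SD, temperature +13.1 g/SD, and an
ozone × temperature interaction of −162 g per SD·SD on top of 450 g
residual noise — builds the 21 + 210-term design, and fits NPB and the 21
single-exposure baselines. `demo_run/selection_report.csv` then contains
exactly one row:

```
term,block,mean,lo,hi,pip,...,interval_excludes_zero
o3:temperature,interaction,-150.8,-180.1,-121.4,1.0,...,True
```

i.e. the planted interaction is selected with PIP 1.00 and a credible
interval covering the true −162 g, while both weak main effects are
correctly shrunk to zero (PIPs ≈ 0.02). The single-exposure table
(`single_exposure.csv`) shows why the mixture model is needed: the ozone
baseline reports +36.0 g/SD (95% CI 4.5 to 67.4) — a confounded estimate
driven by correlated co-exposures, with no way to see the interaction.

The same pipeline exposes `simulate`, `krige`, `design`, `fit-npb`,
`fit-lm`, `stratify` (effect modification by maternal race/ethnicity),
`sweep` (Gamma hyperprior grid {0.5, 1, 2, 4}), and `report` subcommands;
everything is also available as plain library calls
(`npbmix.simulate_cohort`, `npbmix.build_design`, `npbmix.npb_fit`, ...).

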