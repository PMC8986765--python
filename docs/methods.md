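# Methods

## The estimand and the inference chain

The package quantifies the association between household wildmeat
consumption and child hemoglobin concentration in stratified Amazonian
subpopulations, and converts that association into counterfactual anemia
projections.  The chain is: (1) construct the analyzed cohort and classify
household vulnerability; (2) estimate the per-meal hemoglobin effect with a
mixed model; (3) shift each child's hemoglobin under a hypothetical meal
assignment and recompute prevalence; (4) scale the prevalence shift to
census populations.  Every stage is exercised end-to-end on synthetic
cohorts, so nothing requires restricted survey data.

## Synthetic cohort model

The generator emulates a two-wave survey of four river-dependent
municipalities: 800 urban and 311 rural households (the rural remainder
distributed near-evenly across municipalities), riverine communities nested
in rural municipalities (10 per municipality by default), and children aged
6 months to 5 years nested in households.  A household has children with
probability 291/800 (urban) or 145/311 (rural); child-bearing households
have one or two children with means 1.34 and 1.52 respectively.  These
child-count settings are back-computed from the cohort sizes the design
targets (291 households → 390 children urban; 145 → 220 rural) and are
assumptions, not measured quantities.

**Wildmeat consumption.**  A household is a 12-month consumer with
probability 0.83 (rural) or 0.67 (urban).  Conditional on being a consumer,
the 30-day meal count is negative binomial with dispersion 0.7 (rural) /
0.45 (urban), scaled so that the unconditional means are 7.1 and 1.3
meals/30 days — the values implied by mean weekly consumption of ≈1.65
days/week rural and ≈0.30 urban.  A consumer may report zero meals in the
last 30 days; a positive meal count implies 12-month consumption.

**Hemoglobin.**  For child *i* in household *h*, community *c*:

    Hb_i = μ(location) + Σ_j γ_j (x_ij − mean x_j within location)
           + β (meals_i − mean meals within MV-rural) · 1[MV rural]
           + u_c + u_h + ε_i

with σ_community = 0.3, σ_household = 0.5, σ_residual = 1.0 g/dL,
μ_rural = 10.61, μ_urban = 11.07 g/dL, and β = 0.05 g/dL per monthly meal
acting only in the most-vulnerable (MV) rural stratum.  Control-covariate
effects γ (age +0.12/yr, malaria −0.35, worms −0.25, maternal education
+0.03/yr, wet season +0.08, fluvial distance −0.002/km, household size
−0.02/member, small zero-sum municipality offsets, and an income gradient
of 0.13 g/dL per SD of log income) are applied *centered within location*,
and the meal effect centered within its stratum, so the configured location
means are exactly the marginal means of the generated hemoglobin.  That
choice is what lets replicate studies check the generator against its own
stratum means, and the income gradient is what makes the most-vulnerable
half of each location about 0.2 g/dL poorer in hemoglobin than the
least-vulnerable half.

**Introduction of wildmeat into child diets.**  Whether a child normally
eats wildmeat is Bernoulli with log-odds
`intercept(location) + log(2.4)·age + log(2.48)·migrant + v_h`,
v_h ~ N(0, 0.6²) a household-level effect.  The intercepts (−0.17 rural,
−2.09 urban) place the sharing probability near 0.67 at age one in rural
consuming households and near 0.63 at age three in non-migrant urban
households.  "Ever ate" uses the same linear predictor shifted by +1.2 and
a shared uniform draw, which guarantees the implication normally ⇒ ever and
a monotone age profile for both.  A child's meal exposure equals the
household's 30-day count if the child normally eats wildmeat, else zero —
the same rule the analysis applies, so generation and inference agree.

**Vulnerability at generation time.**  The stratum carrying β is defined by
income at or below the median of rural households *with children*, i.e. the
same set the analysis classifies.  Using the all-households median instead
would relabel a few near-median households and attenuate recovery.

**What the generator does not emulate.**  No species composition, harvest
amounts or spatial coordinates; no missing data; no measurement error in
hemoglobin; no correlation between meal counts and income within a
location; covariate effects are linear and additive.  Passing tests
therefore show that the *pipeline* recovers what it assumes, not that the
real-world association is causal or correctly specified.

## Cohort rules

* Vulnerability: within-location median split, ties to "most vulnerable"
  (the conservative direction for a protected group; the tie rule is
  config-free but documented).  Two schemes: monetary per-capita income,
  and a 0–100 scorecard of ten service/asset indicators worth 10 points
  each (electricity, piped water, sanitation, fridge, motorized vehicle,
  TV, mobile phone, gas stove, head completed primary, formal employment).
  The default scorecard is a synthetic stand-in implementing the named
  domains and is fully replaceable via YAML.  Because scorecard answers are
  Bernoulli with log-odds monotone in income, the two schemes correlate but
  disagree for some households.
* Anemia: hemoglobin strictly below 11 g/dL; exactly 11.0 is not anemic.
* Frequency categories: "at least monthly" ⇔ ≥ 1 meal/30 days, "at least
  weekly" ⇔ ≥ 4 meals/30 days; the cut points are arguments.

## Mixed-effects estimation

Gaussian hemoglobin models are linear mixed models with a household random
intercept, plus a community random intercept for rural fits, estimated by
maximum likelihood (`reml=False`) through statsmodels so that AICc is
comparable across fixed-effect subsets; a REML refit of a chosen model is
available via the `reml` flag.  A tiny-cohort test verifies the reported
log-likelihood against direct evaluation of the marginal multivariate
normal density.

Binomial models have no maximum-likelihood implementation in the Python
stack, so the marginal likelihood is computed here with a **Laplace
approximation**: per top-level cluster (community, or household when there
is no community level), the random-effect integral is replaced by a
second-order expansion around the penalized-likelihood mode, found by
damped Newton iterations; the outer optimization over fixed effects and
log-standard-deviations uses L-BFGS-B, with standard errors from a
finite-difference Hessian.  The approximation is named in the fit metadata
and AICc comparisons are only made within one approximation.  On shared
fixtures the implementation matches `lme4::glmer` (`nAGQ=1`, also Laplace)
to ~1e-3 in coefficients and log-likelihood.  Known behaviour of this
estimator with 1–2 children per household: the cluster variance is weakly
identified, so fits can drift a few percent from ordinary logistic
regression even when the true variance is zero, and with high base rates
the likelihood occasionally diverges in σ (cluster-level separation).
Fits whose variance estimate escapes toward the optimizer's box bound, or
whose Hessian is singular, are flagged `converged=False` and excluded from
model sets.

Standardization (mean 0, SD 1, sample SD with ddof=1) is applied to
non-categorical predictors; the stored transform converts every coefficient
back to natural units (g/dL per monthly meal, per year of age).  AICc is
`−2ℓ + 2k + 2k(k+1)/(n−k−1)` with k counting fixed effects plus variance
parameters (including the Gaussian residual).  All-subsets search
enumerates every fixed-effect subset (guarded at 20 candidates), ranks by
AICc and flags ΔAICc ≤ 2 as equally plausible; the per-meal estimate can be
read from the best model containing the meal term.  VIF is the classical
1/(1−R²) per numeric predictor.

Stratified fits mirror the study design: separate model sets per
location × vulnerability subpopulation rather than interaction terms;
private toilet is omitted from rural models (almost no rural household has
one) and fluvial distance from urban models (undefined there).

## Scenario engine

Counterfactual hemoglobin is `Hb + β(m − observed meals)` applied to the
target subpopulation; prevalence uses the strict 11 g/dL rule.  The
"observed" scenario reproduces the baseline exactly, and prevalence is
monotone nonincreasing in m for β > 0.  CIs use a percentile cluster
bootstrap resampling households with replacement (B = 10,000 by default,
seeded); households rather than children are resampled to respect
within-household correlation — the reference analysis does not state its
CI method, so this is the package's choice.  Relative changes are
100·(scenario − reference)/reference computed from unrounded prevalences
and reported to one decimal; computing from pre-rounded prevalences is a
caller option (both conventions are tested).  One published pairing of a
fixed-8-meals prevalence with a "19%" relative decrease is not arithmetically
consistent with its stated reference; the engine simply reports what the
arithmetic gives.

## Census scale-up

Grouped income classes bound the vulnerable-household fraction: the lower
bound uses no-income plus ≤ 1/8 minimum-wage households, the upper bound
adds the (1/8, 1/4] class; no-income households are included in both (they
are poorer than either threshold).  Vulnerable children per municipality =
children aged 6 months–5 years × rural fraction × household fraction, kept
fractional until reporting.  Growth adjustment multiplies counts by
pop_2019/pop_2010 uniformly.  Additional anemic children = vulnerable
children × prevalence shift (percentage points)/100, with headline values
rounded to the nearest hundred and raw values always emitted; aggregation
is a plain sum, so the aggregate case count is linear in the vulnerable
count.  The real 44-municipality census extract is not redistributable;
the module ships a seeded synthetic generator (Dirichlet class shares
concentrated in the poorest classes, so the bounds span roughly 50–80% of
households) plus a 4-row synthetic fixture so all tests run offline.

## Problem sizes and numerical choices

The acceptance study uses 120 replicate cohorts with a rural-focused design
(311 rural households, 16 communities, yielding ~105 most-vulnerable rural
children in ~70 households per replicate) — the scale at which the
per-meal coefficient was originally estimated; 100+ replicates put the
Monte-Carlo standard error of the mean estimate near 0.001 g/dL.  The
logistic odds-ratio recovery test uses larger rural samples (~290 children
per fit), where the Laplace estimator is in its stable regime.  Bootstrap
replicate counts in tests are a few hundred to a few thousand; the default
for reported results is 10,000.  Wald CIs use z = 1.96; Wilson bounds are
clamped to [0, point] / [point, 1] against floating-point excursions;
variance parameters in the binomial optimizer live in
log-space with σ ∈ [1e-4, 5].

## Limitations

* The counterfactual projections are conditional on the fitted coefficient
  and assume it is causal and linear in meals; the package makes no
  causal-identification claim.
* The scorecard and census fixtures are synthetic stand-ins; absolute
  numbers computed from them are illustrative, not estimates for any real
  municipality.
* Laplace-approximate binomial fits share the small-cluster biases of
  `glmer` at default settings; adaptive quadrature is not implemented.
* Survey weighting, missing-data handling and spatial autocorrelation are
  out of scope.
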