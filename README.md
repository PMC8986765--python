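# wildhb

Wildmeat consumption and childhood anemia in Amazonia: a tested, reusable
implementation of the inference chain linking household wildmeat meals to
child hemoglobin concentration and anemia prevalence in rural and urban
river-dependent populations.

Iron-deficiency anemia is the leading micronutrient deficiency in young
children, and in remote Amazonian communities wildmeat (terrestrial game) is
one of the few iron-rich animal source foods that poor households can
access.  `wildhb` is aimed at epidemiologists and conservation scientists
who want to quantify what access to wildmeat means for child health: it
estimates the hemoglobin–consumption association in stratified
subpopulations and projects what anemia prevalence would look like under
counterfactual consumption scenarios, scaled up to census populations.

## What it implements

* **Synthetic cohort generator** — seeded household/child tables with the
  survey's nested structure (children in households, households in riverine
  communities and municipalities, two seasons), hemoglobin drawn from a
  Gaussian mixed model

  `Hb = μ(location) + x'γ + β·meals·1[most-vulnerable rural] + u_community + u_household + ε`

  and wildmeat introduction into child diets drawn from a logistic model in
  age (odds ratio 2.4 per year), location and rural–urban migrant status.
* **Cohort rules** — most/least-vulnerable classification by within-location
  median splits of monetary income and of a 0–100 multidimensional poverty
  scorecard; a child's monthly meal exposure equals the household's 30-day
  wildmeat meal count if the child normally eats wildmeat, else 0; anemia is
  hemoglobin strictly below 11 g/dL.
* **Descriptives** — stratum means with t-intervals, anemia prevalence and
  consumption shares with Wilson score intervals, introduction-age bins.
* **Mixed-effects inference** — Gaussian (hemoglobin) and binomial
  (introduction) GLMMs with household random intercepts, nested in
  communities for rural fits; non-categorical predictors standardized;
  all-subsets model comparison by AICc with ΔAICc ≤ 2 flagged as equally
  plausible; VIF collinearity screening.  Gaussian models are fitted by
  maximum likelihood via statsmodels; binomial models use a Laplace
  approximation validated against `lme4::glmer`.
* **Scenario engine** — counterfactual hemoglobin
  `Hb' = Hb + β·(m − observed meals)`, recomputed anemia prevalence,
  percentile cluster-bootstrap CIs (households resampled with replacement),
  and signed relative changes versus a reference prevalence.
* **Census scale-up** — bounds on vulnerable rural children per municipality
  from grouped income classes (≤ 1/8 and ≤ 1/4 of the per-capita minimum
  wage), population-growth adjustment, and conversion of prevalence shifts
  into counts of additional anemic children.

## Worked example

```python
from wildhb import (SimConfig, generate_cohort, Scenario, ScenarioEngine,
                    read_census, aggregate)
from wildhb.recovery import most_vulnerable_rural_frame, fit_per_meal_model

hh, ch = generate_cohort(SimConfig(seed=1))      # 1111 households, 577 children
frame = most_vulnerable_rural_frame(hh, ch)      # 110 children in 74 households
fit = fit_per_meal_model(frame)
engine = ScenarioEngine(frame, beta=fit["estimate"])
res = engine.run(Scenario("deny", "deny"), replicates=2000, seed=1)
```

This prints, via the fields of `fit` and `res`:

```
per-meal effect: 0.060 g/dL (95% CI 0.032 to 0.089)
baseline anemia: 62.7%
denied wildmeat: 74.5% (95% CI 65.1-82.9)
relative change: +18.8%
```

Read: in this synthetic cohort (generated with a true effect of
0.05 g/dL per monthly meal), each additional monthly wildmeat meal is
associated with a 0.060 g/dL higher hemoglobin concentration among the most
vulnerable rural children, and denying those households wildmeat would push
anemia prevalence in the stratum from 62.7% to 74.5%, a relative increase
of 18.8%.  Feeding the prevalence shift into the shipped 4-municipality
synthetic census extract converts it into additional anemic children:

```python
import importlib.resources
census = read_census(str(importlib.resources.files("wildhb")
                         / "data" / "synthetic_census_4muni.csv"))
scale = aggregate(census, res.scenario_prevalence_pct - res.baseline_prevalence_pct)
# -> 800-1200 additional anemic children across the four municipalities
```

The same steps are available from the shell: `wildhb simulate`,
`wildhb summarize`, `wildhb fit-hemoglobin`, `wildhb scenario`,
`wildhb scaleup` (see `wildhb --help`).

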