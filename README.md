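# traumacost

Decision-analytic costing of childhood trauma exposure under U.S.
border-control policy scenarios.

`traumacost` is a Python library for health economists and child-trauma
researchers who want to estimate the downstream health-sector and societal
costs of policies that expose migrant children and adolescents to
additional trauma. It models three policies — **No Detention** (families
released into the community), **Family Detention** (families detained
together; 50% of children assumed to experience one additional
policy-related trauma) and **Zero Tolerance** (forced child–parent
separation; 100% exposed) — and the mental-health consequences that follow:
PTSD, depression, anxiety, and ADHD.

## The model

Children are stratified into four ordinal severity states by their count
of endorsed day-to-day functional-impairment indicators (the 14-item IOS
checklist): Q1 = 0 items, Q2 = 1–2, Q3 = 3–4, Q4 = >4, plus an absorbing
Dead state. Three linked components:

1. **Trauma dose–response.** A proportional-odds (cumulative logit)
   regression of severity state on the count of confirmed trauma types,
   adjusted for age and sex:

   logit P(S > k | x) = β·trauma + β_age·age + β_sex·male − c_k,  k = 1,2,3

   so e^β is the odds ratio of occupying a more severe state per
   additional trauma type (reference value 1.232, 95% CI [1.141, 1.330]).
   Each policy's starting distribution mixes the baseline with an
   OR-shifted distribution in proportion to the exposed fraction: for each
   cut, the cumulative odds of being above state k multiply by OR^m for m
   additional traumas.

2. **Markov cohort model.** Annual cycles over {Q1..Q4, Dead} with an
   advancing-progression transition matrix (living mass can stay or move
   toward more severe states), then age-based background mortality — no
   excess mortality by severity state. Horizons of 5 and 10 years.

3. **Cost accrual.** State Q1 carries the annual cost of a child with no
   behavior problems; Q2–Q4 carry the behavior-problem base cost plus the
   prevalence-weighted costs of the four conditions (all in 2018 USD).
   Direct costs give the health-sector perspective; direct + indirect
   (time, caregiver absenteeism, transportation) give the societal
   perspective. Incrementals versus No Detention scale to hypothetical
   cohorts of 2,342 / 16,790 / 23,725 affected children.

Deterministic (one-way, tornado-ordered) and probabilistic (Monte Carlo)
sensitivity analyses re-run the whole pipeline over configured ranges and
distributions, including a 0–100% sweep of the additional-trauma fraction.

Because the underlying clinical sample (N = 458 migrant youth) is
restricted, the package ships a synthetic-cohort generator with its
published marginal structure and a deterministic fixture reproducing its
published prevalence table exactly. Transition probabilities and unit
costs from the study's supplementary material are not public; the
packaged defaults for those inputs are clearly-labelled placeholders
(see `docs/methods.md`).

## Worked example

```python
import traumacost as tc

cohort = tc.generate_cohort(tc.GeneratorSpec(n=50_000, seed=20180401))
effect = tc.fit_cumulative_logit(cohort)
print(effect.to_json_dict())
# {'or': 1.2301307475891121, 'ci_low': 1.221319584013482,
#  'ci_high': 1.2390054789684302, 'n': 50000}
```

The generator planted a per-trauma odds ratio of 1.232; the regression
recovers 1.230 [1.221, 1.239] — each additional confirmed trauma type
multiplies a child's odds of occupying a more severe state by about 1.23.

```python
config = tc.default_config()
print(tc.policy_table(config)[["scenario", "perspective", "horizon",
                               "per_child_total", "per_child_incremental"]]
      .head(6).to_string(index=False))
#        scenario perspective  horizon  per_child_total  per_child_incremental
#     NoDetention      direct        5            24173                      0
# FamilyDetention      direct        5            24497                    325
#   ZeroTolerance      direct        5            24822                    649
#     NoDetention    societal        5            35749                      0
# FamilyDetention    societal        5            36232                    482
#   ZeroTolerance    societal        5            36714                    965
```

Under the packaged (partly placeholder) inputs, Zero Tolerance costs an
extra $649 per child over 5 years from the health-sector perspective and
$965 from the societal perspective, relative to No Detention; multiplying
by the first cohort (2,342 children) gives a $1,519,958 budget impact.
The ordering No Detention ≤ Family Detention ≤ Zero Tolerance is
structural (it holds for any odds ratio above 1 with severity-nondecreasing
costs); the absolute levels track the placeholder unit costs.

The `examples/` directory has one short narrative script per capability:
cohort generation, the dose–response fit, the policy cost model, and the
sensitivity analyses. A thin CLI mirrors them
(`traumacost generate | fit | run | dsa | sweep | psa`).

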