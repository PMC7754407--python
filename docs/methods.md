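# Methods

This note documents the model, the data-generating assumptions, the
numerical choices, and the limitations of `traumacost`. It is the
package's own account; every number quoted here is computed by the test
suite or the scripts in `examples/`.

## Severity states and the dose–response model

Severity is an ordinal variable with four states defined by the count of
endorsed items on a 14-item functional-impairment checklist (IOS): Q1 = 0
items, Q2 = 1–2, Q3 = 3–4, Q4 = more than 4. The reference clinical
sample of 458 trauma-exposed migrant children distributes 60/175/134/89
across the states (13.1% / 38.2% / 29.3% / 19.4%; the last share is
sometimes quoted as 19.5%, a rounding discrepancy we record and do not
resolve). A fifth, absorbing Dead state closes the state space.

The dose–response of severity on the count of confirmed trauma types
(0–20) is a proportional-odds (cumulative logit) model. Internally we
store cumulative probabilities as P(S ≤ k) and parameterize

    P(S ≤ k | x) = logistic(c_k − η),   η = β·trauma + β_age·age + β_sex·male,

so a positive β moves mass toward severe states and e^β is reported as
the odds ratio per additional trauma type (reference value 1.232,
95% CI [1.141, 1.330]). The sign convention matters: "OR > 1" always
means "higher odds of a *more* severe state" throughout the package.
Fitting is by maximum likelihood through statsmodels' ordinal model
(logit link); confidence intervals are Wald intervals on the log-odds
scale, exponentiated — the default in standard proportional-odds
software. Records with missing model variables would be dropped listwise
(synthetic cohorts are complete by construction). Age enters linearly in
years, uncentered; sex is coded male = 1. BFGS is run to a tight gradient
tolerance and the score is checked explicitly at the solution, with a
Newton polish as fallback; this reproduces an independent direct
maximization of the likelihood to ~1e-7 on test data.

## Synthetic cohorts

The clinical sample is restricted, so all individual-level inputs come
from a seeded generator that emulates its published marginals:

- **Age**: Normal(13, 4), rounded to whole years, clipped to [3, 20].
  Clipping (rather than truncating and re-drawing) keeps the large-sample
  mean within ±0.05 of 13; hard truncation at these bounds would bias the
  mean to ≈12.8.
- **Sex**: Bernoulli(0.43) for male.
- **Trauma-type count**: the published marginals are mean 3.6, SD 2.3 —
  overdispersed — so we use a negative binomial matched on both moments
  (r ≈ 7.67), clipped to [0, 20]; it degrades gracefully to Poisson if a
  spec is at or below equidispersion.
- **Severity state**: drawn from the proportional-odds model above.
  Default cutpoints are the logits of the reference cumulative shares
  offset by β×3.6 so that the marginal distribution at the mean trauma
  burden approximates the reference shares (the logistic mixture over
  trauma counts makes this approximate, not exact, which is irrelevant
  downstream: the pipeline's baseline distribution comes from the
  reference counts, not from generated cohorts).
- **IOS count**: uniform within the state's item-count bin (Q1: {0},
  Q2: 1–2, Q3: 3–4, Q4: 5–14). Only the state is used downstream.
- **Diagnoses** (PTSD, depression, anxiety, ADHD): independent Bernoulli
  draws given the state, at the state-conditional prevalence. Real
  comorbidity is correlated; only per-state marginals are published, so
  independence is a documented simplification.

Two generated cohorts with identical spec and seed are identical
(`numpy.random.default_rng` throughout).

**Reference fixture.** Exact reproduction of the published prevalence
table requires exact counts, which iid sampling cannot deliver at
n = 458. `reference_cohort()` therefore assigns states and diagnosis
flags by exact stratified counts (60/175/134/89 children per state;
published per-condition counts within each state) and draws the
remaining fields with seed 20180401. Its trauma counts are drawn
marginally, not conditionally on the assigned state, so the fixture does
not itself encode the dose–response — use `generate_cohort` for that.
One published cell is internally inconsistent: the depression row prints
per-state counts 7/32/32/36 (sum 107) against a full-sample count of 109
and a Q3 percentage of 25.37% (= 34/134). Both the row total and the
percentage imply Q3 = 34; the fixture uses 34 and treats the printed 32
as a misprint.

## Policy scenarios

Each policy is an exposure assumption: a fraction f of children
experiences m additional policy-related traumas (defaults: No Detention
f = 0, Family Detention f = 0.5, Zero Tolerance f = 1, m = 1). For the
exposed fraction the baseline distribution is shifted on the cumulative
odds scale: with G_k = P(S > k | alive),

    G'_k = OR^m · G_k / (1 − G_k + OR^m · G_k),

and the starting distribution is the mixture (1−f)·base + f·shifted.
This transform is the package's explicit definition of "higher odds of
starting in a more severe state"; it preserves total probability to
1e-12, first-order stochastically dominates toward severity for OR > 1,
composes multiplicatively in m, and inverts exactly under 1/OR. Shifting
the aggregate distribution and shifting individuals then re-binning are
equivalent under proportional odds; we shift the aggregate. The
confidence interval on per-child costs is obtained by re-running the
entire pipeline at the OR's lower and upper 95% bounds, varying nothing
else. Background (non-policy) trauma accrual is taken as common to all
scenarios and embodied in the shared transition matrix; the odds-ratio
shift applies to starting states only.

## Markov engine

Annual cycles. Within a cycle, living mass first transitions among
Q1–Q4 by the configured row-stochastic matrix, then a fraction q(age) of
all living mass moves to Dead; the order is a stated contract (the
effect of swapping is second order). The default matrix is
advancing-progression (no mass below the diagonal), matching the model's
severity-ratchet structure, but any row-stochastic matrix — including
ones that skip states — is expressible in config. Mortality is age-based
only, from a single-year-of-age table; no excess mortality attaches to
severer states, deliberately. The cohort is run at a single
representative starting age (13, the sample mean), configurable. No
half-cycle correction is applied: costs accrue on start-of-cycle
occupancy, consistent with undiscounted annual accounting; a discount
rate (default 0) is available and applied as 1/(1+r)^t.

## Costs

State Q1 carries the "no behavior problems" annual base cost; Q2–Q4
carry the "behavior problems" base plus Σ_c P(c | state)·cost_c over the
four conditions; Dead costs nothing. A config switch
(`include_q1_conditions`) lets Q1 also accrue prevalence-weighted
condition costs — off by default, since the modelled convention assigns
the least-severe state its base cost only even though some Q1 children
carry diagnoses. Direct and indirect components are tracked separately;
the societal perspective is their exact sum (tested to additivity).
Internal arithmetic is full precision; reports round to whole dollars,
and incrementals are computed from unrounded totals before rounding.
Cohort budget figures are exact products of the whole-dollar per-child
incremental and the cohort size. A conversion factor (default 1) can be
applied uniformly for currency/inflation adjustment and is recorded in
the cost metadata.

## Sensitivity analyses

**One-way DSA** re-runs the full pipeline with exactly one config key set
to its low, then high, value, and ranks parameters by the absolute
outcome spread (tornado order). The shipped tornado uses per-child
*total* cost as the outcome, matching the reported sensitivity result
that total cost was most sensitive to the direct depression cost — under
the packaged ranges (wide for depression, ±30% for the behavior-problem
base), that qualitative ordering is reproduced and tested. At base
values the DSA reproduces the base case exactly.

**Exposure sweep**: the additional-trauma fraction runs 0–100% in 10%
steps. The starting distribution is linear in the mixture weight and
everything downstream is linear in the distribution, so the incremental
cost is *exactly* linear in the fraction — constant per-10% steps are
asserted to 1e-8, and any deviation indicates a bug. (The analogous
published per-10% figures imply a societal step larger than one tenth of
the full-exposure incremental, which exact linearity rules out; whether
that sweep varied something besides the mixture fraction is not
determinable, and we do not reproduce those two numbers.)

**PSA**: parameters are sampled jointly — lognormal for the odds ratio
(fitted so the 2.5/97.5 quantiles hit the published CI), gamma for costs
(moment-matched), beta for probabilities/fractions — each draw re-runs
the full pipeline; summaries are the mean and 2.5/97.5 percentiles.
Default 2,000 iterations, seeded and reproducible; family choices are the
package's (the source names Monte Carlo simulation without specifying
distributions).

## Provenance of packaged inputs and what tests do (and don't) show

Published and packaged as-is: baseline state counts, the state-conditional
prevalence table, the per-trauma odds ratio and CI, scenario exposure
fractions, cohort sizes, horizons, starting age. Placeholder (the study's
literature-derived values live in supplementary material that is not
public): the transition matrix, unit costs, the mortality table, DSA
ranges, PSA distributions. Every placeholder is flagged in the config's
`provenance` block, surfaced in run metadata and logged by the CLI.
Consequently the package's absolute per-child totals are *not* estimates
of the published ones (which required the supplementary inputs); what is
reproduced exactly is the published arithmetic downstream of per-child
totals (incrementals and cohort budget figures), the prevalence table,
and the dose–response recovery — plus the structural properties
(ordering, conservation, ratchet, linearity) that hold under any valid
config. Passing tests therefore validate the machinery and the published
arithmetic, not the calibration of placeholder inputs; and synthetic
cohorts validate estimator behaviour under the stated generating model,
not the clinical realism of that model (real data have correlated
comorbidities, informant effects, and missingness the generator omits).

## Problem sizes

Default analysis runs use the published cohort structure (4 states,
5- and 10-year horizons) and are effectively instantaneous. Statistical
checks use n = 50,000 generated children for point recovery of the odds
ratio (Monte Carlo SE ≈ 0.005 on the OR scale) and 500 replicates at the
study's n = 458 for CI coverage (measured 95.8% against the nominal
95%, within the 93–97% acceptance band); PSA tests run at a few hundred
iterations against the 2,000-iteration default.

## Known limitations

- Trauma is a count of types without severity grading; one
  policy-related trauma is one unit on the odds scale regardless of kind.
- Diagnosis flags are conditionally independent given state in synthetic
  data; comorbidity correlation is not modelled.
- The single representative starting age ignores age heterogeneity in
  mortality within a cohort.
- No detention operating costs, litigation costs, suicide/substance-use/
  STD extensions, or state-dependent excess mortality: all out of scope.
- Placeholder inputs make absolute cost levels illustrative until a
  calibrated config is supplied.
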