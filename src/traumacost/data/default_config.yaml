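# Default model configuration.
#
# Provenance: inputs marked "study" reproduce values printed in the source
# publication; inputs marked "placeholder" stand in for literature-derived
# values that were published only in supplementary material and are not
# reproduced here — replace them with calibrated values for substantive use.
# All costs are annual, 2018 USD.

generator:                     # study: sample demographics
  n: 458
  age_mean: 13.0
  age_sd: 4.0
  prop_male: 0.43
  trauma_mean: 3.6
  trauma_sd: 2.3
  beta_trauma: 0.20866356231917787   # ln(1.232), study
  beta_age: 0.0
  beta_sex: 0.0
  seed: 20180401

trauma_effect:                 # study: adjusted per-trauma-type odds ratio
  or: 1.232
  ci_low: 1.141
  ci_high: 1.330

scenarios:                     # study: additional-trauma exposure fractions
  - {name: NoDetention,     exposed_fraction: 0.0, extra_traumas: 1}
  - {name: FamilyDetention, exposed_fraction: 0.5, extra_traumas: 1}
  - {name: ZeroTolerance,   exposed_fraction: 1.0, extra_traumas: 1}

state_counts: [60, 175, 134, 89]   # study: children per severity state

prevalence_counts:             # study: diagnosed children per state
  ptsd:       [21, 60, 70, 44]
  depression: [7, 32, 34, 36]   # Q3 reconciled from full count 109 and 25.37%
  anxiety:    [4, 12, 15, 8]
  adhd:       [1, 2, 6, 1]

transition_matrix:             # placeholder: small annual progression
  - [0.90, 0.10, 0.00, 0.00]
  - [0.00, 0.92, 0.08, 0.00]
  - [0.00, 0.00, 0.94, 0.06]
  - [0.00, 0.00, 0.00, 1.00]
progression_only: true

mortality:                     # placeholder: age-based annual death probability
  3: 0.00015
  4: 0.00013
  5: 0.00012
  6: 0.00011
  7: 0.00011
  8: 0.00010
  9: 0.00010
  10: 0.00011
  11: 0.00012
  12: 0.00015
  13: 0.00020
  14: 0.00027
  15: 0.00037
  16: 0.00048
  17: 0.00059
  18: 0.00069
  19: 0.00077
  20: 0.00084
  21: 0.00090
  22: 0.00094
  23: 0.00096
  24: 0.00097
  25: 0.00098
  26: 0.00099
  27: 0.00100
  28: 0.00101
  29: 0.00102
  30: 0.00103

start_age: 13                  # study: cohort mean age
horizons: [5, 10]              # study: 5- and 10-year models
discount_rate: 0.0             # study reports undiscounted accumulation
include_q1_conditions: false   # least-severe state accrues base cost only

costs:                         # placeholder unit costs (annual, 2018 USD)
  base_no_problems:       {direct: 1000,  indirect: 400}
  base_behavior_problems: {direct: 2500,  indirect: 1200}
  conditions:
    ptsd:       {direct: 3000, indirect: 1500}
    depression: {direct: 4500, indirect: 2000}
    anxiety:    {direct: 2500, indirect: 1200}
    adhd:       {direct: 2000, indirect: 1800}
  currency_note: "2018 USD; placeholder values pending calibrated inputs"
  conversion_factor: 1.0

cohorts:                       # study: hypothetical affected cohorts
  - {label: cohort1, size: 2342}
  - {label: cohort2, size: 16790}
  - {label: cohort3, size: 23725}

dsa_ranges:                    # placeholder high-low ranges
  - {path: costs.conditions.depression.direct, low: 2000, high: 13000}
  - {path: costs.conditions.ptsd.direct,       low: 2000, high: 6000}
  - {path: costs.base_behavior_problems.direct, low: 1750, high: 3250}
  - {path: costs.conditions.anxiety.direct,    low: 1250, high: 5000}
  - {path: costs.conditions.adhd.direct,       low: 1000, high: 4000}
  - {path: trauma_effect.or,                   low: 1.141, high: 1.330}

psa:
  iterations: 2000
  seed: 20180402
  parameters:
    - {path: trauma_effect.or, dist: lognormal,
       params: {ci_low: 1.141, ci_high: 1.330}}
    - {path: costs.conditions.depression.direct, dist: gamma,
       params: {mean: 4500, sd: 900}}
    - {path: costs.conditions.ptsd.direct, dist: gamma,
       params: {mean: 3000, sd: 600}}
    - {path: costs.base_behavior_problems.direct, dist: gamma,
       params: {mean: 2500, sd: 500}}

provenance:
  generator: study
  trauma_effect: study
  scenarios: study
  state_counts: study
  prevalence_counts: study
  transition_matrix: placeholder
  mortality: placeholder
  costs: placeholder
  dsa_ranges: placeholder
  psa: placeholder
  cohorts: study
  horizons: study
  start_age: study
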