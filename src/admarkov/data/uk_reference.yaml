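# UK reference parameter set, 2019 GBP.
#
# Prevalence, incidence, severity splits, cost ratios, and unit costs are the
# published literature values the model was built around.  The inter-state
# transition probabilities are NOT published as numbers anywhere we can cite;
# the values below are illustrative placeholders in a clinically plausible
# range and are flagged as such in the provenance block.  Supply your own
# transitions for any quantitative use.
#
# Age bands below 30 carry zero disease prevalence/incidence (no source data
# below 30) and zero general-population HCRU cost (costing scoped to 30+).

meta:
  base_year: 2020
  horizon_year: 2040
  currency: GBP 2019

population:
  synthetic:
    base_year: 2020
    horizon_year: 2040
    total_population: 67000000
    growth_rate: 0.0035
    median_age: 40.0
    dispersion: 6.0
    ageing_drift: 0.2
    seed: 2020

prevalence:
  ad_dementia:            # [male, female]
    "30-34": [0.0001, 0.0002]
    "35-39": [0.0003, 0.0003]
    "40-44": [0.0005, 0.0005]
    "45-49": [0.0009, 0.0010]
    "50-54": [0.0016, 0.0018]
    "55-59": [0.0028, 0.0033]
    "60-64": [0.0052, 0.0059]
    "65-69": [0.0078, 0.0117]
    "70-74": [0.0195, 0.0163]
    "75-79": [0.0338, 0.0403]
    "80-84": [0.0689, 0.0618]
    "85-89": [0.0832, 0.1177]
    "90-94": [0.1112, 0.2275]
    "95-99": [0.1112, 0.2275]
    "100+":  [0.1112, 0.2275]
  mci:                    # all-sex
    "30-34": 0.0039
    "35-39": 0.0054
    "40-44": 0.0075
    "45-49": 0.0103
    "50-54": 0.0143
    "55-59": 0.0197
    "60-64": 0.0297
    "65-69": 0.0416
    "70-74": 0.0553
    "75-79": 0.0886
    "80-84": 0.1630
    "85-89": 0.2612
    "90-94": 0.2757
    "95-99": 0.2757
    "100+":  0.2757

incidence:
  mci:                    # unimpaired -> MCI, all-sex, increases with age
    "30-34": 0.0001
    "35-39": 0.0002
    "40-44": 0.0003
    "45-49": 0.0005
    "50-54": 0.0009
    "55-59": 0.0015
    "60-64": 0.0024
    "65-69": 0.0043
    "70-74": 0.0078
    "75-79": 0.0135
    "80-84": 0.0265
    "85-89": 0.0417
    "90-94": 0.0745
    "95-99": 0.1218
    "100+":  0.1990

transitions:              # PLACEHOLDER values — illustrative, not literature
  mci_to_mild: 0.15
  mild_to_moderate: 0.25
  moderate_to_severe: 0.30
  moderate_to_mild: 0.03
  severe_to_moderate: 0.02
  mortality:
    mci: 0.08
    mild: 0.12
    moderate: 0.18
    severe: 0.35

severity:
  split:                  # [mild, moderate, severe]; printed percentages / 100
    "35-64": [0.5882, 0.3529, 0.0588]
    "65-74": [0.1792, 0.4083, 0.4125]
    "75-84": [0.1897, 0.4018, 0.4084]
    "85+":   [0.1470, 0.3153, 0.5378]
  cost_ratios:            # stage cost / all-severity AD cost
    health: [0.5548, 1.4829, 1.7597]
    social: [0.4261, 1.7049, 1.7622]

costs:
  england_hcru:           # £/person-year, general population [male, female]
    "30-34": [693.86, 1789.63]
    "35-39": [734.49, 1515.61]
    "40-44": [821.90, 1268.05]
    "45-49": [1045.25, 1364.51]
    "50-54": [1222.83, 1502.76]
    "55-59": [1448.22, 1615.18]
    "60-64": [1663.87, 1698.39]
    "65-69": [2412.88, 2221.96]
    "70-74": [2795.88, 2479.90]
    "75-79": [3621.93, 3027.38]
    "80-84": [4181.89, 3505.93]
    "85-89": [4781.36, 3891.96]
    "90-94": [4797.56, 3461.62]
    "95-99": [4548.80, 3219.13]
    "100+":  [3218.98, 2088.91]
  ad_hcru:                # £/person-year, all-severity AD (same for both sexes)
    "30-34": 2626.96
    "35-39": 2626.96
    "40-44": 2626.96
    "45-49": 2626.96
    "50-54": 2740.08
    "55-59": 2996.39
    "60-64": 3327.09
    "65-69": 3740.76
    "70-74": 4019.29
    "75-79": 4130.35
    "80-84": 4643.33
    "85-89": 5001.80
    "90-94": 5547.85
    "95-99": 5460.43
    "100+":  4465.27
  social_general:         # £/person-year, general population
    under_18: 0.0
    age_18_64: 200.26
    age_65_plus: 499.89
  social_ad:              # £/person-year, all-severity AD dementia
    male: 12526.0
    female: 12480.0
  social_utilisation: 0.48
  primary_visit_cost: 33.0
  specialist_visit_cost: 465.0
  drug_price_annual: null # secondary analysis only: 1200 / 11100 / 21000

scenario_defaults:
  launch_year: 2025
  efficacy: {high: 0.30, medium: 0.25, low: 0.20}
  uptake:
    high: {start: 2025, end: 2034, max: 0.58}
    low:  {start: 2025, end: 2034, max: 0.25}
  care_models:
    majority_primary:    {primary_visits: 4, specialist_visits: 0, initiation_specialist_visits: 1}
    majority_specialist: {primary_visits: 2, specialist_visits: 2, initiation_specialist_visits: 1}

provenance:
  population: synthetic
  prevalence: literature
  incidence: literature
  transitions: placeholder
  severity: literature
  costs: literature
  scenario_defaults: literature
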