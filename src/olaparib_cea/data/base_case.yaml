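# Base-case model configuration: adjuvant olaparib vs no olaparib for
# gBRCA1/2-mutated, high-risk early breast cancer.
# Money in 2021 US dollars, times in months, ages in years.
scenario: base-case
starting_age: 42.0
max_age: 110.0
annual_discount_rate: 0.03

costs:
  monthly_drug: 14523.0          # olaparib, per treatment month
  oncologist_visit: 867.0
  imaging: 540.0                 # diagnostic mammogram + breast MRI, annual
  monthly_metastatic: 23599.0    # all-inclusive metastatic care

utilities:
  no_recurrence: 0.98
  metastatic: 0.55
  olaparib_multiplier: 0.90      # applies to no-recurrence utility on treatment

hazard_ratio:                    # distant disease or death, olaparib vs none
  point: 0.61
  ci_low: 0.48
  ci_high: 0.77

recurrence:                      # post-trial extrapolation, both arms
  annual_prob_years5to9: 0.0156
  annual_prob_years10plus: 0.0078

monthly_metastatic_death_rate: 0.052   # ln(2) / 13.3-month median survival
imaging_fraction: 0.535                # fraction of cohort with >= 1 breast
treatment_duration_months: 12

calibration_targets:             # trial DDFS / OS fractions by month
  olaparib:
    ddfs: {12: 0.944, 24: 0.906, 36: 0.880, 48: 0.865}
    os: {12: 0.980, 24: 0.950, 36: 0.928, 48: 0.898}
  no_olaparib:
    ddfs: {12: 0.903, 24: 0.840, 36: 0.810, 48: 0.791}
    os: {12: 0.969, 24: 0.928, 36: 0.891, 48: 0.864}

sensitivity:
  n_psa: 10000
  seed: 20240103
  wtp_grid: {start: 0.0, stop: 300000.0, step: 5000.0}
  ranges:
    hazard_ratio: [0.48, 0.77]
    annual_discount_rate: [0.0, 0.06]
    utility_no_recurrence: [0.735, 1.0]
    utility_metastatic: [0.413, 0.688]
    olaparib_utility_multiplier: [0.80, 1.0]
    monthly_drug_cost: [10892.0, 18154.0]
    oncologist_visit_cost: [650.0, 1084.0]
    imaging_cost: [405.0, 675.0]
    monthly_metastatic_cost: [17699.0, 29499.0]
    monthly_metastatic_death_rate: [0.039, 0.065]

life_table: null                 # null = bundled synthetic US-2018-female table
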