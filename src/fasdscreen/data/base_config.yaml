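# Base-case configuration: the published parameter table, verbatim.
# Annual health-service costs are on the pre-inflation basis; the model
# normalizes them to 2017 CAD using costs.inflation_factor (null means
# "derive from the three published pre/post cost pairs", about 1.2685).
cohort:
  size: 100
  prevalence: 0.663
  prevalence_sd: 0.014
tools:
  meconium:
    sensitivity: 0.924
    sensitivity_sd: 0.081
    specificity: 0.515
    specificity_sd: 0.197
    unit_cost: 175.0
    unit_cost_sd: 18.0
    screen_age: 0
    lag_to_testing: 5
  nst:
    sensitivity: 0.859
    sensitivity_sd: 0.055
    specificity: 0.729
    specificity_sd: 0.107
    unit_cost: 20.0
    unit_cost_sd: 2.0
    screen_age: 5
    lag_to_testing: 0
costs:
  basis: pre_inflation
  first_year: 15976.0
  first_year_sd: 1598.0
  diagnosed_annual: 3426.0
  diagnosed_annual_sd: 343.0
  undiagnosed_annual: 2713.0
  no_fasd_annual: 3101.0
  diagnostic_testing: 3870.0
  diagnostic_testing_sd: 387.0
  inflation_factor: null
  inflate_no_fasd: true
  psych_diagnosed_rate: 0.556
  psych_diagnosed_rate_sd: 0.073
  psych_undiagnosed_rate: 0.330
  psych_undiagnosed_rate_sd: 0.147
  psych_cost_share: null
mortality:
  smr_diagnosed: 3.15
  smr_diagnosed_sd: 1.6
  undiagnosed_multiplier: 1.10
  smr_no_fasd: 3.15
  smr_no_fasd_sd: 2.0
time:
  end_age: 18
  discount_rate: 0.015
  half_cycle: mid_cycle
model:
  future_diagnosis_rate: 0.05
  diagnostic_test_sensitivity: 1.0
  cost_basis: inflated_2017
  pending_fasd_cost: undiagnosed
psa:
  n_draws: 5000
  seed: 20190101
  future_diagnosis_halfwidth: 0.02
  undiagnosed_multiplier_low: 1.0
  undiagnosed_multiplier_high: 1.2
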