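demographics:
  base_pop40plus: null
  anchor_year: 2013
  growth_rate: 0.01405
  adult_ratio: 1.653
  start_year: 2003
  end_year: 2015
  calibration_target:
    incident_advanced: 854
    year: 2013
  series_csv: null
epidemiology:
  kidney_incidence_40plus:
    value: 19.8
    per_100k: true
  rcc_fraction: 0.9
  advanced_at_diagnosis_fraction: 0.2
  localized_mortality: 0.0166
  progression_prob:
  - 0.1318
  - 0.0457
  - 0.0457
  - 0.0192
  - 0.0192
  - 0.0164
  - 0.0164
  - 0.0126
  - 0.0126
  - 0.0126
  fav_int_risk_fraction: 0.89
  to_post_advanced_prob: 1.0
  same_cycle_first_risk: false
  prevalence_includes_advanced: false
costs:
  drugs:
    pazopanib:
      cost_per_cycle: 4046.0
      cycles_per_year: 8
      time_on_treatment_fraction: 0.57
    sunitinib:
      cost_per_cycle: 4904.0
      cycles_per_year: 8
      time_on_treatment_fraction: 0.57
  adverse_events: null
budget:
  horizon_years:
  - 2013
  - 2014
  - 2015
  discount_rate: 0.03
  reference_year: 2013
  share_step: 0.01
  new_arm: pazopanib
  ref_arm: sunitinib
sensitivity:
  output_year: 2013
  share: 1.0
  ranges:
  - parameter: kidney_incidence_40plus
    lower: 17.82
    upper: 21.78
    per_100k: true
  - parameter: rcc_fraction
    lower: 0.85
    upper: 0.95
  - parameter: advanced_at_diagnosis_fraction
    lower: 0.15
    upper: 0.25
  - parameter: localized_mortality
    lower: 0.0149
    upper: 0.0183
  - parameter: progression_year1
    lower: 0.1186
    upper: 0.1449
  - parameter: progression_years2_3
    lower: 0.0411
    upper: 0.0502
  - parameter: progression_years4_5
    lower: 0.0173
    upper: 0.0211
  - parameter: progression_years6_7
    lower: 0.0148
    upper: 0.0181
  - parameter: progression_years8_10
    lower: 0.0113
    upper: 0.0138
  - parameter: fav_int_risk_fraction
    lower: 0.801
    upper: 0.979
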