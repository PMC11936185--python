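ae_costs:
  anaemia: 531.72
  leukopenia: 461.25
  neutropenia: 84.21
  thrombocytopenia: 1054.0
ae_disutilities:
  anaemia: 0.073
  leukopenia: 0.2
  neutropenia: 0.2
  thrombocytopenia: 0.19
ae_incidence:
  chemotherapy:
    anaemia: 0.17
    leukopenia: 0.1
    neutropenia: 0.55
    thrombocytopenia: 0.25
  tislelizumab:
    anaemia: 0.16
    leukopenia: 0.11
    neutropenia: 0.56
    thrombocytopenia: 0.19
care_costs:
  bsc_per_cycle: 359.52
  followup_per_cycle: 55.6
  imaging_per_cycle: 105.9
  labs_per_cycle: 92.5
  subsequent_treatment: 854.05
patient:
  body_surface_area_m2: 1.72
  body_weight_kg: 60.0
  gfr_ml_min: 70.0
prices:
  carboplatin: 0.086
  cisplatin: 0.22
  etoposide: 0.45
  tislelizumab: 1.78
provenance:
  currency: USD; RMB costs converted at 1 USD = 7.05 RMB (2023 average)
  survival_time_unit: months
  wtp: 3x 2023 Chinese per-capita GDP
regimen:
  carboplatin_auc: 5.0
  cisplatin_dose_mg_per_m2: 75.0
  etoposide_days: 3
  etoposide_dose_mg_per_m2: 100.0
  induction_cycles: 4
  platinum_cisplatin_fraction: 0.5
  tislelizumab_flat_dose_mg: 200.0
settings:
  annual_discount_rate: 0.05
  cycle_length_days: 21.0
  half_cycle_correction: false
  horizon_years: 10.0
  wtp: 39855.79
subsequent_uptake:
  chemotherapy: 0.74
  tislelizumab: 0.6
survival:
  chemotherapy:
    os:
      family: loglogistic
      scale: 0.0019
      shape: 2.37
      time_unit: months
    pfs:
      family: loglogistic
      scale: 0.0022
      shape: 3.97
      time_unit: months
  tislelizumab:
    os:
      family: loglogistic
      scale: 0.0068
      shape: 1.78
      time_unit: months
    pfs:
      family: loglogistic
      scale: 0.035
      shape: 1.92
      time_unit: months
utilities:
  progression_free: 0.67
  progressive: 0.47
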