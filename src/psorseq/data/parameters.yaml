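# Moderate-to-severe psoriasis fixture: model configuration, BSC inputs,
# biologic dosing schedules and the evaluated treatment sequences.
# Monetary values are USD; utilities are per year of life.
config:
  cycle_weeks: 16
  weeks_per_year: 52
  start_age: 35
  max_age: 100
  discount_annual: 0.03
  rr_mortality: 1.52
  wtp_threshold: 104337.19
  wtp_grid: "0:400000:2000"
  psa_iterations: 10000
  psa_se_fraction: 0.10
  seed: 20240906

bsc:
  utility: 0.11
  utility_low: 0.09
  utility_high: 0.13
  # per-cycle BSC cost is unpublished: recovered by pinning the systemic-first
  # comparator's total discounted cost to its published value
  calibrate_to:
    comparator: "SYS→UST→ADA"
    total_cost: 149721.0

outpatient:
  cost_per_visit: 71
  low: 57
  high: 86

dosing:
  # 300 mg at weeks 0, 1, 2, 3 and 4, then every 4 weeks; 150 mg vials
  SEC:
    loading_dose_mg: 300
    loading_week: 0
    induction_dose_weeks: [1, 2, 3, 4]
    induction_dose_mg: 300
    maintenance_interval_weeks: 4
    maintenance_dose_mg: 300
    vial_mg: 150
  # 45 mg at weeks 0 and 4, then every 12 weeks; 45 mg vials
  UST:
    loading_dose_mg: 45
    loading_week: 0
    induction_dose_weeks: [4]
    induction_dose_mg: 45
    maintenance_interval_weeks: 12
    maintenance_dose_mg: 45
    vial_mg: 45
  # 80 mg at week 0, then 40 mg every 2 weeks; 40 mg vials
  ADA:
    loading_dose_mg: 80
    loading_week: 0
    induction_dose_weeks: []
    induction_dose_mg: 40
    maintenance_interval_weeks: 2
    maintenance_dose_mg: 40
    vial_mg: 40
  ADA_BS:
    loading_dose_mg: 80
    loading_week: 0
    induction_dose_weeks: []
    induction_dose_mg: 40
    maintenance_interval_weeks: 2
    maintenance_dose_mg: 40
    vial_mg: 40

sequences:
  # comparators: standard first-line care
  - "SYS→UST→ADA"
  - "PHOTO→UST→ADA"
  # first analysis set: originator biologic sequences
  - "UST→ADA→SEC"
  - "UST→SEC→ADA"
  - "SEC→UST→ADA"
  - "SEC→ADA→UST"
  - "ADA→UST→SEC"
  - "ADA→SEC→UST"
  # second analysis set: adalimumab biosimilar pathways
  - "ADA_BS→UST→SEC"
  - "ADA_BS→SEC→UST"
  - "UST→ADA_BS→SEC"
  - "SEC→ADA_BS→UST"
  - "UST→SEC→ADA_BS"
  - "SEC→UST→ADA_BS"
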