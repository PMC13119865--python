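# Default model configuration.
#
# costs / utilities / probabilities reproduce the published input tables
# verbatim (2022 GBP; method-of-moments Gamma/Beta fitted downstream).
# Blocks marked `assumption: true` are synthetic stand-ins for inputs the
# source evidence base does not print (per-state resource use, inter-state
# transition probabilities, all-cause mortality, AMR trajectories); they are
# documented in docs/methods.md and flagged in run manifests.

structural:
  annual_discount_rate: 0.035
  cycle_length_years: 0.25
  start_age: 60
  end_age: 100
  cohort_size: 10000
  wtp_threshold: 20000
  psa_draws: 10000
  test_sensitivity: 0.97

policies:
  invalid_beta: clamp

costs:
  prescription:              {mean: 29.00,   se: 5.80}
  phone_call:                {mean: 8.80,    se: 1.76}
  patient_contact:           {mean: 4.46,    se: 0.89}
  home_visit:                {mean: 115.87,  se: 23.17}
  gp_consultation:           {mean: 53.36,   se: 10.67}
  ae_without_admission:      {mean: 499.00,  se: 99.80}
  copd_hospital_stay:        {mean: 1930.01, se: 386.0}
  community_nurse_follow_up: {mean: 122.00,  se: 24.40}
  outpatient_follow_up:      {mean: 50.72,   se: 10.14}
  rp21_test:                 {mean: 94.00,   se: 24.00}
  antibiotic_course:         {mean: 1.84,    se: 0.37}
  steroid_course:            {mean: 0.70,    se: 0.14}
  alternative_antibiotics:   {mean: 1.01,    se: 0.20}
  secondary_care_follow_up:  {mean: 76.08,   se: 15.22}
  primary_care_follow_up:    {mean: 122.00,  se: 24.40}
  secondary_care_spirometry: {mean: 64.56,   se: 12.91}
  primary_care_spirometry:   {mean: 22.35,   se: 4.47}
  influenza_vaccination:     {mean: 8.00,    se: 1.60}
  oxygen_therapy:            {mean: 60.93,   se: 12.19}

utilities:
  recovery:
    dead:                {value: 0.0, fixed: true}
    partially_recovered: {value: 0.5558, se: 0.1248}
    fully_recovered:     {value: 0.6607, se: 0.1112}
  gold:
    stage_2: {value: 0.7820, se: 0.1564}
    stage_3: {value: 0.7210, se: 0.1442}
    stage_4: {value: 0.6240, se: 0.1248}

probabilities:
  intervention:
    # Enforced identity: equals 1 - test_sensitivity.
    antibiotics_initial:         {mean: 0.03, se: 0.0058}
    improve_initial_antibiotics: {mean: 0.85, se: 0.17}
    improve_second_ab_ae:        {mean: 0.90, se: 0.18}
    improve_second_st_ab:        {mean: 0.87, se: 0.174}
    improve_initial_st_ab:       {mean: 0.92, se: 0.184}
    improve_second_ab:           {mean: 0.85, se: 0.17}
  control:
    antibiotics_initial:         {mean: 0.80, se: 0.16}
    # Published SE 0.8 is impossible for a Beta with mean 0.8 (presumed typo);
    # default follows the 20%-of-mean pattern of every other row.
    improve_initial_antibiotics: {mean: 0.80, se: 0.16}
    improve_initial_st_ab:       {mean: 0.89, se: 0.177}
    improve_second_st_ab:        {mean: 0.87, se: 0.174}
    improve_second_ab:           {mean: 0.80, se: 0.16}
    improve_second_ab_ae:        {mean: 0.90, se: 0.18}
  shared:
    mortality_after_admission:   {mean: 0.05, se: 0.0101}
    improve_third_treatment:     {mean: 0.89, se: 0.177}
  hospitalisation:
    # Admission-stage probabilities (from the one-way sensitivity table;
    # SEs follow the 20%-of-mean convention of the probability table).
    control_bacterial:    {mean: 0.20, se: 0.040}
    control_viral:        {mean: 0.10, se: 0.020}
    intervention_ab:      {mean: 0.15, se: 0.030}
    intervention_st_ab:   {mean: 0.10, se: 0.020}

tree:
  # Split of first-line antibiotic failures between a repeat antibiotic
  # course and antibiotics with an A&E attendance (supplementary pathway
  # detail not printed; assumption).
  second_line_ae_split: 0.5
  # Fraction of control-arm admission candidates whose exacerbation is
  # bacterial (governs which hospitalisation probability applies).
  p_bacterial_control: 0.5
  assumption_p_bacterial: true
  # Among admission survivors, fraction fully (vs partially) recovered.
  full_recovery_after_admission: 0.5
  assumption_recovery_split: true
  # Whether control-arm viral admission candidates incur the
  # alternative-antibiotics course cost.
  control_viral_alt_antibiotics: false
  # Undiscounted QALY weight horizon attached to the tree episode (years).
  episode_duration_years: 0.25

markov:
  assumption: true
  # Entry GOLD-stage mix (not printed; uniform, flagged).
  stage_mix: [0.3333333333333333, 0.3333333333333333, 0.3333333333333334]
  # Markov entry state for each short-run severity class.
  entry_states: {mild: mild, moderate: moderate, severe: moderate}
  # Per-cycle movement between stable / mild / moderate exacerbation states
  # (rows sum to 1; synthetic stand-ins for unpublished source transitions).
  severity_transitions:
    stable:   {stable: 0.85, mild: 0.12, moderate: 0.03}
    mild:     {stable: 0.30, mild: 0.50, moderate: 0.20}
    moderate: {stable: 0.05, mild: 0.25, moderate: 0.70}
  # Per-cycle GOLD progression (no regression).
  stage_progression: {stage_2_to_3: 0.010, stage_3_to_4: 0.010}
  # Per-cycle hospital-admission event probability while in an exacerbation
  # state (carries the hospital-stay and oxygen costs).
  admission_probability: {stable: 0.0, mild: 0.02, moderate: 0.12}
  # Per-cycle disease-specific (admission-related) excess death probability.
  disease_death: {stable: 0.0, mild: 0.0005, moderate: 0.002}
  # Utility multiplier applied to the GOLD-stage utility while exacerbating.
  exacerbation_utility_multiplier: {stable: 1.0, mild: 0.85, moderate: 0.70}
  # Per-cycle resource-use quantities by severity state (units of the cost
  # items above; synthetic stand-ins for unpublished source quantities).
  resource_use:
    stable:
      gp_consultation: 0.20
      prescription: 0.30
      phone_call: 0.20
      influenza_vaccination: 0.25
      primary_care_spirometry: 0.25
    mild:
      gp_consultation: 0.50
      prescription: 0.80
      antibiotic_course: 0.50
      steroid_course: 0.50
      patient_contact: 0.30
      primary_care_follow_up: 0.30
    moderate:
      gp_consultation: 1.00
      prescription: 1.50
      antibiotic_course: 1.00
      steroid_course: 1.00
      home_visit: 0.30
      community_nurse_follow_up: 0.50
      secondary_care_follow_up: 0.50
      outpatient_follow_up: 0.30
      oxygen_therapy: 0.30
      secondary_care_spirometry: 0.25

mortality:
  # Synthetic Gompertz all-cause annual mortality (England & Wales-like
  # shape, not calibrated to the 2022 life table).
  kind: synthetic_gompertz
  assumption: true
  baseline: 2.0e-5
  slope: 0.097
  noise_sd: 0.0
  seed: 0

amr:
  exchange_rate_gbp_per_usd: 0.800769
  rmf: 0.37
  gdp_loss_total_usd: 1.0e+14
  horizon_years: 35
  ddd_per_1000_per_day: 14.1
  # Global population behind the published consumption figure (back-solved,
  # not printed; assumption).
  population: 7.8e+9
  course_days: 5
  copd_share: 0.075
  # Published per-prescription chain values, used downstream by default.
  canonical:
    usd_per_prescription: 356.96
    gbp_per_prescription: 285.84
    penalty_gbp: 105.76
  use_canonical: true
  penalty_sensitivity_gbp: {broad_spectrum: 7.45, narrow_spectrum: 14.89}
  annual_cost_bases_gbp:
    gdp: 2.2e+12
    hospital: 5.54e+11
    productivity: 1.55e+11
  reductions: [0.01, 0.05, 0.10, 0.25]
  uk_shares: [1.0, 0.5, 0.25]
  uk_annual_diagnoses: 115000
  uk_exacerbation_fractions: [0.30, 0.50]
  # Synthetic resistance-rate trajectory generators, 2023-2040 (qualitative
  # shapes only: MRSA slowly declining, PRSP slowly rising).
  trajectories:
    assumption: true
    mrsa: {start_rate: 0.30, annual_trend: -0.02, trend_kind: relative, noise_sd: 0.004, seed: 11}
    prsp: {start_rate: 0.25, annual_trend: 0.015, trend_kind: relative, noise_sd: 0.004, seed: 12}
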