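model:
  cycle_length_days: 14
  horizon_years: 10.0
  discount_rate_annual: 0.05
  half_cycle_correction: false
  life_years_discounted: true
curves:
  pfs_control:
    scale: 0.00267
    shape: 1.89552
    time_unit: cycle_14d
    label: PFS control (FOLFIRI)
  pfs_cetuximab:
    scale: 0.00195
    shape: 1.52888
    time_unit: week
    label: PFS cetuximab + FOLFIRI
  os_control:
    scale: 0.0054
    shape: 1.53841
    time_unit: month
    label: OS control (FOLFIRI)
  os_cetuximab:
    scale: 0.00324
    shape: 1.2641
    time_unit: cycle_14d
    label: OS cetuximab + FOLFIRI
costs:
  folfiri_per_cycle: 2050.5
  cetuximab_per_100mg: 637.4
  salvage_per_cycle: 2411.8
  ras_test_per_unit: 176.9
  terminal_care: 1980.1
  sae_unit_costs:
    vomiting: 175.7
    rash_acne: 11.1
    fatigue: 1524.6
    neutropenia: 2694.6
    diarrhea: 891.5
dosing:
  loading_dose_mg_m2: 400.0
  maintenance_dose_mg_m2: 250.0
  infusions_per_cycle: 2
  vial_size_mg: 100.0
  bsa_m2: 1.72
pap:
  lead_pay_months: 2
  lead_free_months: 2
  repeat_pay_months: 1
  repeat_free_months: 3
  cycles_per_month: 2.0
utilities:
  u_pfs: 0.85
  u_pd_chemo: 0.24
  u_pd_targeted: 0.68
  pd_targeted_fraction_cetux_arm: 0.3714
strategies:
  control:
    pap_enabled: false
    screening_applied: false
    ras_prevalence: 0.41
    coverage_fraction: 0.6
    salvage_cycles_cap: 3
    sae_probabilities: {}
    cetuximab_pricing: per_unit_cycle
    terminal_care_mode: once
  cetuximab:
    pap_enabled: true
    screening_applied: true
    ras_prevalence: 0.41
    coverage_fraction: 0.6
    salvage_cycles_cap: 3
    sae_probabilities: {}
    cetuximab_pricing: per_unit_cycle
    terminal_care_mode: once
param_specs:
- name: cost_folfiri_per_cycle
  base: 2050.5
  low: 1083.0
  high: 3018.0
  psa_distribution: triangular
  target: costs.folfiri_per_cycle
- name: cost_cetuximab_per_100mg
  base: 637.4
  low: 318.7
  high: 637.4
  psa_distribution: triangular
  target: costs.cetuximab_per_100mg
- name: cost_salvage_per_cycle
  base: 2411.8
  low: 1891.0
  high: 2739.1
  psa_distribution: triangular
  target: costs.salvage_per_cycle
- name: cost_ras_test
  base: 176.9
  low: 132.7
  high: 221.2
  psa_distribution: triangular
  target: costs.ras_test_per_unit
- name: cost_terminal_care
  base: 1980.1
  low: 769.2
  high: 5288.3
  psa_distribution: triangular
  target: costs.terminal_care
- name: cost_sae_vomiting
  base: 175.7
  low: 134.0
  high: 223.0
  psa_distribution: triangular
  target: costs.sae.vomiting
- name: cost_sae_rash_acne
  base: 11.1
  low: 6.2
  high: 16.0
  psa_distribution: triangular
  target: costs.sae.rash_acne
- name: cost_sae_fatigue
  base: 1524.6
  low: 421.9
  high: 3322.6
  psa_distribution: triangular
  target: costs.sae.fatigue
- name: cost_sae_neutropenia
  base: 2694.6
  low: 2154.7
  high: 3294.0
  psa_distribution: triangular
  target: costs.sae.neutropenia
- name: cost_sae_diarrhea
  base: 891.5
  low: 158.6
  high: 1104.6
  psa_distribution: triangular
  target: costs.sae.diarrhea
- name: utility_pfs
  base: 0.85
  low: 0.68
  high: 1.0
  psa_distribution: beta
  target: utilities.u_pfs
- name: utility_pd_chemo
  base: 0.24
  low: 0.2
  high: 0.28
  psa_distribution: beta
  target: utilities.u_pd_chemo
- name: utility_pd_targeted
  base: 0.68
  low: 0.52
  high: 0.78
  psa_distribution: beta
  target: utilities.u_pd_targeted
- name: ras_mutation_prevalence
  base: 0.41
  low: 0.366
  high: 0.454
  psa_distribution: beta
  target: cetuximab.ras_prevalence
- name: body_surface_area
  base: 1.72
  low: 1.5
  high: 1.9
  psa_distribution: fixed
  target: dosing.bsa_m2
- name: insurance_coverage
  base: 0.6
  low: 0.44999999999999996
  high: 0.75
  psa_distribution: fixed
  target: coverage_fraction
- name: median_pfs_control
  base: 0.7198346261748754
  low: 0.5398759696311566
  high: 0.8997932827185942
  psa_distribution: fixed
  target: curves.pfs_control.median
- name: median_pfs_cetuximab
  base: 0.8931259195545191
  low: 0.6698444396658894
  high: 1.116407399443149
  psa_distribution: fixed
  target: curves.pfs_cetuximab.median
- name: median_os_control
  base: 1.9558938106561863
  low: 1.4669203579921397
  high: 2.4448672633202326
  psa_distribution: fixed
  target: curves.os_control.median
- name: median_os_cetuximab
  base: 2.67281116073392
  low: 2.0046083705504403
  high: 3.3410139509174
  psa_distribution: fixed
  target: curves.os_cetuximab.median
seed: 20170411
threshold: 22200.0
provenance:
  curves: printed survival-parameter rows, duplicated labels resolved in row order
  costs: printed unit-cost rows with deterministic ranges
  utilities: printed utility rows; PSA standard errors at 25% of mean
  pap: pay 2 months / donate 2 months lead-in, then pay 1 / donate 3 repeating
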