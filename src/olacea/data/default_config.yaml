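# Base-case model configuration: fitted Weibull survival parameters per arm
# and endpoint, and every economic input with its deterministic-sensitivity
# range and probabilistic-sensitivity-analysis distribution family.
# Time unit: months. Money: 2020 USD ($1 = 6.9 CNY).

model:
  horizon_cycles: 120          # 10 years of monthly cycles
  annual_discount_rate: 0.03
  background_annual_mortality: 0.00707   # Chinese general population, 2020
  half_cycle_correction: true
  engine_mode: partitioned_survival

survival:
  olaparib:
    pfs: {scale: 0.015753, shape: 1.255852,
          scale_se: 0.005225, shape_se: 0.104899,
          scale_ci: [0.008223, 0.030178], shape_ci: [1.066202, 1.479237]}
    os:  {scale: 0.001509, shape: 1.543080,
          scale_se: 0.000779, shape_se: 0.126463,
          scale_ci: [0.000549, 0.041519], shape_ci: [1.314099, 1.811960]}
  placebo:
    pfs: {scale: 0.078114, shape: 1.083484,
          scale_se: 0.020234, shape_se: 0.093435,
          scale_ci: [0.047016, 0.129781], shape_ci: [0.914994, 1.282999]}
    os:  {scale: 0.002097, shape: 1.534778,
          scale_se: 0.001341, shape_se: 0.158965,
          scale_ci: [0.000599, 0.007343], shape_ci: [1.252801, 1.880221]}

economics:
  olaparib_price_per_150mg: {base: 14.78, low: 11.82, high: 17.74, distribution: triangle}
  brca_testing:             {base: 507.25, low: 405.80, high: 608.70, distribution: triangle}
  followup_per_cycle:       {base: 35.63, low: 28.50, high: 42.76, distribution: triangle}
  radiology_per_cycle:      {base: 64.73, low: 51.78, high: 77.68, distribution: triangle}
  salvage_per_cycle:        {base: 270.20, low: 216.16, high: 324.24, distribution: triangle}
  terminal_care:            {base: 2212.80, low: 1770.24, high: 2655.36, distribution: triangle}
  sae_unit_costs:
    anemia:      {base: 531.70, low: 425.36, high: 638.04, distribution: triangle}
    neutropenia: {base: 530.80, low: 424.64, high: 636.96, distribution: triangle}
    nausea:      {base: 40.00, low: 32.00, high: 48.00, distribution: triangle}
    fatigue:     {base: 110.30, low: 88.24, high: 132.36, distribution: triangle}
  sae_risks_olaparib:
    anemia:      {base: 0.19, low: 0.152, high: 0.228, distribution: beta}
    neutropenia: {base: 0.05, low: 0.04, high: 0.06, distribution: beta}
    nausea:      {base: 0.03, low: 0.023, high: 0.036, distribution: beta}
    fatigue:     {base: 0.04, low: 0.032, high: 0.048, distribution: beta}
  sae_risks_placebo:
    anemia:      {base: 0.02, low: 0.016, high: 0.024, distribution: beta}
    neutropenia: {base: 0.04, low: 0.032, high: 0.048, distribution: beta}
    nausea:      {base: 0.00, low: 0.00, high: 0.00, distribution: beta}
    fatigue:     {base: 0.02, low: 0.016, high: 0.024, distribution: beta}
  utility_pfs: {base: 0.81, low: 0.729, high: 0.891, distribution: beta}
  utility_pd:  {base: 0.74, low: 0.666, high: 0.814, distribution: beta}
  bsa:         {base: 1.72, low: 1.38, high: 2.06, distribution: triangle}
  discount_rate: {base: 0.03, low: 0.00, high: 0.08, distribution: fixed}

wtp_threshold: 31498.70   # 3x China 2020 per-capita GDP, USD/QALY
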