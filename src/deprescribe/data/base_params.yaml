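# Base-case model parameters for the antihypertensive-deprescribing
# cost-utility model.  Values in the treatment_effect, event_risks,
# mortality.smr and utilities blocks are published trial / literature
# estimates; every entry in the costs block is a placeholder standing in
# for an unpublished unit-cost appendix (order-of-magnitude UK 2017/18
# reference costs) and is flagged non-paper-default at load time.

treatment_effect:
  # ITT systolic BP difference (mm Hg, intervention minus usual care) at 12 weeks
  delta_sbp_mmhg: {value: 3.4, ci: [1.0, 5.8]}
  # BP difference to which the relative risks below correspond; RRs are
  # rescaled to delta_sbp via log-linear interpolation RR^(delta/reference).
  reference_delta_mmhg: 3.4
  rr_chd: {value: 1.009, ci: [0.896, 1.135]}
  rr_stroke_tia: {value: 1.108, ci: [1.047, 1.177]}
  rr_hf: {value: 1.290, ci: [1.134, 1.472]}
  rr_sae: {value: 0.685, ci: [0.343, 1.366]}
  rr_minor: {value: 0.685, ci: [0.343, 1.366]}
  effect_duration_years: null          # null = lifetime
  maintain_reduction_prob: 0.663
  # annual utility gained from taking one fewer drug (base 0; varied in
  # threshold analysis)
  reduction_utility_gain_annual: 0.0

event_risks:
  chd_cerebro_split: [0.5, 0.5]
  cerebro_type_fractions:              # P(stroke), P(TIA) by sex and age band
    M: {"75-84": [0.811, 0.189], "85+": [0.956, 0.044]}
    F: {"75-84": [0.826, 0.174], "85+": [0.852, 0.148]}
  chd_type_fractions:                  # P(MI), P(ACS), P(stable angina)
    M: {"75-84": [0.372, 0.187, 0.441], "85+": [0.375, 0.194, 0.431]}
    F: {"75-84": [0.358, 0.119, 0.523], "85+": [0.377, 0.109, 0.514]}
  hf_annual_risk: {"80-84": 0.0223, "85-89": 0.0358, "90+": 0.0536}
  sae_annual_risk: 0.0174
  fall_aki_split: [0.52, 0.48]
  minor_ae_annual_risk: 0.137
  prior_cvd_multiplier: 1.5

mortality:
  life_table: null                     # null = bundled synthetic fixture
  smr:
    mi: 2.68
    acs: 2.19
    angina: 1.95
    stroke: 2.72
    tia: 1.40
    hf: 2.17
    serious_fall: 1.49
    aki: 1.18

utilities:
  baseline: 0.769
  multipliers:
    stroke: 0.629
    mi: 0.778
    acs: 0.77
    angina: 0.88
    hf: 0.68
    serious_fall: 0.797
  decrements_annual:
    tia: 0.103
    aki: 0.15
    hypotension: 0.029
    syncope: 0.1
    bradycardia: 0.1
    electrolyte: 0.1
    nonserious_fall: 0.1

# Placeholder unit costs (GBP, 2017/18).  All flagged non-paper-default.
costs:
  consultations_per_cycle: 0.8         # published assumption, 0.8 per 3 months
  cost_per_consultation: 37.0
  cost_per_drug_per_cycle: 9.0
  safety_visit_cost: 37.0
  reinstatement_visit_cost: 37.0
  acute_event_costs:
    mi: 2400.0
    acs: 1900.0
    angina: 1100.0
    stroke: 4500.0
    tia: 1000.0
    hf: 2600.0
    serious_fall: 6000.0
    aki: 2500.0
    minor_ae: 0.0
  longterm_event_costs_per_cycle:
    mi: 60.0
    acs: 60.0
    angina: 50.0
    stroke: 500.0
    tia: 20.0
    hf: 220.0
    serious_fall: 150.0
    aki: 50.0

simulation:
  n_patients: 100000
  cycle_length_years: 0.25
  max_horizon_years: 20.0
  discount_rate_annual: 0.035
  half_cycle_correction: true
  seed: 20220310
  common_random_numbers: true
  wtp_thresholds: [20000.0, 30000.0]
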