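# Stand-in natural-history calibration (synthetic).
#
# These values are NOT a transcription of any published calibrated
# microsimulation model.  They were chosen once to yield plausible US-like
# benchmarks for an average-risk cohort entering at age 40:
#   - lifetime adenoma prevalence ~30-40%
#   - unscreened lifetime colorectal-cancer risk ~4-5%
# Users with access to a fully calibrated parameter set (e.g. a published
# natural-history model) should transcribe it into this schema and pass the
# file to the simulator; every field below is overridable.

adenoma_baseline_log_rate: -6.0      # log annual onset intensity at age-effect 1
frailty_sd: 1.1                      # sd of the individual log-risk deviate
sex_log_effect: 0.4                  # additive log-rate for males

# piecewise-constant age multipliers: [band start age, multiplier]
age_effect_knots:
  - [20, 0.5]
  - [40, 1.0]
  - [50, 1.4]
  - [60, 1.8]
  - [70, 2.0]

segment_probs: {colon: 0.72, rectum: 0.28}

# lognormal years from adenoma onset to 10 mm diameter, by segment
growth_time_to_10mm:
  colon:  {meanlog: 3.2, sdlog: 0.70}   # median ~24.5 y
  rectum: {meanlog: 3.0, sdlog: 0.70}   # median ~20.1 y

initial_diameter_mm: 1.0
max_diameter_mm: 50.0

# adenoma -> preclinical cancer hazard (see TransitionCoeffs)
transition_coeffs:
  log_hazard_at_10mm: -5.2
  size_power: 2.0
  male_log_effect: 0.2
  age_log_slope: 0.01

# lognormal years from preclinical onset to clinical presentation
sojourn_params: {meanlog: 0.95, sdlog: 0.5}   # median ~2.6 y, mean ~2.9 y

# mean years dwelling in preclinical AJCC stages I, II, III (IV absorbing)
stage_dwell_means: [1.0, 0.85, 0.75]

survival_params:
  cure_prob:     {1: 0.80, 2: 0.55, 3: 0.28, 4: 0.02}
  excess_hazard: {1: 0.08, 2: 0.18, 3: 0.40, 4: 0.85}   # per year if not cured
  age_band_edges: [65, 75]
  age_band_multipliers: [1.0, 1.15, 1.4]

life_table_csv: life_table_synthetic_us.csv
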