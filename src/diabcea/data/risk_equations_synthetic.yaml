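# SYNTHETIC default equation set for the annual-cycle outcomes
# microsimulation.  These coefficients were written for this package (and
# loosely tuned so a routine-care cohort of UK screen-detected type 2
# diabetes patients shows broadly plausible 30-year cumulative incidences);
# they are NOT the licensed coefficients of any published outcomes model.
synthetic: true
description: >-
  Synthetic annual-cycle equation set: deterministic risk-factor mean paths
  (x_t = intercept + a*x0 + b*t + c*x_{t-1}) and logistic annual event
  probabilities on age at diagnosis, sex, ethnicity, duration, current risk
  factors and prevalent-complication flags.
risk_factor_paths:
  hba1c: {intercept: 0.47, baseline: 0.0, duration: 0.0, lag: 0.95}
  sbp: {intercept: 7.25, baseline: 0.0, duration: 0.0, lag: 0.95}
  total_cholesterol: {intercept: 0.25, baseline: 0.0, duration: 0.0, lag: 0.95}
  hdl: {intercept: 0.06, baseline: 0.0, duration: 0.0, lag: 0.95}
  smoker: {intercept: 0.0, baseline: 0.0, duration: 0.0, lag: 1.0}
events:
  mi:
    link: logistic
    coefficients: {intercept: -8.10, age_diag: 0.030, male: 0.40, hba1c: 0.12,
                   sbp: 0.010, total_cholesterol: 0.12, hdl: -0.60, smoker: 0.35,
                   prev_ihd: 0.50}
  stroke:
    link: logistic
    coefficients: {intercept: -12.56, age_diag: 0.060, male: 0.15, hba1c: 0.08,
                   sbp: 0.025, smoker: 0.35, afro_caribbean: 0.30}
  ihd:
    link: logistic
    coefficients: {intercept: -8.27, age_diag: 0.020, male: 0.30, hba1c: 0.10,
                   sbp: 0.010, total_cholesterol: 0.15, hdl: -0.80, asian_indian: 0.30}
  heart_failure:
    link: logistic
    coefficients: {intercept: -11.77, age_diag: 0.060, hba1c: 0.08, sbp: 0.020,
                   prev_mi: 0.80, prev_ihd: 0.50}
  amputation:
    link: logistic
    coefficients: {intercept: -9.57, age_diag: 0.020, hba1c: 0.18, smoker: 0.40,
                   duration: 0.030}
  blindness:
    link: logistic
    coefficients: {intercept: -8.97, age_diag: 0.015, hba1c: 0.15, sbp: 0.008,
                   duration: 0.040}
  renal_failure:
    link: logistic
    coefficients: {intercept: -11.00, age_diag: 0.010, hba1c: 0.12, sbp: 0.015,
                   duration: 0.050}
  diabetes_death:
    link: logistic
    coefficients: {intercept: -9.85, age_diag: 0.060, duration: 0.040, hba1c: 0.10,
                   prev_mi: 0.60, prev_stroke: 0.50, prev_heart_failure: 0.70,
                   prev_renal_failure: 1.20, prev_amputation: 0.60}
  other_death:
    link: logistic
    coefficients: {intercept: -10.00, age_diag: 0.090, duration: 0.090, male: 0.20,
                   smoker: 0.40}
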