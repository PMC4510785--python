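# Default two-arm cohort configuration: baseline characteristics of a UK
# screen-detected type 2 diabetes trial population (means/sds/proportions),
# first-CVD-event hazards and follow-up distribution.
arms:
  routine:
    n: 511
    age: {mean: 60.1, sd: 7.5}
    female: 0.407
    caucasian: 0.867
    smoker: 0.180
    bmi: {mean: 33.0, sd: 5.9}
    total_cholesterol: {mean: 5.5, sd: 1.2}
    hdl: {mean: 1.2, sd: 0.3}
    sbp: {mean: 143.1, sd: 19.4}
    hba1c: {mean: 7.3, sd: 1.7}
  intensive:
    n: 513
    age: {mean: 61.1, sd: 7.2}
    female: 0.366
    caucasian: 0.918
    smoker: 0.177
    bmi: {mean: 33.1, sd: 5.6}
    total_cholesterol: {mean: 5.3, sd: 1.1}
    hdl: {mean: 1.2, sd: 0.4}
    sbp: {mean: 142.0, sd: 20.1}
    hba1c: {mean: 7.3, sd: 1.7}
centre_proportion_cambridge: 0.845   # 867 of 1026 participants
cvd_hazard_routine: 0.0159           # first events per person-year
hazard_ratio_intensive: 0.83
followup: {mean: 5.0, sd: 1.1, lo: 1.0, hi: 6.0}
# Intensive-arm shifts applied to the year-1 and year-5 measurements
# (modest risk-factor improvements attributable to intensified treatment).
treatment_effect:
  sbp: -1.5       # mmHg
  hba1c: -0.06    # percentage points
  total_cholesterol: -0.2  # mmol/l
missing_rate: 0.0
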