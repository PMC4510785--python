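# Metadata accompanying the itemised intervention delivery cost table
# (GBP, 2009/10 UK price level, multi-year rows pre-discounted at 3.5%/year).
discount_rate: 0.035
price_year_factor: 1.0          # multiplier to the 2009/10 price level
n_per_person_denominator: 513   # intensive-treatment arm headcount
centre_denominators:
  Cambridge: 452
  Leicester: 61
# Per-centre totals as recorded in the trial's own accounts. The itemised
# table does not determine this split: centre-tagged rows alone already
# exceed the Cambridge account total, so part of the Cambridge-run
# preparatory activity was attributed to Leicester in the accounts.
published_centre_totals:
  Cambridge: 412595
  Leicester: 90379
# Per-patient extra-prescription payment (a total over the 3-year official
# intervention duration) and that duration, used to annualise the continuing
# prescription cost in long-horizon modelling.
prescription_payment_per_patient: 262.5
intervention_duration_years: 3
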