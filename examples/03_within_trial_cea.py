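"""Within-trial cost-utility analysis over 1-5 year horizons.

Accumulates each patient's discounted costs and QALYs from their event
history, adds the intervention's per-person cost to the intensive arm, and
prints the cumulative table: per-arm means, covariate-adjusted incremental
cost and QALYs (OLS on arm, centre, age, sex, baseline HbA1c) and the ICER
classification.
"""

import diabcea as d

cfg = d.default_config(seed=11)
cohort = d.generate_cohort(cfg)
cohort = d.simulate_trial_events(
    cohort, cfg.cvd_hazard_routine, cfg.hazard_ratio_intensive, seed=12
)
tables = d.load_valuation_tables()

# per-person intervention schedule: materials up front, consultations over
# three years, prescriptions over the 3-year official duration
schedule = {1: 339.0 + 127.6 + 87.5, 2: 127.6 + 87.5, 3: 127.6 + 87.5}
table = d.cumulative_table(cohort, tables, horizons=(1, 2, 3, 4, 5), rate=0.035,
                           intervention_schedule=schedule)
cols = ["horizon", "n_routine", "n_intensive", "mean_cost_routine",
        "mean_cost_intensive", "delta_cost", "delta_qaly", "icer_class"]
print(table[cols].round(3).to_string(index=False))
print(
    "\ndelta_cost tracks the intervention spend (plus any excess event\n"
    "costs); delta_qaly is near zero over five years because few CVD events\n"
    "separate the arms this early - positive cost at ~zero QALY gain means\n"
    "the intervention is not cost-effective within the trial window."
)
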