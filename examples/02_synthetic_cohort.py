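"""Synthetic two-arm trial cohort.

Generates a cohort with the default baseline distributions (routine n=511,
intensive n=513), simulates first-CVD-event times at the configured hazards
(0.0159/person-year routine, hazard ratio 0.83), and prints the realised
epidemiology next to the generating parameters.
"""

import numpy as np

import diabcea as d

cfg = d.default_config(seed=2024)
cohort = d.generate_cohort(cfg)
cohort = d.simulate_trial_events(
    cohort, cfg.cvd_hazard_routine, cfg.hazard_ratio_intensive, seed=2025
)

for arm in ("routine", "intensive"):
    sub = cohort[cohort["arm"] == arm]
    events = (sub["event_type"] != "").sum()
    py = np.minimum(sub["event_year"].fillna(np.inf), sub["followup_years"]).sum()
    print(
        f"{arm:10s} n={len(sub):4d}  age {sub['age'].mean():.1f}  "
        f"HbA1c {sub['hba1c_y0'].mean():.2f}%  "
        f"events {events:3d}  incidence {1000 * events / py:.1f}/1000py  "
        f"follow-up {sub['followup_years'].mean():.2f}y"
    )

print(
    "\nIncidence should sit near 15.9 (routine) and 13.2 (intensive) per\n"
    "1000 person-years; at n~500/arm the Monte-Carlo error is ~+/-2."
)
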