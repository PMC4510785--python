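"""Long-term extrapolation with the outcomes microsimulation.

Runs the annual-cycle patient-level simulator over 10/20/30-year horizons
on a (small, for speed) imputed cohort: deterministic risk-factor paths
with observed year-0/1/5 overrides, yearly event draws from the synthetic
default equation set, valuation through the complication cost/utility
tables, inner-loop expectations and Rubin-pooled covariate-adjusted
incremental cost and QALYs.
"""

import diabcea as d
from diabcea import microsim as ms
from diabcea.imputation import ImputationConfig

cfg = d.default_config(seed=51, missing_rate=0.05)
for arm in cfg.arms.values():
    arm.n = 150  # scaled down for a quick demonstration
cohort = d.generate_cohort(cfg)
masked, _ = d.inject_missingness(cohort, 0.05, seed=52)
imputed = d.impute(masked, ImputationConfig(m=3, burn_in=100, thin=50, seed=53))

tables = d.load_valuation_tables()
equations = d.load_default_equations()
ledger = d.load_intervention_ledger()
sim = ms.SimulationConfig(
    horizons=(10, 20, 30), inner_loops=100, bootstraps=50, seed=54,
    annual_prescription_cost=ledger.annual_prescription_cost(),
)
res = d.cohort_extrapolate(
    imputed, equations, sim, tables,
    intervention_cost_per_person=d.ledger_totals(ledger)["per_person"],
)

print("Pooled adjusted increments (intensive - routine):")
print(res["increments"].round(4).to_string(index=False))
print("\n30-year cumulative incidence (mean per arm):")
inc30 = res["incidence"].query("horizon == 30")
print(inc30[["event", "routine", "intensive", "adjusted_difference"]].round(4).to_string(index=False))

for h in (10, 30):
    dc, dq = res["bootstrap"][h].mean(axis=0)
    print(f"\n{h}-year bootstrap mean increment: cost {dc:,.0f} GBP, QALYs {dq:.4f} "
          f"-> ICER {d.icer(dc, dq).classification}")
print(
    "\nCost increments are dominated by the up-front intervention cost plus\n"
    "the continuing prescription cost; QALY increments grow slowly as the\n"
    "intensive arm's lower risk-factor paths avert late events."
)
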