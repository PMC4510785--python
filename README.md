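# diabcea

Cost-utility analysis toolkit for two-arm trials of intensive multifactorial
treatment versus routine care in **screen-detected type 2 diabetes**, built
for health economists who need a tested, reusable pipeline rather than a
spreadsheet: intervention micro-costing, within-trial cost/QALY accumulation,
covariate-adjusted incremental estimates, multivariate-normal multiple
imputation, a patient-level outcomes microsimulation for 10–30-year
extrapolation, and the standard decision-uncertainty analyses.

Real patient-level data from such trials are not public, so the package
ships a first-class **synthetic cohort generator** calibrated to the
published trial population (routine n=511 / intensive n=513; first-CVD-event
hazard 15.9 per 1000 person-years in routine care, hazard ratio 0.83; mean
follow-up 5.0 years), and every downstream stage is exercised and tested on
those synthetic panels plus the published parameter tables.

## The model

For patient *i* in year *t* (year 1 undiscounted, discount rate *r* = 3.5%):

- **Cost**: `C_it = c_base + Σ_k [event_k(i,t)·c_k^event + prevalent_k(i,t)·c_k^subseq]`,
  the *additive* convention over complications *k* (diabetes base cost
  £494.5/year; e.g. non-fatal MI £6,861.8 in the event year, £1,129.8/year
  thereafter), all GBP at the 2009/10 UK price level.
- **Utility**: `U_it = max(0, 1 − δ_base − Σ_k present_k(i,t)·δ_k)` with
  additive decrements (δ_base = 0.220 for uncomplicated diabetes,
  δ_MI = 0.055, δ_stroke = 0.164, ...); QALYs are discounted sums of `U_it`.
- **Incremental estimates**: OLS of per-patient discounted cost and QALYs on
  treatment arm, centre, age at diagnosis, sex and baseline HbA1c; the arm
  coefficient is the adjusted ΔC or ΔQ, and `ICER = ΔC/ΔQ` with the usual
  dominance classification.
- **Extrapolation**: an annual-cycle microsimulation: risk factors follow
  `x_t = α + β·x_0 + γ·t + λ·x_{t−1}` (observed year-0/1/5 measurements
  override the path); each year every non-prevalent complication is drawn
  from a logistic (or Weibull hazard-increment) annual probability given the
  current state, deaths drawn last; expectations are inner-loop means
  (default 1000) and uncertainty comes from patient-level bootstrap (default
  100), pooled over m=5 imputations with Rubin's rules. The engine is
  coefficient-agnostic; the packaged default equation set is synthetic
  (clearly labelled — the licensed coefficients of the published UK outcomes
  model are not redistributable).
- **Decision uncertainty**: CE-plane bootstrap clouds, CEAC
  (`P(λ·ΔQ − ΔC > 0)`), threshold intervention cost
  `c* = c₀ − (ΔC − λ·ΔQ)`, scenario ICERs for cheaper delivery, and one-way
  tornado analysis (unit costs ±10%, decrements ±10%, discount rate 0–5%).

## Worked example

```python
import diabcea as d

# 1. the intervention's micro-costed delivery cost
totals = d.ledger_totals(d.load_intervention_ledger())
print(totals["rounded"]["subtotals"], totals["rounded"]["total"])
# {'delivery': 173895, 'extra_consultations': 190010, 'extra_treatments': 139069} 502974
print(round(totals["per_person"], 2))   # 980.46 per person in the intensive arm

# 2. the cost at which a 30-year ICER of 30,000 GBP/QALY is reached,
#    from the published 30-year adjusted increments
print(d.threshold_cost(1745.0, 0.0465, c0=981.0, lam=30_000.0))  # 631.0

# 3. scenario ICERs for cheaper delivery
print(d.scenario_icers(1745.0, 0.0465, 981.0, [981, 750, 500])["icer"].round(0).tolist())
# [37527.0, 32559.0, 27183.0]
```

The first block rebuilds the intervention cost table line by line (staff
time × unit rates, materials, per-patient payments) — £502,974 over five
years, £980.46 per intensive-arm participant. The second solves the
threshold analysis: delivered below £631/patient the intervention would meet
a £30,000/QALY willingness-to-pay; at its estimated cost it does not. The
third reprices the base case at three delivery costs.

The `examples/` directory holds one short narrative script per capability
(costing, cohort generation, within-trial CEA, imputation, long-term
extrapolation, uncertainty analysis); each prints the numbers it computes
and a line on what they mean.

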