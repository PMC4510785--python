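# Methods

This note documents the models and numerical conventions behind `diabcea`,
the choices made where the design was genuinely open, and what the synthetic
study conditions do and do not establish about real trial data.

## Scope and perspective

The package evaluates intensive multifactorial treatment against routine
care for screen-detected type 2 diabetes from a UK payer (NHS) perspective:
costs are NHS costs in GBP at the 2009/10 price level, outcomes are QALYs,
and both are discounted at 3.5% per annum with year 1 undiscounted (year *t*
weight `(1+r)^-(t-1)`). Only macrovascular complications plus blindness and
renal failure are modelled; microvascular disease beyond those two
conditions, EQ-5D tariff scoring, and the screening phase of such trials are
out of scope.

## Intervention micro-costing

The intervention's five-year delivery cost is rebuilt from itemised resource
lines: `value = unit_rate × quantity × multiplicity + extra`, where `extra`
carries additive lumps (travel, logistics), or a lump-sum override for rows
costed by internal trial accounting and for the consultation rows whose
printed values embed a 3.5% multi-year discount that is not exactly
recoverable from the printed unit rates (we verified symbolically that no
standard discounting convention reproduces them; fidelity to the printed
totals wins over reverse-engineering). Internal arithmetic is unrounded;
reporting rounds to the nearest pound, halves away from zero, which is the
convention the printed table follows (e.g. 61 × £262.5 = £16,012.5 →
£16,013).

Per-centre totals are reported two ways. The rule-based view allocates
shared rows to centres proportionally to intensive-arm headcount (452:61,
configurable weights). The published-accounts view uses the per-centre
totals recorded in the trial's own accounts, carried in the fixture
metadata: the itemised table cannot reproduce that split (its centre-tagged
rows alone already exceed the published Cambridge total — some centrally run
preparatory activity was evidently attributed to the other centre in the
accounts), so the accounts figure is data, not a derivable quantity.

The per-person cost divides by the intensive-arm headcount (513) and is
reported unrounded (£980.46). For long-horizon modelling the per-patient
extra-prescription payment (£262.5, a total over the intervention's 3-year
official duration) is annualised to £87.5/person/year and charged to
intensive-arm patients every simulated year — reading it as £262.5 *per
year* would add ≈£5,000 discounted over 30 years, inconsistent with the
scale of published 30-year cost increments.

## Valuation

Each condition carries up to four values: event-year cost (fatal /
non-fatal), subsequent-year cost, and a utility decrement applied in the
event year and every year thereafter. Annual cost is the base diabetes cost
(while alive) plus event-year costs for incident events plus subsequent-year
costs for prevalent complications; annual utility is `1 − Σ decrements`,
floored at 0, over the base condition, prevalent set and incident events.
Conventions where the source conventions are unstated:

- **Death year**: the full event-year cost is charged; the utility
  contribution is 0 (no half-cycle credit anywhere in the model).
- **Recurrence** (MI, revascularisation): each recurrence charges an
  event-year cost, but prevalence flags are absorbing, so the
  subsequent-year cost and the decrement apply once.
- **Fatal events without a specific fatal cost** fall back to the
  unattributed CVD-death cost (£3,724.3); a specific fatal cost takes
  precedence where tabulated.
- **Event timing**: an event at continuous time *y* lands in model year
  `ceil(y)` and becomes prevalent from the following year.
- The decrement applies fully (not pro-rata) in the event year, consistent
  with assigning the same value to event and subsequent years.

The utility baseline is full health (1.0); an uncomplicated alive year is
worth 0.780 QALYs and costs £494.5.

## Synthetic cohorts

The generator emulates the published trial population: per-arm normal
baseline distributions (age, BMI, total cholesterol, HDL, SBP, HbA1c) and
proportions (female, Caucasian, smoker), a centre indicator (Cambridge
0.845), and measurements at years 0, 1 and 5. Height is fixed per sex from
population norms (1.75 m / 1.62 m) and weight derived from the BMI draw so
BMI matches its target moments. Ethnicity is Caucasian at the configured
proportion with the remainder split equally between Afro-Caribbean and
Asian-Indian; unclassifiable ethnicities are not generated. Year-1/5
measurements are the baseline value plus a configurable intensive-arm
treatment effect (defaults ΔSBP −1.5 mmHg, ΔHbA1c −0.06 %, ΔChol −0.2
mmol/l — the "modest but significant" scale such trials report) plus
within-person remeasurement noise (sd = 10% of the between-person sd);
baseline smokers quit by year 1/5 with small arm-specific probabilities
(0.10/0.15 routine/intensive by year 1), which also keeps the smoking
columns from being perfectly collinear across years. HDL is capped at total
cholesterol − 0.1 throughout.

First CVD events are exponential at the arm hazard (routine
0.0159/person-year; intensive = routine × 0.83), censored at follow-up, with
the event type drawn from a configurable mix over {MI, stroke,
revascularisation, amputation, CVD death}. Follow-up is a truncated normal
on [1, 6] years whose *truncated* mean is matched to 5.0 exactly by solving
for the parent parameters; the pair (mean 5.0, sd 1.1) is infeasible on that
support — the family's maximum sd at mean 5.0 is ≈0.95 — so the sd is the
closest achievable (0.935). Missingness is MCAR only (each targeted cell
independently with the configured rate); real trials' missingness is
unlikely to be MCAR, and the imputation coverage results below are
conditional on that mechanism.

What passing tests on these cohorts show: the pipeline's estimators recover
known generating parameters (hazards, hazard ratios, injected cost effects,
distribution moments) at the configured trial scale. What they do not show:
agreement with the real trial's patient-level tables (cluster structure,
practice-level correlation, non-MCAR missingness and recruitment imbalance
are not emulated), which is why published within-trial cost/QALY rows are
structural targets only.

## Within-trial analysis

Per-patient discounted costs and QALYs over horizons 1–5 are accumulated
from each patient's event list; the intensive arm additionally receives the
per-person intervention schedule. Adjusted increments are the arm
coefficient of an OLS fit on arm, centre, age at diagnosis, sex and baseline
HbA1c (indicator coding, untransformed age/HbA1c, normal-theory 95% CIs;
covariates without variation are dropped rather than left to alias the
intercept, and genuinely collinear designs raise an error naming the
offending columns). A patient enters the horizon-*h* row only if followed at
least *h* years, so the per-horizon n shrinks the way published cumulative
tables do; partial-exposure patients are excluded from that row rather than
biasing its means downward. ICERs classify all sign quadrants: finite ratio,
infinite (ΔQ = 0 at positive cost), dominated (ΔC > 0, ΔQ < 0), dominant
(ΔC < 0, ΔQ > 0), equivalent (both zero).

## Multiple imputation

Missing values of weight, height, smoking status, total cholesterol, HDL,
SBP and HbA1c (all year-indexed measurement columns) are imputed under a
multivariate normal model by data augmentation: the I-step draws missing
cells from their conditional normal given observed cells and current
parameters, grouped by distinct missing pattern; the P-step draws the
covariance from its inverse-Wishart posterior and the mean from its
conditional normal (Jeffreys-type prior, with a small ridge
(1e-6 × mean variance) for numerical stability). Defaults: m = 5
imputations, 200 burn-in sweeps, 100 sweeps between retained imputations,
all driven by one seeded generator. Smoking is imputed on the latent normal
scale and thresholded at 0.5. After each imputation the HDL constraint is
repaired: an HDL strictly above total cholesterol (logically impossible) is
reset to cholesterol − 0.1; a stricter variant triggering at
cholesterol − 0.1 is available but off by default. Estimates are pooled with
Rubin's rules (total variance = within + (1 + 1/m) × between; CIs use
Rubin's degrees of freedom, normal when the between-variance vanishes).

The sampler is implemented in-package: the alternative library kernel we
evaluated groups missing patterns by a non-injective hash and can silently
leave cells unimputed, which is unacceptable for a pipeline stage.

## Outcomes microsimulation

An annual-cycle, patient-level state-transition simulation. Continuous risk
factors follow deterministic mean-path recurrences
`x_t = α + β·x_0 + γ·t + λ·x_{t−1}`; observed year-0/1/5 measurements
override the simulated value (so trial-observed trends propagate into the
future, the standard — and strong — extrapolation assumption of this model
family); smoking is carried forward. Stochasticity enters only through
event draws: each year, every non-prevalent complication is drawn
independently from an annual probability given by a linear predictor on age
at diagnosis, sex, ethnicity, duration, current risk factors and prevalent
complication flags through a logistic link (a Weibull hazard-increment link
`p_t = 1 − exp(−ΔH)`, `H(t) = exp(lp)·t^k`, is also supported). The two
death causes are evaluated last so a death year still records same-year
morbidity; dead patients accrue nothing. All prevalence flags start at zero
(everyone newly diagnosed). Per-patient expectations are inner-loop means
(default 1000); cohort-level uncertainty is patient-level bootstrap (default
100 replicates) of the covariate-adjusted increments computed on inner-loop
means; results are pooled over imputations by Rubin's rules. Risk-factor
paths carry no stochastic noise — a deliberate choice for reproducibility
and because the within-year event draws dominate the Monte-Carlo budget.

The packaged default equation set is **synthetic**, written for this package
and labelled as such in its YAML header: the licensed coefficients of the
published UK outcomes model are not redistributable. Its intercepts were
calibrated once, before any acceptance measurement, so a routine-arm cohort
shows broadly plausible 30-year cumulative incidences (MI ≈ 0.36,
stroke ≈ 0.17, heart failure ≈ 0.19, other-cause death ≈ 0.67); this is a
soft sanity band, not a validation claim, and no test asserts those values
tightly. Users with access to licensed or estimated equation sets supply
them as the same YAML structure.

## Decision uncertainty

CEAC: fraction of bootstrap (ΔC, ΔQ) pairs with strictly positive net
monetary benefit `λ·ΔQ − ΔC` per willingness-to-pay λ (ties count as not
cost-effective; measure-zero for continuous draws); the default λ grid is
0–£50,000 in £500 steps, bracketing the conventional UK £20k–£30k range.
Threshold cost `c* = c₀ − (ΔC − λ·ΔQ)` is the per-patient intervention cost
at which the ICER equals λ (undefined for ΔQ ≤ 0, signalled explicitly);
scenario ICERs reprice the increment at alternative delivery costs and
satisfy the exact round-trip identity `scenario_icer(threshold_cost(λ)) = λ`.
One-way tornado analysis perturbs unit treatment costs (±10%), utility
decrements (±10%) and the discount rate (0%, 5%) one at a time around the
30-year base case and reports ICER ranges sorted descending; a perturbation
with non-positive ΔQ reports the ICER class instead of a value. Figure
outputs are tidy CSV-ready frames; matplotlib rendering is optional
(`diabcea.plotting`).

## Problem sizes used in tests and the acceptance script

Distributional and recovery checks run at the sizes that make their
3-standard-error bands meaningful: cohort calibration at ~21,000 patients
per arm (≥100,000 person-years; Cox fit on 42,000 rows), moment checks at
6,000/arm, imputation CI coverage at 220 replications of n = 250 with
m = 5. Microsimulation checks use reduced inner loops (5–100) except the
enumeration oracle (60,000 loops against an exact 2-event/3-year
enumeration, agreement within 2%); full-scale defaults (1000 loops,
100 bootstraps) are exercised at small cohort sizes in the examples. These
are the package's chosen study sizes; scaling any of them up only narrows
the Monte-Carlo bands.

## Known limitations

- MCAR missingness and no practice-level (cluster) correlation in the
  generator; centre is the only design variable, mirroring the analytic
  choice of adjusting for centre rather than practice.
- The synthetic equation set reproduces qualitative behaviour
  (risk-factor-driven, age-driven mortality, prevalence feedback), not any
  estimated model's quantitative predictions.
- Follow-up sd is 0.935 rather than 1.1 (infeasible on the [1, 6] support
  at mean 5.0, see above).
- The additive cost/decrement convention is the model family's standard but
  contestable for multimorbidity; both tables are user-replaceable CSVs.
- No half-cycle correction, no expected-value-of-perfect-information
  analysis.
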