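"""Annual-cycle patient-level outcomes microsimulation.

Extrapolates a trial cohort over a 10-30 year horizon in yearly cycles.
Continuous risk factors follow deterministic path equations

    x_t = intercept + a * x_baseline + b * t + c * x_{t-1}

with observed trial measurements (years 0, 1 and 5) overriding the
simulated path.  Each year, every non-prevalent complication is drawn
independently from an annual probability given by a linear predictor on the
patient's current state through a logistic link (or a Weibull
hazard-increment link, p = 1 - exp(-dH)); the two death causes are
evaluated last, so a death year still records same-year morbidity.  Costs
and QALYs accrue through the valuation tables plus the continuing
intensive-arm prescription cost, discounted at the model rate.  A patient's
expected outcome is the mean over ``inner_loops`` Monte-Carlo passes;
decision uncertainty comes from bootstrap resampling of patients.

The engine is coefficient-agnostic.  The packaged default equation set is
SYNTHETIC (written for this package and labelled as such); it mimics the
broad behaviour of published type 2 diabetes outcome models but carries no
estimated coefficients from any of them.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from . import valuation as val
from .imputation import rubins_pool
from .within_trial import adjusted_increment

__all__ = [
    "PathEquation",
    "EventEquation",
    "RiskEquationSet",
    "SimulationConfig",
    "load_default_equations",
    "propagate_risk_factors",
    "simulate_patient",
    "cohort_extrapolate",
]

RISK_FACTORS = ("hba1c", "sbp", "total_cholesterol", "hdl", "smoker")
MORBIDITIES = (
    "ihd",
    "mi",
    "heart_failure",
    "stroke",
    "amputation",
    "blindness",
    "renal_failure",
)
DEATHS = ("diabetes_death", "other_death")
EVENTS = MORBIDITIES + DEATHS


@dataclass(frozen=True)
class PathEquation:
    """Deterministic annual path of one risk factor (mean trajectory)."""

    intercept: float = 0.0
    baseline: float = 0.0  # coefficient on the year-0 value
    duration: float = 0.0  # coefficient on years since diagnosis
    lag: float = 1.0  # coefficient on the previous-year value


@dataclass(frozen=True)
class EventEquation:
    """Annual event-probability equation.

    link='logistic': p_t = expit(lp_t).
    link='weibull':  p_t = 1 - exp(-(H(t) - H(t-1))), H(t) = exp(lp_t) t^shape.
    The linear predictor lp sums coefficient * covariate over named
    covariates (age_diag, male, afro_caribbean, asian_indian, duration,
    the current risk-factor values, and prev_<event> prevalence flags),
    plus an 'intercept' term.
    """

    link: str
    coefficients: dict[str, float]
    shape: float | None = None

    def __post_init__(self):
        if self.link not in ("logistic", "weibull"):
            raise ValueError(f"unknown link {self.link!r}")
        if self.link == "weibull" and (self.shape is None or self.shape <= 0):
            raise ValueError("weibull link requires shape > 0")


@dataclass
class RiskEquationSet:
    risk_factor_paths: dict[str, PathEquation]
    events: dict[str, EventEquation]
    synthetic: bool = True
    description: str = ""

    def validate(self) -> None:
        for f in RISK_FACTORS:
            if f not in self.risk_factor_paths:
                raise ValueError(f"missing path equation for {f!r}")
        for e in EVENTS:
            if e not in self.events:
                raise ValueError(f"missing event equation for {e!r}")

    @classmethod
    def from_yaml(cls, path) -> "RiskEquationSet":
        with (path.open() if hasattr(path, "open") else open(path)) as fh:
            raw = yaml.safe_load(fh)
        paths = {
            k: PathEquation(**v) for k, v in raw["risk_factor_paths"].items()
        }
        events = {
            k: EventEquation(
                link=v["link"],
                coefficients=dict(v["coefficients"]),
                shape=v.get("shape"),
            )
            for k, v in raw["events"].items()
        }
        obj = cls(
            risk_factor_paths=paths,
            events=events,
            synthetic=bool(raw.get("synthetic", True)),
            description=raw.get("description", ""),
        )
        obj.validate()
        return obj

    def to_yaml(self, path) -> None:
        raw = {
            "synthetic": self.synthetic,
            "description": self.description,
            "risk_factor_paths": {
                k: {f: getattr(v, f) for f in ("intercept", "baseline", "duration", "lag")}
                for k, v in self.risk_factor_paths.items()
            },
            "events": {
                k: {
                    "link": v.link,
                    **({"shape": v.shape} if v.shape is not None else {}),
                    "coefficients": dict(v.coefficients),
                }
                for k, v in self.events.items()
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def load_default_equations() -> RiskEquationSet:
    """The packaged synthetic default equation set."""
    p = resources.files("diabcea") / "data" / "risk_equations_synthetic.yaml"
    return RiskEquationSet.from_yaml(p)


@dataclass
class SimulationConfig:
    horizons: tuple = (10, 20, 30)
    inner_loops: int = 1000
    bootstraps: int = 100
    discount_rate: float = 0.035
    seed: int = 0
    #: trial measurement years whose observed values override the simulated path
    observed_years: tuple = (0, 1, 5)
    #: continuing per-person annual prescription cost in the intensive arm
    annual_prescription_cost: float = 87.5

    def __post_init__(self):
        if min(self.horizons) < 1:
            raise ValueError("horizons must be >= 1")
        if self.inner_loops < 1:
            raise ValueError("inner_loops must be >= 1")

    @property
    def horizon(self) -> int:
        return max(self.horizons)


def propagate_risk_factors(
    patient, equations: RiskEquationSet, horizon: int, observed_years=(0, 1, 5)
) -> pd.DataFrame:
    """Yearly risk-factor matrix (rows = years 0..horizon) for one patient
    (a cohort-panel row).  Observed measurements at ``observed_years``
    override the simulated path; everything else follows the path equations
    deterministically."""
    out = pd.DataFrame(index=range(horizon + 1), columns=RISK_FACTORS, dtype=float)
    for f in RISK_FACTORS:
        eq = equations.risk_factor_paths[f]
        x0 = patient.get(f"{f}_y0")
        if x0 is None or (isinstance(x0, float) and np.isnan(x0)):
            raise ValueError(f"missing baseline value for {f!r} (impute first)")
        x0 = float(x0)
        x = x0
        out.loc[0, f] = x0
        for t in range(1, horizon + 1):
            x = eq.intercept + eq.baseline * x0 + eq.duration * t + eq.lag * x
            if t in observed_years:
                obs = patient.get(f"{f}_y{t}")
                if obs is not None and not (isinstance(obs, float) and np.isnan(obs)):
                    x = float(obs)
            out.loc[t, f] = x
    return out


def _static_covariates(patient) -> dict[str, float]:
    return {
        "intercept": 1.0,
        "age_diag": float(patient["age"]),
        "male": float(patient["sex"] == "male"),
        "afro_caribbean": float(patient["ethnicity"] == "afro_caribbean"),
        "asian_indian": float(patient["ethnicity"] == "asian_indian"),
    }


def _base_linear_predictors(
    patient, rf: pd.DataFrame, equations: RiskEquationSet, horizon: int
) -> dict[str, np.ndarray]:
    """lp per event per year, excluding the prevalence-flag terms (which
    vary across inner loops)."""
    static = _static_covariates(patient)
    lps = {}
    for e, eq in equations.events.items():
        lp = np.zeros(horizon + 1)
        for name, c in eq.coefficients.items():
            if name in static:
                lp += c * static[name]
            elif name == "duration":
                lp += c * np.arange(horizon + 1)
            elif name in RISK_FACTORS:
                lp += c * rf[name].to_numpy()
            elif name.startswith("prev_"):
                continue
            else:
                raise ValueError(f"equation {e!r}: unknown covariate {name!r}")
        lps[e] = lp
    return lps


def _annual_prob(eq: EventEquation, lp_t: float | np.ndarray, t: int, event: str):
    if eq.link == "logistic":
        return expit(lp_t)
    dh = np.exp(lp_t) * (t**eq.shape - (t - 1) ** eq.shape)
    p = 1.0 - np.exp(-dh)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError(f"equation {event!r} produced probability outside [0, 1]")
    return p


def _valuation_arrays(tables: val.ValuationTables):
    ev_cost = np.array([tables.event_cost(e, fatal=False) for e in MORBIDITIES])
    sub_cost = np.array([tables.subsequent_cost(e) for e in MORBIDITIES])
    decr = np.array([tables.decrement(e) for e in MORBIDITIES])
    base_cost = tables.subsequent_cost(val.BASE_CONDITION)
    base_decr = tables.decrement(val.BASE_CONDITION)
    # diabetes deaths are cardiovascular-attributable in this model and
    # charge the unattributed CVD-death cost; other-cause deaths cost nothing
    dd_cost = tables.event_cost(val.CVD_DEATH, fatal=True)
    return ev_cost, sub_cost, decr, base_cost, base_decr, dd_cost


def simulate_patient(
    patient,
    equations: RiskEquationSet,
    config: SimulationConfig,
    tables: val.ValuationTables,
    rng: np.random.Generator,
    extra_annual_cost: float = 0.0,
):
    """Inner-loop expectation for one patient.

    Returns a dict with discounted ``cost``/``qaly`` snapshots at every year
    (cumulative, shape horizon+1 with index = years elapsed), per-event
    cumulative incidence by year (events x horizon+1), and expected
    life-years.  All prevalent-complication flags start at zero (everyone is
    newly diagnosed).
    """
    equations.validate()
    H = config.horizon
    rf = propagate_risk_factors(patient, equations, H, config.observed_years)
    lps = _base_linear_predictors(patient, rf, equations, H)
    ev_cost, sub_cost, decr, base_cost, base_decr, dd_cost = _valuation_arrays(tables)

    L = config.inner_loops
    nm = len(MORBIDITIES)
    prev = np.zeros((L, nm), dtype=bool)
    alive = np.ones(L, dtype=bool)
    cost_by_year = np.zeros((H + 1,))
    qaly_by_year = np.zeros((H + 1,))
    cuminc = np.zeros((len(EVENTS), H + 1))
    life_years = 0.0

    prev_coefs = {
        e: np.array(
            [equations.events[e].coefficients.get(f"prev_{m}", 0.0) for m in MORBIDITIES]
        )
        for e in EVENTS
    }

    for t in range(1, H + 1):
        w = (1.0 + config.discount_rate) ** -(t - 1)
        incident = np.zeros((L, nm), dtype=bool)
        for j, e in enumerate(MORBIDITIES):
            eq = equations.events[e]
            lp = lps[e][t] + prev @ prev_coefs[e]
            p = _annual_prob(eq, lp, t, e)
            occur = alive & ~prev[:, j] & (rng.random(L) < p)
            incident[:, j] = occur
            cuminc[j, t:] += occur.sum()
        # deaths evaluated last: a death year still records morbidity
        eq_dd = equations.events["diabetes_death"]
        p_dd = _annual_prob(eq_dd, lps["diabetes_death"][t] + prev @ prev_coefs["diabetes_death"], t, "diabetes_death")
        died_dd = alive & (rng.random(L) < p_dd)
        eq_od = equations.events["other_death"]
        p_od = _annual_prob(eq_od, lps["other_death"][t] + prev @ prev_coefs["other_death"], t, "other_death")
        died_od = alive & ~died_dd & (rng.random(L) < p_od)
        cuminc[len(MORBIDITIES), t:] += died_dd.sum()
        cuminc[len(MORBIDITIES) + 1, t:] += died_od.sum()
        died = died_dd | died_od

        year_cost = (
            alive * (base_cost + extra_annual_cost)
            + incident @ ev_cost
            + (prev & alive[:, None]) @ sub_cost
            + died_dd * dd_cost
        )
        utility = np.maximum(1.0 - base_decr - (prev | incident) @ decr, 0.0)
        year_qaly = np.where(alive & ~died, utility, 0.0)
        cost_by_year[t] = w * year_cost.sum() / L
        qaly_by_year[t] = w * year_qaly.sum() / L
        life_years += alive.sum() / L

        prev |= incident
        alive &= ~died

    return {
        "cost": np.cumsum(cost_by_year),
        "qaly": np.cumsum(qaly_by_year),
        "cumulative_incidence": cuminc / L,
        "life_years": life_years,
        "risk_factors": rf,
    }


def _simulate_completed_cohort(cohort, equations, config, tables, rng):
    """Per-patient expected outcomes for one completed (imputed) cohort."""
    rows = []
    for _, patient in cohort.iterrows():
        extra = (
            config.annual_prescription_cost if patient["arm"] == "intensive" else 0.0
        )
        res = simulate_patient(patient, equations, config, tables, rng, extra)
        r = {
            "id": patient["id"],
            "arm": patient["arm"],
            "centre": patient["centre"],
            "age": patient["age"],
            "sex": patient["sex"],
            "hba1c_y0": patient["hba1c_y0"],
        }
        for h in config.horizons:
            r[f"cost_{h}"] = res["cost"][h]
            r[f"qaly_{h}"] = res["qaly"][h]
            for j, e in enumerate(EVENTS):
                r[f"inc_{e}_{h}"] = res["cumulative_incidence"][j, h]
        rows.append(r)
    return pd.DataFrame(rows)


def cohort_extrapolate(
    imputed_cohorts: list[pd.DataFrame],
    equations: RiskEquationSet,
    config: SimulationConfig,
    tables: val.ValuationTables,
    intervention_cost_per_person: float = 0.0,
):
    """Extrapolate m completed cohorts and pool with Rubin's rules.

    Returns a dict with:
      - ``increments``: per-horizon pooled adjusted incremental cost/QALYs
        (the per-person up-front intervention cost is added to the cost
        increment);
      - ``incidence``: per-arm mean cumulative incidence per event/horizon
        plus the adjusted arm difference;
      - ``bootstrap``: per-horizon (B x 2) arrays of resampled adjusted
        (dCost, dQALY) pairs feeding the CE plane / CEAC;
      - ``patient_means``: the per-patient expected outcomes, averaged over
        imputations.
    """
    rng = np.random.default_rng(config.seed)
    per_imp = [
        _simulate_completed_cohort(c, equations, config, tables, rng)
        for c in imputed_cohorts
    ]
    m = len(per_imp)

    increments = []
    for h in config.horizons:
        for outcome, label in ((f"cost_{h}", "cost"), (f"qaly_{h}", "qaly")):
            ests, variances = [], []
            for df in per_imp:
                e = adjusted_increment(df, outcome)
                ests.append(e.estimate)
                variances.append(e.se**2)
            pooled = rubins_pool(ests, variances) if m >= 2 else None
            if pooled is None:
                e = adjusted_increment(per_imp[0], outcome)
                point, lo, hi = e.estimate, e.ci_low, e.ci_high
            else:
                point, lo, hi = pooled.estimate, pooled.ci_low, pooled.ci_high
            if label == "cost":
                point, lo, hi = (
                    point + intervention_cost_per_person,
                    lo + intervention_cost_per_person,
                    hi + intervention_cost_per_person,
                )
            increments.append(
                {
                    "horizon": h,
                    "outcome": label,
                    "estimate": point,
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
    increments = pd.DataFrame(increments)

    stacked = pd.concat(per_imp).groupby("id").mean(numeric_only=True)
    meta = per_imp[0].set_index("id")[["arm", "centre", "sex"]]
    patient_means = stacked.join(meta).reset_index()

    inc_rows = []
    for h in config.horizons:
        for e in EVENTS:
            col = f"inc_{e}_{h}"
            row = {"horizon": h, "event": e}
            for arm in ("routine", "intensive"):
                row[arm] = patient_means.loc[patient_means["arm"] == arm, col].mean()
            adj = adjusted_increment(patient_means, col)
            row["adjusted_difference"] = adj.estimate
            row["se"] = adj.se
            inc_rows.append(row)
    incidence = pd.DataFrame(inc_rows)

    boot = {h: np.empty((config.bootstraps, 2)) for h in config.horizons}
    n = len(patient_means)
    for b in range(config.bootstraps):
        idx = rng.integers(0, n, n)
        sample = patient_means.iloc[idx]
        for h in config.horizons:
            dc = adjusted_increment(sample, f"cost_{h}").estimate
            dq = adjusted_increment(sample, f"qaly_{h}").estimate
            boot[h][b] = (dc + intervention_cost_per_person, dq)

    return {
        "increments": increments,
        "incidence": incidence,
        "bootstrap": boot,
        "patient_means": patient_means,
    }


def tornado_runner(
    imputed_cohorts,
    equations: RiskEquationSet,
    config: SimulationConfig,
    tables: val.ValuationTables,
    intervention_cost_per_person: float,
    horizon: int | None = None,
):
    """Wire the microsimulation to the one-way sensitivity layer: returns an
    ``evaluate(**overrides)`` callable producing the (dCost, dQALY) pair at
    ``horizon`` under a single perturbation of unit costs, utility
    decrements or the discount rate."""
    h = horizon or config.horizon

    def evaluate(cost_scale=1.0, decrement_scale=1.0, discount_rate=None):
        t = val.scaled_tables(tables, cost_scale, decrement_scale)
        cfg = SimulationConfig(
            horizons=(h,),
            inner_loops=config.inner_loops,
            bootstraps=1,
            discount_rate=config.discount_rate if discount_rate is None else discount_rate,
            seed=config.seed,
            observed_years=config.observed_years,
            annual_prescription_cost=config.annual_prescription_cost * cost_scale,
        )
        res = cohort_extrapolate(
            imputed_cohorts, equations, cfg, t, intervention_cost_per_person * cost_scale
        )
        inc = res["increments"].set_index("outcome")
        return float(inc.loc["cost", "estimate"]), float(inc.loc["qaly", "estimate"])

    return evaluate
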