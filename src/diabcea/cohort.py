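"""Synthetic two-arm trial cohorts.

Generates patient panels with the statistical structure a screen-detected
type 2 diabetes treatment trial assumes: arm-specific baseline covariate
distributions, risk-factor measurements at years 0/1/5 (with a small
intensive-arm treatment effect), first-CVD-event times from an exponential
hazard with a configurable arm hazard ratio, censoring at a truncated-normal
follow-up, and MCAR missingness.

The canonical in-memory container is a wide pandas DataFrame, one row per
patient (year-indexed measurement columns ``sbp_y0`` ... ``hdl_y5``), which
round-trips to CSV with empty cells for missing values and a YAML sidecar
recording every generation parameter and the seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources

from functools import lru_cache

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

__all__ = [
    "CohortConfig",
    "default_config",
    "generate_cohort",
    "simulate_trial_events",
    "inject_missingness",
    "write_cohort_csv",
    "read_cohort_csv",
    "MEASUREMENT_VARS",
    "IMPUTABLE_VARS",
]

ARMS = ("routine", "intensive")
ETHNICITIES = ("caucasian", "afro_caribbean", "asian_indian")
MEASUREMENT_YEARS = (0, 1, 5)
MEASUREMENT_VARS = ("sbp", "hba1c", "total_cholesterol", "hdl", "smoker")
#: the variables imputed on the multivariate-normal scale downstream
IMPUTABLE_VARS = ("weight", "height", "smoker", "total_cholesterol", "hdl", "sbp", "hba1c")
#: composition of the first-CVD-event mix (type -> probability, fatal flag on cvd_death)
DEFAULT_EVENT_MIX = {
    "mi": 0.35,
    "stroke": 0.25,
    "revascularisation": 0.30,
    "amputation": 0.03,
    "cvd_death": 0.07,
}
# sex-specific adult heights (m) used to derive weight from the BMI draw
HEIGHT_BY_SEX = {"male": 1.75, "female": 1.62}


def _check_prop(name, p):
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"{name} must be a proportion in [0, 1], got {p}")


@dataclass
class ArmConfig:
    n: int
    age: tuple[float, float]
    female: float
    caucasian: float
    smoker: float
    bmi: tuple[float, float]
    total_cholesterol: tuple[float, float]
    hdl: tuple[float, float]
    sbp: tuple[float, float]
    hba1c: tuple[float, float]

    def validate(self, arm: str) -> None:
        if self.n < 1:
            raise ValueError(f"{arm}: n must be >= 1")
        for p in ("female", "caucasian", "smoker"):
            _check_prop(f"{arm}.{p}", getattr(self, p))
        for v in ("age", "bmi", "total_cholesterol", "hdl", "sbp", "hba1c"):
            _, sd = getattr(self, v)
            if sd < 0:
                raise ValueError(f"{arm}.{v}: sd must be >= 0")


@dataclass
class CohortConfig:
    arms: dict[str, ArmConfig]
    centre_proportion_cambridge: float = 0.845
    cvd_hazard_routine: float = 0.0159  # first events per person-year
    hazard_ratio_intensive: float = 0.83
    followup: tuple[float, float] = (5.0, 1.1)  # mean, sd (years)
    followup_bounds: tuple[float, float] = (1.0, 6.0)
    treatment_effect: dict[str, float] = field(
        default_factory=lambda: {"sbp": -1.5, "hba1c": -0.06, "total_cholesterol": -0.2}
    )
    remeasurement_sd_fraction: float = 0.1  # within-person noise at years 1/5
    #: per-arm probability of a baseline smoker having quit by each
    #: measurement year (conditional on still smoking at the previous one);
    #: newly diagnosed smokers are encouraged to stop, more so under
    #: intensive treatment
    smoking_quit_prob: dict[str, dict[int, float]] = field(
        default_factory=lambda: {
            "routine": {1: 0.10, 5: 0.10},
            "intensive": {1: 0.15, 5: 0.10},
        }
    )
    event_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EVENT_MIX))
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for arm in ARMS:
            if arm not in self.arms:
                raise ValueError(f"missing arm config {arm!r}")
            self.arms[arm].validate(arm)
        _check_prop("centre_proportion_cambridge", self.centre_proportion_cambridge)
        if self.cvd_hazard_routine <= 0 or self.hazard_ratio_intensive <= 0:
            raise ValueError("hazards must be > 0")
        if self.followup[1] < 0:
            raise ValueError("follow-up sd must be >= 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if abs(sum(self.event_mix.values()) - 1.0) > 1e-9:
            raise ValueError("event mix probabilities must sum to 1")

    def arm_hazard(self, arm: str) -> float:
        h = self.cvd_hazard_routine
        return h * self.hazard_ratio_intensive if arm == "intensive" else h


def default_config(**overrides) -> CohortConfig:
    """Configuration matching the published baseline characteristics of the
    two trial arms (n=511 routine / n=513 intensive)."""
    path = resources.files("diabcea") / "data" / "baseline_characteristics.yaml"
    with path.open() as fh:
        raw = yaml.safe_load(fh)
    arms = {}
    for arm, a in raw["arms"].items():
        arms[arm] = ArmConfig(
            n=a["n"],
            age=(a["age"]["mean"], a["age"]["sd"]),
            female=a["female"],
            caucasian=a["caucasian"],
            smoker=a["smoker"],
            bmi=(a["bmi"]["mean"], a["bmi"]["sd"]),
            total_cholesterol=(a["total_cholesterol"]["mean"], a["total_cholesterol"]["sd"]),
            hdl=(a["hdl"]["mean"], a["hdl"]["sd"]),
            sbp=(a["sbp"]["mean"], a["sbp"]["sd"]),
            hba1c=(a["hba1c"]["mean"], a["hba1c"]["sd"]),
        )
    fu = raw["followup"]
    cfg = CohortConfig(
        arms=arms,
        centre_proportion_cambridge=raw["centre_proportion_cambridge"],
        cvd_hazard_routine=raw["cvd_hazard_routine"],
        hazard_ratio_intensive=raw["hazard_ratio_intensive"],
        followup=(fu["mean"], fu["sd"]),
        followup_bounds=(fu["lo"], fu["hi"]),
        treatment_effect=dict(raw["treatment_effect"]),
        missing_rate=raw["missing_rate"],
    )
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise TypeError(f"unknown config field {k!r}")
        setattr(cfg, k, v)
    cfg.validate()
    return cfg


def _truncnorm(rng, mean, sd, lo, hi, size):
    if sd == 0:
        return np.full(size, float(mean))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _trunc_moments(mu, sigma, lo, hi):
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
    return float(m), float(np.sqrt(v))


@lru_cache(maxsize=32)
def _matched_truncnorm_params(mean, sd, lo, hi):
    """Parent (mu, sigma) of a [lo, hi]-truncated normal whose TRUNCATED
    distribution has mean exactly ``mean`` and sd as close to ``sd`` as the
    support permits.

    Plain truncation of N(mean, sd) biases the mean towards the interval
    centre, so the parent mean is solved numerically.  Some (mean, sd)
    pairs are unattainable on a finite interval (the requested sd exceeds
    the family's maximum dispersion at that mean); the mean is then matched
    exactly and the sd is the closest achievable.
    """
    if not (lo < mean < hi):
        raise ValueError(f"target mean {mean} outside truncation bounds [{lo}, {hi}]")

    def mu_for_mean(sigma):
        # truncated mean is increasing in mu, spanning (lo, hi)
        f = lambda mu: _trunc_moments(mu, sigma, lo, hi)[0] - mean
        span = 60 * sigma + (hi - lo)
        return optimize.brentq(f, lo - span, hi + span, xtol=1e-10)

    lo_s, hi_s = sd / 4, sd * 12
    best = None
    for _ in range(3):  # grid search, refined twice around the incumbent
        for sigma in np.geomspace(lo_s, hi_s, 33):
            mu = mu_for_mean(sigma)
            err = abs(_trunc_moments(mu, sigma, lo, hi)[1] - sd)
            if best is None or err < best[0]:
                best = (err, mu, sigma)
        lo_s, hi_s = best[2] / 1.3, best[2] * 1.3
    return float(best[1]), float(best[2])


def _followup_draw(rng, mean, sd, lo, hi, size):
    if sd == 0:
        return np.full(size, float(mean))
    mu, sigma = _matched_truncnorm_params(mean, sd, lo, hi)
    return _truncnorm(rng, mu, sigma, lo, hi, size)


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a cohort (baseline covariates, year-0/1/5 measurements and
    follow-up) deterministically from ``config.seed``.  Events are added by
    :func:`simulate_trial_events`."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    frames = []
    offset = 0
    for arm in ARMS:
        a = config.arms[arm]
        n = a.n
        age = np.maximum(rng.normal(*a.age, n), 18.0) if a.age[1] > 0 else np.full(n, a.age[0])
        female = rng.random(n) < a.female
        u = rng.random(n)
        ethnicity = np.where(
            u < a.caucasian,
            "caucasian",
            np.where(u < a.caucasian + (1 - a.caucasian) / 2, "afro_caribbean", "asian_indian"),
        )
        smoker = rng.random(n) < a.smoker
        height = np.where(female, HEIGHT_BY_SEX["female"], HEIGHT_BY_SEX["male"])
        bmi = _truncnorm(rng, a.bmi[0], a.bmi[1], 15.0, 60.0, n)
        weight = bmi * height**2
        centre = np.where(
            rng.random(n) < config.centre_proportion_cambridge, "Cambridge", "Leicester"
        )
        followup = _followup_draw(
            rng, config.followup[0], config.followup[1], *config.followup_bounds, size=n
        )

        base = {
            "sbp": rng.normal(*a.sbp, n) if a.sbp[1] > 0 else np.full(n, a.sbp[0]),
            "hba1c": np.maximum(
                rng.normal(*a.hba1c, n) if a.hba1c[1] > 0 else np.full(n, a.hba1c[0]), 4.0
            ),
            "total_cholesterol": np.maximum(
                rng.normal(*a.total_cholesterol, n)
                if a.total_cholesterol[1] > 0
                else np.full(n, a.total_cholesterol[0]),
                2.0,
            ),
            "hdl": np.maximum(
                rng.normal(*a.hdl, n) if a.hdl[1] > 0 else np.full(n, a.hdl[0]), 0.4
            ),
        }
        # physiological consistency: HDL cannot exceed total cholesterol
        base["hdl"] = np.minimum(base["hdl"], base["total_cholesterol"] - 0.1)

        df = pd.DataFrame(
            {
                "id": np.arange(offset, offset + n),
                "arm": arm,
                "centre": centre,
                "age": age,
                "sex": np.where(female, "female", "male"),
                "ethnicity": ethnicity,
                "height": height,
                "weight": weight,
                "followup_years": followup,
            }
        )
        for v in ("sbp", "hba1c", "total_cholesterol", "hdl"):
            df[f"{v}_y0"] = base[v]
        df["smoker_y0"] = smoker.astype(int)
        current_smoker = smoker.copy()
        for year in MEASUREMENT_YEARS[1:]:
            for v in ("sbp", "hba1c", "total_cholesterol", "hdl"):
                effect = config.treatment_effect.get(v, 0.0) if arm == "intensive" else 0.0
                noise_sd = config.remeasurement_sd_fraction * getattr(a, v)[1]
                noise = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else 0.0
                df[f"{v}_y{year}"] = base[v] + effect + noise
            quit_p = config.smoking_quit_prob.get(arm, {}).get(year, 0.0)
            current_smoker = current_smoker & ~(rng.random(n) < quit_p)
            df[f"smoker_y{year}"] = current_smoker.astype(int)
        for year in MEASUREMENT_YEARS[1:]:
            df[f"hdl_y{year}"] = np.minimum(
                df[f"hdl_y{year}"], df[f"total_cholesterol_y{year}"] - 0.1
            )
        frames.append(df)
        offset += n
    out = pd.concat(frames, ignore_index=True)
    out["event_type"] = ""
    out["event_year"] = np.nan
    out["event_fatal"] = 0
    out["alive"] = 1
    return out


def simulate_trial_events(
    cohort: pd.DataFrame,
    cvd_hazard_routine: float,
    hazard_ratio: float,
    seed: int,
    event_mix: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Draw first-CVD-event times from the arm-specific exponential hazard,
    censored at each patient's follow-up; the event type is sampled from the
    configured mix (``cvd_death`` is fatal)."""
    if cvd_hazard_routine <= 0 or hazard_ratio <= 0:
        raise ValueError("hazards must be > 0")
    mix = dict(DEFAULT_EVENT_MIX if event_mix is None else event_mix)
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("event mix probabilities must sum to 1")
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    hazard = np.where(
        out["arm"].to_numpy() == "intensive",
        cvd_hazard_routine * hazard_ratio,
        cvd_hazard_routine,
    )
    t_event = rng.exponential(1.0 / hazard)
    observed = t_event <= out["followup_years"].to_numpy()
    types = rng.choice(list(mix), p=list(mix.values()), size=len(out))
    out["event_type"] = np.where(observed, types, "")
    out["event_year"] = np.where(observed, t_event, np.nan)
    out["event_fatal"] = (observed & (types == "cvd_death")).astype(int)
    out["alive"] = 1 - out["event_fatal"]
    return out


def events_of(row) -> list[tuple[str, float, bool]]:
    """Event list of one cohort row in the (condition, year, fatal) form the
    valuation layer consumes."""
    if not row["event_type"]:
        return []
    return [(row["event_type"], float(row["event_year"]), bool(row["event_fatal"]))]


def inject_missingness(
    cohort: pd.DataFrame,
    missing_rate: float,
    variables=IMPUTABLE_VARS,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Set each targeted cell missing independently with probability
    ``missing_rate`` (MCAR).  Returns (masked cohort, withheld truth copy).

    ``variables`` are base variable names; all their year-indexed measurement
    columns (and the static weight/height columns) are targeted.
    """
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing rate must be in [0, 1)")
    truth = cohort.copy()
    out = cohort.copy()
    if missing_rate == 0.0:
        return out, truth
    rng = np.random.default_rng(seed)
    cols = []
    for v in variables:
        if v in ("weight", "height"):
            cols.append(v)
        else:
            cols.extend(f"{v}_y{y}" for y in MEASUREMENT_YEARS if f"{v}_y{y}" in out)
    for c in cols:
        mask = rng.random(len(out)) < missing_rate
        out[c] = out[c].astype(float).mask(mask)
    return out, truth


def write_cohort_csv(cohort: pd.DataFrame, path, config: CohortConfig | None = None) -> None:
    """Write the panel as CSV (missing cells -> empty fields); if a config is
    given, a ``<path>.yaml`` sidecar records all generation parameters."""
    cohort.to_csv(path, index=False, float_format="%.10g")
    if config is not None:
        raw = copy.deepcopy(vars(config))
        raw["arms"] = {k: vars(v) for k, v in config.arms.items()}
        with open(f"{path}.yaml", "w") as fh:
            yaml.safe_dump(_plain(raw), fh, sort_keys=False)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=True)
    df["event_type"] = df["event_type"].fillna("")
    return df
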