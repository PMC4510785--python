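"""Annual cost and utility valuation of patient health states.

Maps a patient-year (prevalent complications, incident events, vital
status) to that year's NHS cost and QALY weight using per-condition unit
costs and utility decrements, with the additive convention for multiple
complications: costs of co-occurring conditions are summed, and the QALY
weight is 1 minus the sum of decrements (floored at zero).

Conditions carry up to four values: an event-year cost when the event is
fatal, an event-year cost when non-fatal, an annual cost for every
subsequent year lived with the condition, and a utility decrement applied
in the event year and in all subsequent years.  The background cost and
decrement of uncomplicated type 2 diabetes (``t2dm``) apply to every year
alive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

__all__ = [
    "ValuationTables",
    "PatientYearState",
    "annual_cost",
    "annual_utility",
    "accumulate",
    "load_valuation_tables",
]

BASE_CONDITION = "t2dm"
CVD_DEATH = "cvd_death"


@dataclass(frozen=True)
class ConditionValues:
    cost_event_fatal: float | None
    cost_event_nonfatal: float | None
    cost_subsequent: float | None
    utility_decrement: float | None  # stored as a positive magnitude

    def __post_init__(self):
        for n in ("cost_event_fatal", "cost_event_nonfatal", "cost_subsequent"):
            v = getattr(self, n)
            if v is not None and v < 0:
                raise ValueError(f"negative cost {n}")
        d = self.utility_decrement
        if d is not None and not (0.0 <= d <= 1.0):
            raise ValueError("utility decrement outside [0, 1]")


@dataclass
class ValuationTables:
    """Per-condition unit costs (GBP) and utility decrements."""

    conditions: dict[str, ConditionValues]

    def __post_init__(self):
        if BASE_CONDITION not in self.conditions:
            raise ValueError(f"tables must include the base condition {BASE_CONDITION!r}")

    def _get(self, condition: str) -> ConditionValues:
        try:
            return self.conditions[condition]
        except KeyError:
            raise KeyError(f"unknown condition {condition!r}") from None

    def event_cost(self, condition: str, fatal: bool) -> float:
        cv = self._get(condition)
        if fatal:
            if cv.cost_event_fatal is not None:
                return cv.cost_event_fatal
            # fatal event of a condition without a specific fatal cost:
            # fall back to the unattributed CVD-death cost
            fb = self._get(CVD_DEATH).cost_event_fatal
            return fb if fb is not None else 0.0
        return cv.cost_event_nonfatal or 0.0

    def subsequent_cost(self, condition: str) -> float:
        return self._get(condition).cost_subsequent or 0.0

    def decrement(self, condition: str) -> float:
        return self._get(condition).utility_decrement or 0.0


@dataclass
class PatientYearState:
    """Health state of one patient in one model year (t >= 1)."""

    year: int
    prevalent: frozenset = field(default_factory=frozenset)
    incident: tuple = ()  # tuple of (condition, fatal_flag)
    alive_at_start: bool = True
    died_this_year: bool = False

    def __post_init__(self):
        if self.year < 1:
            raise ValueError("year index starts at 1")
        if not self.alive_at_start and self.incident:
            raise ValueError("dead patients cannot have incident events")


def annual_cost(state: PatientYearState, tables: ValuationTables) -> float:
    """NHS cost of one patient-year: base diabetes cost while alive, plus
    event-year costs for incident events and subsequent-year costs for
    prevalent complications.  Zero for years fully after death."""
    if not state.alive_at_start:
        return 0.0
    cost = tables.subsequent_cost(BASE_CONDITION)
    for condition, fatal in state.incident:
        cost += tables.event_cost(condition, fatal)
    for condition in state.prevalent:
        cost += tables.subsequent_cost(condition)
    return cost


def annual_utility(state: PatientYearState, tables: ValuationTables) -> float:
    """QALY weight of one patient-year: 1 minus the summed decrements of the
    base condition, prevalent complications and this year's incident events,
    floored at 0.  Death years (and later years) contribute 0."""
    if not state.alive_at_start or state.died_this_year:
        return 0.0
    seen = {BASE_CONDITION} | set(state.prevalent)
    seen |= {c for c, _ in state.incident}
    u = 1.0 - sum(tables.decrement(c) for c in seen)
    return max(u, 0.0)


def accumulate(
    events,
    horizon: int,
    rate: float,
    tables: ValuationTables,
    extra_annual_cost: float = 0.0,
) -> tuple[float, float]:
    """Discounted (cost, QALYs) of one patient over ``horizon`` years.

    ``events`` is an iterable of (condition, year, fatal) with real-valued
    event years; an event at time y lands in model year ceil(y) (clamped to
    year 1) and makes the condition prevalent from the following year on.
    Year t is discounted by (1+rate)^-(t-1).  ``extra_annual_cost`` is added
    to every alive year (e.g. the continuing intervention prescription cost).
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    by_year: dict[int, list[tuple[str, bool]]] = {}
    for condition, year, fatal in events:
        t = max(1, math.ceil(float(year)))
        by_year.setdefault(t, []).append((condition, bool(fatal)))

    cost = qaly = 0.0
    prevalent: set[str] = set()
    alive = True
    for t in range(1, horizon + 1):
        incident = tuple(by_year.get(t, ())) if alive else ()
        died = any(f for _, f in incident)
        state = PatientYearState(
            year=t,
            prevalent=frozenset(prevalent),
            incident=incident,
            alive_at_start=alive,
            died_this_year=died,
        )
        w = (1.0 + rate) ** -(t - 1)
        cost += w * (annual_cost(state, tables) + (extra_annual_cost if alive else 0.0))
        qaly += w * annual_utility(state, tables)
        for condition, _ in incident:
            if condition != CVD_DEATH:
                prevalent.add(condition)
        if died:
            alive = False
    return cost, qaly


def load_valuation_tables(csv_path=None) -> ValuationTables:
    """Read the packaged per-condition cost/decrement table (or a user CSV
    with columns condition,cost_event_fatal,cost_event_nonfatal,
    cost_subsequent,utility_decrement)."""
    if csv_path is None:
        csv_path = resources.files("diabcea") / "data" / "complication_valuation.csv"
    with (csv_path.open() if hasattr(csv_path, "open") else open(csv_path)) as fh:
        df = pd.read_csv(fh)
    conditions = {}
    for _, r in df.iterrows():
        conditions[str(r["condition"])] = ConditionValues(
            cost_event_fatal=None if pd.isna(r["cost_event_fatal"]) else float(r["cost_event_fatal"]),
            cost_event_nonfatal=None if pd.isna(r["cost_event_nonfatal"]) else float(r["cost_event_nonfatal"]),
            cost_subsequent=None if pd.isna(r["cost_subsequent"]) else float(r["cost_subsequent"]),
            utility_decrement=None if pd.isna(r["utility_decrement"]) else float(r["utility_decrement"]),
        )
    return ValuationTables(conditions=conditions)


def scaled_tables(
    tables: ValuationTables, cost_scale: float = 1.0, decrement_scale: float = 1.0
) -> ValuationTables:
    """Copy of the tables with all costs (resp. decrements) multiplied by a
    factor — the one-way sensitivity perturbations."""
    out = {}
    for name, cv in tables.conditions.items():
        out[name] = ConditionValues(
            cost_event_fatal=None if cv.cost_event_fatal is None else cv.cost_event_fatal * cost_scale,
            cost_event_nonfatal=None if cv.cost_event_nonfatal is None else cv.cost_event_nonfatal * cost_scale,
            cost_subsequent=None if cv.cost_subsequent is None else cv.cost_subsequent * cost_scale,
            utility_decrement=None if cv.utility_decrement is None else min(cv.utility_decrement * decrement_scale, 1.0),
        )
    return ValuationTables(conditions=out)
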