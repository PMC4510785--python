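"""Micro-costing of the intensive-treatment intervention.

Builds the intervention's delivery cost from itemised resource lines
(staff time x unit rates, materials, per-patient payments), supports
multi-year discounted schedules and a single price-year inflation factor,
and reports category subtotals, totals and per-person / per-centre costs.

All monetary values are GBP at the 2009/10 UK price level unless a
``price_year_factor`` says otherwise.  Internal arithmetic is unrounded;
rounding to the nearest pound happens only in the reporting layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "CostItem",
    "CostLedger",
    "resolve_item",
    "discounted_stream",
    "ledger_totals",
    "load_intervention_ledger",
    "round_gbp",
]

CATEGORIES = ("delivery", "extra_consultations", "extra_treatments")
CENTRES = ("Cambridge", "Leicester")


def round_gbp(x: float) -> int:
    """Round to the nearest pound, halves away from zero (accounting style)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class CostItem:
    """One priced resource line of the intervention cost table.

    Exactly one of {computed amount, lump_sum_override} governs the value:
    rows priced from unit rates leave ``lump_sum_override`` as None, rows
    taken from internal accounting (or pre-discounted multi-year streams)
    carry the pound value directly.
    """

    label: str
    category: str
    centre: str = "shared"  # Cambridge | Leicester | shared
    unit_rate: float | None = None  # GBP per hour or per item
    quantity: float | None = None  # hours or item count
    multiplicity: float | None = None  # persons / sessions the line repeats over
    extra: float = 0.0  # additive lump (travel, logistics)
    lump_sum_override: float | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.centre not in CENTRES + ("shared",):
            raise ValueError(f"unknown centre {self.centre!r}")
        if self.lump_sum_override is None:
            missing = [
                n
                for n in ("unit_rate", "quantity", "multiplicity")
                if getattr(self, n) is None
            ]
            if missing:
                raise ValueError(
                    f"{self.label!r}: no lump sum and no computable amount "
                    f"(missing {', '.join(missing)})"
                )
            if self.unit_rate < 0 or self.multiplicity < 0:
                raise ValueError(f"{self.label!r}: negative rate or multiplicity")


def resolve_item(item: CostItem) -> float:
    """Pound value of one line: ``unit_rate * quantity * multiplicity + extra``
    unless a lump-sum override is present."""
    if item.lump_sum_override is not None:
        return float(item.lump_sum_override)
    return float(item.unit_rate * item.quantity * item.multiplicity + item.extra)


def discounted_stream(amounts_per_year: Sequence[float], rate: float) -> float:
    """Present value of an annual stream: year 1 undiscounted, year t
    weighted by (1+rate)^-(t-1)."""
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    return float(sum(a / (1.0 + rate) ** t for t, a in enumerate(amounts_per_year)))


@dataclass
class CostLedger:
    """A resolved set of cost items plus the reporting conventions."""

    items: list[CostItem]
    discount_rate: float = 0.035
    price_year_factor: float = 1.0
    n_per_person_denominator: int = 513
    centre_denominators: Mapping[str, int] = field(
        default_factory=lambda: {"Cambridge": 452, "Leicester": 61}
    )
    #: per-centre totals from the source accounts, when the itemised rows do
    #: not determine the split of shared/centrally run activity (None -> use
    #: the rule-based allocation of shared rows)
    published_centre_totals: Mapping[str, float] | None = None
    #: per-patient prescription payment and the duration it covers, used to
    #: annualise the continuing intensive-arm prescription cost
    prescription_payment_per_patient: float = 262.5
    intervention_duration_years: float = 3.0

    def resolved_values(self) -> pd.Series:
        vals = pd.Series(
            [resolve_item(it) * self.price_year_factor for it in self.items],
            index=[it.label for it in self.items],
            dtype=float,
        )
        return vals

    def annual_prescription_cost(self) -> float:
        """Continuing per-person prescription cost per simulated year in the
        intensive arm (the per-patient payment annualised over the official
        intervention duration)."""
        return (
            self.prescription_payment_per_patient
            * self.price_year_factor
            / self.intervention_duration_years
        )


def _allocate_shared(
    ledger: CostLedger, centre_totals: dict[str, float], shared_amount: float
) -> dict[str, float]:
    weights = ledger.centre_denominators
    wsum = sum(weights.values())
    return {
        c: centre_totals.get(c, 0.0) + shared_amount * weights[c] / wsum
        for c in CENTRES
    }


def ledger_totals(ledger: CostLedger) -> dict:
    """Subtotals by category, grand total, per-person and per-centre costs.

    Returns unrounded values plus a ``rounded`` view (nearest pound).  The
    per-centre block uses the published account totals if the ledger carries
    them, otherwise centre-tagged rows plus a proportional allocation of
    shared rows (weights = per-centre headcount).
    """
    if ledger.n_per_person_denominator == 0:
        raise ValueError("per-person denominator is zero")
    values = ledger.resolved_values()
    cats = pd.Series([it.category for it in ledger.items], index=values.index)
    subtotals = {c: float(values[cats == c].sum()) for c in CATEGORIES}
    total = float(values.sum())

    tagged: dict[str, float] = {c: 0.0 for c in CENTRES}
    shared = 0.0
    for it, v in zip(ledger.items, values):
        if it.centre == "shared":
            shared += v
        else:
            tagged[it.centre] += v
    if ledger.published_centre_totals is not None:
        centre_totals = {c: float(ledger.published_centre_totals[c]) for c in CENTRES}
    else:
        centre_totals = _allocate_shared(ledger, tagged, shared)
    per_centre = {
        c: {
            "total": centre_totals[c],
            "per_person": centre_totals[c] / ledger.centre_denominators[c],
        }
        for c in CENTRES
    }

    n = ledger.n_per_person_denominator
    out = {
        "subtotals": subtotals,
        "total": total,
        "per_person": total / n,
        "per_person_by_category": {c: subtotals[c] / n for c in CATEGORIES},
        "per_centre": per_centre,
    }
    out["rounded"] = {
        "subtotals": {c: round_gbp(v) for c, v in subtotals.items()},
        "total": round_gbp(total),
        "per_person": round_gbp(out["per_person"]),
        "per_person_by_category": {
            c: round_gbp(v) for c, v in out["per_person_by_category"].items()
        },
        "per_centre": {
            c: {
                "total": round_gbp(per_centre[c]["total"]),
                "per_person": round_gbp(per_centre[c]["per_person"]),
            }
            for c in CENTRES
        },
    }
    return out


def _read_items(df: pd.DataFrame) -> list[CostItem]:
    items = []
    for _, r in df.iterrows():
        items.append(
            CostItem(
                label=str(r["label"]),
                category=str(r["category"]),
                centre=str(r["centre"]),
                unit_rate=None if pd.isna(r["unit_rate"]) else float(r["unit_rate"]),
                quantity=None if pd.isna(r["quantity"]) else float(r["quantity"]),
                multiplicity=None
                if pd.isna(r["multiplicity"])
                else float(r["multiplicity"]),
                extra=0.0 if pd.isna(r["extra"]) else float(r["extra"]),
                lump_sum_override=None
                if pd.isna(r["lump_sum"])
                else float(r["lump_sum"]),
            )
        )
    return items


def load_intervention_ledger(
    items_csv=None, meta_yaml=None, price_year_factor: float | None = None
) -> CostLedger:
    """Load the packaged intervention cost table (or a user CSV of the same
    shape: category,label,centre,unit_rate,quantity,multiplicity,extra,lump_sum)."""
    pkg = resources.files("diabcea") / "data"
    if items_csv is None:
        items_csv = pkg / "intervention_cost_items.csv"
    if meta_yaml is None:
        meta_yaml = pkg / "intervention_cost_meta.yaml"
    with (items_csv.open() if hasattr(items_csv, "open") else open(items_csv)) as fh:
        df = pd.read_csv(fh)
    with (meta_yaml.open() if hasattr(meta_yaml, "open") else open(meta_yaml)) as fh:
        meta = yaml.safe_load(fh)
    return CostLedger(
        items=_read_items(df),
        discount_rate=float(meta["discount_rate"]),
        price_year_factor=float(
            meta["price_year_factor"] if price_year_factor is None else price_year_factor
        ),
        n_per_person_denominator=int(meta["n_per_person_denominator"]),
        centre_denominators=dict(meta["centre_denominators"]),
        published_centre_totals=meta.get("published_centre_totals"),
        prescription_payment_per_patient=float(
            meta["prescription_payment_per_patient"]
        ),
        intervention_duration_years=float(meta["intervention_duration_years"]),
    )


def write_totals_csv(totals: dict, path) -> None:
    """Flatten a ledger_totals() dict into a two-column CSV report."""
    rows = []
    for c, v in totals["subtotals"].items():
        rows.append((f"subtotal:{c}", v))
    rows.append(("total", totals["total"]))
    rows.append(("per_person", totals["per_person"]))
    for c, v in totals["per_centre"].items():
        rows.append((f"{c}:total", v["total"]))
        rows.append((f"{c}:per_person", v["per_person"]))
    pd.DataFrame(rows, columns=["quantity", "gbp"]).to_csv(path, index=False)
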