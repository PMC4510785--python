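"""Decision-uncertainty analysis.

Cost-effectiveness plane draws, cost-effectiveness acceptability curves
(CEAC), the threshold intervention-cost solver, scenario ICERs for cheaper
delivery, and one-way sensitivity (tornado) analysis.  Figure outputs are
tidy CSV (plot-ready data); optional matplotlib rendering lives in
:mod:`diabcea.plotting`.

Conventions: net monetary benefit at willingness-to-pay lambda is
NMB = lambda * dQALY - dCost, and a bootstrap draw counts as cost-effective
iff NMB > 0 (strict; ties are measure-zero for continuous draws).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .within_trial import icer

__all__ = [
    "BootstrapDraws",
    "SensitivitySpec",
    "ceac",
    "threshold_cost",
    "scenario_icers",
    "one_way_tornado",
    "default_lambda_grid",
]


def default_lambda_grid() -> np.ndarray:
    """0 to 50,000 GBP/QALY in 500 steps (covers the conventional UK
    decision range of 20,000-30,000)."""
    return np.arange(0.0, 50_500.0, 500.0)


@dataclass
class BootstrapDraws:
    """Resampled (dCost, dQALY) pairs under one scenario."""

    pairs: np.ndarray  # (B, 2)
    label: str = "base"
    intervention_cost: float | None = None

    def __post_init__(self):
        self.pairs = np.asarray(self.pairs, dtype=float)
        if self.pairs.ndim != 2 or self.pairs.shape[1] != 2 or len(self.pairs) == 0:
            raise ValueError("pairs must be a non-empty (B, 2) array")
        if not np.isfinite(self.pairs).all():
            raise ValueError("pairs must be finite")

    def reprice(self, new_cost: float, label: str | None = None) -> "BootstrapDraws":
        """Same draws under a different per-person intervention cost (the
        cost difference shifts every dCost by new_cost - current)."""
        if self.intervention_cost is None:
            raise ValueError("draws carry no intervention cost to reprice from")
        shifted = self.pairs.copy()
        shifted[:, 0] += new_cost - self.intervention_cost
        return BootstrapDraws(shifted, label or f"cost={new_cost:g}", new_cost)


def ceac(draws: BootstrapDraws, lambdas=None) -> pd.DataFrame:
    """Probability of cost-effectiveness per willingness-to-pay: the
    fraction of draws with lambda * dQALY - dCost > 0."""
    lam = default_lambda_grid() if lambdas is None else np.asarray(lambdas, float)
    dc, dq = draws.pairs[:, 0], draws.pairs[:, 1]
    prob = [(l * dq - dc > 0).mean() for l in lam]
    return pd.DataFrame({"lambda": lam, "probability": prob, "scenario": draws.label})


def threshold_cost(
    delta_cost_base: float, delta_qaly: float, c0: float, lam: float
) -> float:
    """Per-patient intervention cost at which the ICER equals ``lam``:
    c0 - (dCost_base - lam * dQALY).  Undefined for dQALY <= 0."""
    if delta_qaly <= 0:
        raise ValueError(
            "no finite threshold cost: incremental QALYs must be positive"
        )
    return c0 - (delta_cost_base - lam * delta_qaly)


def scenario_icers(
    delta_cost_base: float,
    delta_qaly: float,
    c0: float,
    intervention_costs=(981.0, 750.0, 500.0),
) -> pd.DataFrame:
    """ICER under alternative per-person delivery costs:
    (dCost_base - (c0 - c_s)) / dQALY."""
    if delta_qaly <= 0:
        raise ValueError("scenario ICERs need positive incremental QALYs")
    rows = [
        {
            "intervention_cost": c_s,
            "delta_cost": delta_cost_base - (c0 - c_s),
            "icer": (delta_cost_base - (c0 - c_s)) / delta_qaly,
        }
        for c_s in intervention_costs
    ]
    return pd.DataFrame(rows)


@dataclass
class SensitivitySpec:
    """One-way perturbations: each applied alone (all others at base)."""

    cost_scales: tuple = (0.9, 1.1)  # unit treatment costs +/- 10%
    decrement_scales: tuple = (0.9, 1.1)  # utility decrements +/- 10%
    discount_rates: tuple = (0.0, 0.05)  # vs the 3.5% base
    intervention_costs: tuple = (981.0, 750.0, 500.0)


def one_way_tornado(evaluate, spec: SensitivitySpec | None = None) -> pd.DataFrame:
    """Tornado table over one-way perturbations.

    ``evaluate(**overrides)`` must return (dCost, dQALY) for overrides drawn
    from {cost_scale, decrement_scale, discount_rate}; called with no
    overrides it returns the base case.  Emits one row per parameter family
    (parameter, low/high ICER, range) sorted by range descending; a
    perturbation with non-positive dQALY reports the ICER class instead of
    a value.
    """
    spec = spec or SensitivitySpec()
    base_ic = icer(*evaluate())

    def _icer_of(**ov):
        res = icer(*evaluate(**ov))
        return res

    rows = []
    families = [
        ("unit_treatment_costs", [{"cost_scale": s} for s in spec.cost_scales]),
        ("utility_decrements", [{"decrement_scale": s} for s in spec.decrement_scales]),
        ("discount_rate", [{"discount_rate": r} for r in spec.discount_rates]),
    ]
    for name, overrides in families:
        results = [_icer_of(**ov) for ov in overrides]
        values = [r.value for r in results]
        classes = [r.classification for r in results]
        if any(v is None for v in values):
            rows.append(
                {
                    "parameter": name,
                    "low": np.nan,
                    "high": np.nan,
                    "range": np.inf,
                    "classes": "/".join(classes),
                }
            )
        else:
            lo, hi = min(values), max(values)
            rows.append(
                {
                    "parameter": name,
                    "low": lo,
                    "high": hi,
                    "range": hi - lo,
                    "classes": "/".join(classes),
                }
            )
    out = pd.DataFrame(rows).sort_values("range", ascending=False, kind="stable")
    out.attrs["base_icer"] = base_ic.value
    out.attrs["base_class"] = base_ic.classification
    return out.reset_index(drop=True)


def ce_plane_frame(draws_list) -> pd.DataFrame:
    """Tidy CE-plane export: one row per draw per scenario."""
    frames = []
    for d in draws_list:
        frames.append(
            pd.DataFrame(
                {
                    "delta_cost": d.pairs[:, 0],
                    "delta_qaly": d.pairs[:, 1],
                    "scenario": d.label,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
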