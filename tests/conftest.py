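import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import diabcea as d

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tables():
    return d.load_valuation_tables()


@pytest.fixture(scope="session")
def ledger():
    return d.load_intervention_ledger()


@pytest.fixture(scope="session")
def equations():
    return d.load_default_equations()


@pytest.fixture(scope="session")
def small_cohort():
    """400-patient two-arm cohort with events, fixed seed."""
    cfg = d.default_config(seed=42)
    cfg.arms["routine"].n = 200
    cfg.arms["intensive"].n = 200
    coh = d.generate_cohort(cfg)
    return d.simulate_trial_events(
        coh, cfg.cvd_hazard_routine, cfg.hazard_ratio_intensive, seed=43
    )


def annuity(horizon: int, rate: float) -> float:
    """Independent closed form: sum_{t=1..H} (1+rate)^-(t-1)."""
    if rate == 0:
        return float(horizon)
    v = 1.0 / (1.0 + rate)
    return (1.0 - v**horizon) / (1.0 - v)


@pytest.fixture(scope="session")
def annuity_fn():
    return annuity
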