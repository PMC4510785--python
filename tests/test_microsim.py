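"""Outcomes microsimulation: path equations, event draws, enumeration oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import diabcea as d
from diabcea import microsim as ms


def patient_row(**kw):
    base = dict(
        id=0,
        arm="routine",
        centre="Cambridge",
        age=60.0,
        sex="male",
        ethnicity="caucasian",
        sbp_y0=143.0,
        hba1c_y0=7.3,
        total_cholesterol_y0=5.5,
        hdl_y0=1.2,
        smoker_y0=0,
    )
    base.update(kw)
    return pd.Series(base)


def null_equations(**event_overrides):
    """All events impossible unless overridden; risk factors constant."""
    paths = {f: ms.PathEquation(lag=1.0) for f in ms.RISK_FACTORS}
    events = {
        e: ms.EventEquation("logistic", {"intercept": -1e9}) for e in ms.EVENTS
    }
    events.update(event_overrides)
    return ms.RiskEquationSet(risk_factor_paths=paths, events=events)


class TestPropagate:
    def test_identity_path_is_constant(self):
        eq = null_equations()
        rf = ms.propagate_risk_factors(patient_row(), eq, 10, observed_years=(0,))
        assert (rf["hba1c"] == 7.3).all()

    def test_linear_drift_matches_arithmetic_sequence(self):
        eq = null_equations()
        eq.risk_factor_paths["hba1c"] = ms.PathEquation(intercept=0.07, lag=1.0)
        rf = ms.propagate_risk_factors(patient_row(), eq, 10, observed_years=(0,))
        np.testing.assert_allclose(rf["hba1c"], 7.3 + 0.07 * np.arange(11))

    def test_observed_override_creates_discontinuity(self):
        eq = null_equations()
        eq.risk_factor_paths["hba1c"] = ms.PathEquation(intercept=0.07, lag=1.0)
        p = patient_row(hba1c_y1=7.3, hba1c_y5=9.9)
        rf = ms.propagate_risk_factors(p, eq, 8, observed_years=(0, 1, 5))
        assert rf.loc[5, "hba1c"] == 9.9
        assert rf.loc[6, "hba1c"] == pytest.approx(9.9 + 0.07)
        assert rf.loc[4, "hba1c"] == pytest.approx(7.3 + 0.07 * 3)  # from year-1 override

    def test_missing_baseline_rejected(self):
        p = patient_row(hba1c_y0=np.nan)
        with pytest.raises(ValueError, match="hba1c"):
            ms.propagate_risk_factors(p, null_equations(), 5)

    def test_fixed_point_convergence(self, equations):
        """Default paths drift towards their fixed point (worsening HbA1c)."""
        rf = ms.propagate_risk_factors(patient_row(), equations, 30, observed_years=(0,))
        eq = equations.risk_factor_paths["hba1c"]
        fp = eq.intercept / (1 - eq.lag)
        assert rf["hba1c"].is_monotonic_increasing
        assert abs(rf.loc[30, "hba1c"] - fp) < abs(7.3 - fp)


class TestSimulatePatient:
    def test_no_events_gives_annuity(self, tables, annuity_fn):
        cfg = ms.SimulationConfig(horizons=(30,), inner_loops=10, bootstraps=1, seed=1)
        res = ms.simulate_patient(
            patient_row(), null_equations(), cfg, tables, np.random.default_rng(2)
        )
        a30 = annuity_fn(30, 0.035)
        assert res["qaly"][30] == pytest.approx(0.78 * a30, rel=1e-9)
        assert res["cost"][30] == pytest.approx(494.5 * a30, rel=1e-9)
        assert res["qaly"][30] == pytest.approx(14.85, abs=0.02)
        assert res["cumulative_incidence"].sum() == 0.0

    def test_constant_death_probability_geometric_life_years(self, tables):
        p_death = 0.2
        eq = null_equations(
            other_death=ms.EventEquation(
                "logistic", {"intercept": float(np.log(p_death / (1 - p_death)))}
            )
        )
        H = 60
        cfg = ms.SimulationConfig(horizons=(H,), inner_loops=4000, bootstraps=1, seed=3)
        res = ms.simulate_patient(patient_row(), eq, cfg, tables, np.random.default_rng(4))
        expected = sum((1 - p_death) ** (t - 1) for t in range(1, H + 1))
        se = np.sqrt(expected / cfg.inner_loops)  # crude MC error scale
        assert res["life_years"] == pytest.approx(expected, abs=4 * se)

    def test_dead_accrue_nothing(self, tables):
        eq = null_equations(
            other_death=ms.EventEquation("logistic", {"intercept": 1e9})
        )
        cfg = ms.SimulationConfig(horizons=(10,), inner_loops=50, bootstraps=1, seed=5)
        res = ms.simulate_patient(patient_row(), eq, cfg, tables, np.random.default_rng(6))
        # death in year 1: year-1 cost only, no QALYs, flat thereafter
        assert res["qaly"][10] == 0.0
        assert res["cost"][10] == pytest.approx(494.5)
        assert res["life_years"] == pytest.approx(1.0)

    def test_monotone_in_horizon(self, tables, equations):
        cfg = ms.SimulationConfig(horizons=(30,), inner_loops=40, bootstraps=1, seed=7)
        res = ms.simulate_patient(patient_row(), equations, cfg, tables, np.random.default_rng(8))
        assert np.all(np.diff(res["cost"]) >= -1e-9)
        assert np.all(np.diff(res["qaly"]) >= -1e-9)
        assert np.all(np.diff(res["cumulative_incidence"], axis=1) >= 0)

    def test_higher_intercept_more_events(self, tables):
        def run(intercept):
            eq = null_equations(
                mi=ms.EventEquation("logistic", {"intercept": intercept})
            )
            cfg = ms.SimulationConfig(horizons=(10,), inner_loops=800, bootstraps=1, seed=9)
            res = ms.simulate_patient(
                patient_row(), eq, cfg, tables, np.random.default_rng(10)
            )
            return res["cumulative_incidence"][ms.EVENTS.index("mi"), 10]

        assert run(-2.0) > run(-3.0)

    def test_inner_loop_error_scales_as_root_n(self, tables):
        """sd of the per-patient mean over replicates shrinks ~1/sqrt(loops)."""
        eq = null_equations(
            mi=ms.EventEquation("logistic", {"intercept": -2.0}),
            other_death=ms.EventEquation("logistic", {"intercept": -2.5}),
        )

        def reps(loops, n=40, seed0=100):
            out = []
            for k in range(n):
                cfg = ms.SimulationConfig(horizons=(10,), inner_loops=loops, bootstraps=1, seed=1)
                r = ms.simulate_patient(
                    patient_row(), eq, cfg, tables, np.random.default_rng(seed0 + k)
                )
                out.append(r["qaly"][10])
            return np.std(out, ddof=1)

        ratio = reps(100) / reps(400)
        assert 1.4 < ratio < 2.9  # ideal 2.0


class TestEnumerationOracle:
    def test_two_event_three_year_toy_model(self, tables):
        """Monte-Carlo agrees with exhaustive enumeration of all outcome
        paths in a 2-event (MI, other death), 3-year configuration."""
        p_mi, p_death = 0.3, 0.25
        eq = null_equations(
            mi=ms.EventEquation("logistic", {"intercept": float(np.log(p_mi / (1 - p_mi)))}),
            other_death=ms.EventEquation(
                "logistic", {"intercept": float(np.log(p_death / (1 - p_death)))}
            ),
        )
        H, rate = 3, 0.035
        base_cost, mi_event, mi_sub = 494.5, 6861.8, 1129.8
        u_base, u_mi = 0.78, 0.055

        # independent brute force: recursively enumerate every outcome path
        # (MI yes/no while event-free, death yes/no, per year); MI and death
        # may land in the same year (morbidity drawn before death)
        totals = {"cost": 0.0, "qaly": 0.0}

        def enumerate_paths(t, had_mi, prob, cost, qaly):
            mi_branches = [False] if had_mi else [False, True]
            for mi_now in mi_branches:
                p1 = 1.0 if had_mi else (p_mi if mi_now else 1 - p_mi)
                for death_now in (False, True):
                    p2 = p_death if death_now else 1 - p_death
                    w = (1 + rate) ** -(t - 1)
                    c = cost + w * (
                        base_cost
                        + (mi_event if mi_now else 0.0)
                        + (mi_sub if had_mi else 0.0)
                    )
                    q = qaly + w * (
                        0.0 if death_now else u_base - (u_mi if (mi_now or had_mi) else 0.0)
                    )
                    p = prob * p1 * p2
                    if death_now or t == H:
                        totals["cost"] += p * c
                        totals["qaly"] += p * q
                    else:
                        enumerate_paths(t + 1, had_mi or mi_now, p, c, q)

        enumerate_paths(1, False, 1.0, 0.0, 0.0)
        exp_cost, exp_qaly = totals["cost"], totals["qaly"]

        cfg = ms.SimulationConfig(horizons=(H,), inner_loops=60000, bootstraps=1, seed=11)
        res = ms.simulate_patient(patient_row(), eq, cfg, tables, np.random.default_rng(12))
        assert res["cost"][H] == pytest.approx(exp_cost, rel=0.02)
        assert res["qaly"][H] == pytest.approx(exp_qaly, rel=0.02)


class TestCohortExtrapolate:
    def test_null_equations_give_flat_arm_difference(self, tables):
        cfg = d.default_config(seed=71)
        for a in cfg.arms.values():
            a.n = 60
        coh = d.generate_cohort(cfg)
        sim = ms.SimulationConfig(horizons=(10,), inner_loops=5, bootstraps=5, seed=72)
        res = ms.cohort_extrapolate([coh, coh], null_equations(), sim, tables)
        inc = res["increments"]
        q = inc[(inc.outcome == "qaly")].iloc[0]
        assert q["estimate"] == pytest.approx(0.0, abs=1e-9)
        assert (res["incidence"]["adjusted_difference"].abs() < 1e-12).all()

    def test_intervention_cost_shifts_cost_increment(self, tables):
        cfg = d.default_config(seed=73)
        for a in cfg.arms.values():
            a.n = 60
        coh = d.generate_cohort(cfg)
        sim = ms.SimulationConfig(
            horizons=(10,), inner_loops=5, bootstraps=5, seed=74, annual_prescription_cost=0.0
        )
        res = ms.cohort_extrapolate([coh, coh], null_equations(), sim, tables, intervention_cost_per_person=981.0)
        c = res["increments"].query("outcome == 'cost'").iloc[0]
        assert c["estimate"] == pytest.approx(981.0, abs=1e-6)

    def test_lower_risk_factor_paths_lower_mi_incidence(self, tables, equations):
        """Paired cohorts identical except for lower intensive-arm risk
        factors: the MI incidence difference must be <= 0."""
        cfg = d.default_config(seed=75)
        for a in cfg.arms.values():
            a.n = 50
            a.hba1c = (7.3, 0.0)
            a.sbp = (143.0, 0.0)
            a.total_cholesterol = (5.5, 0.0)
        cfg.treatment_effect = {"sbp": -8.0, "hba1c": -0.8, "total_cholesterol": -0.8}
        cfg.remeasurement_sd_fraction = 0.0
        coh = d.generate_cohort(cfg)
        sim = ms.SimulationConfig(horizons=(30,), inner_loops=80, bootstraps=2, seed=76)
        res = ms.cohort_extrapolate([coh], equations, sim, tables)
        mi = res["incidence"].query("event == 'mi'").iloc[0]
        assert mi["intensive"] <= mi["routine"] + 2 * mi["se"] + 0.01


def test_equation_set_yaml_round_trip(tmp_path, equations):
    p = tmp_path / "eq.yaml"
    equations.to_yaml(p)
    back = ms.RiskEquationSet.from_yaml(p)
    assert back.risk_factor_paths == equations.risk_factor_paths
    assert back.events == equations.events
    assert back.synthetic


def test_unknown_covariate_rejected(tables):
    eq = null_equations(mi=ms.EventEquation("logistic", {"intercept": -2.0, "bmi_cubed": 1.0}))
    cfg = ms.SimulationConfig(horizons=(5,), inner_loops=5, bootstraps=1, seed=1)
    with pytest.raises(ValueError, match="bmi_cubed"):
        ms.simulate_patient(patient_row(), eq, cfg, tables, np.random.default_rng(1))


def test_weibull_link_matches_closed_form(tables):
    """With constant lp, the Weibull link reproduces 1-exp(-(t^k-(t-1)^k)e^lp)."""
    lp, shape = -4.0, 1.4
    eq = ms.EventEquation("weibull", {"intercept": lp}, shape=shape)
    for t in (1, 2, 5):
        p = ms._annual_prob(eq, lp, t, "mi")
        expected = 1 - np.exp(-np.exp(lp) * (t**shape - (t - 1) ** shape))
        assert p == pytest.approx(expected)
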