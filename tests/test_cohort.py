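"""Synthetic cohort generator: distributional calibration, events, missingness."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import diabcea as d
from diabcea.cohort import IMPUTABLE_VARS, _matched_truncnorm_params, _trunc_moments


def degenerate_config(seed=0):
    cfg = d.default_config(seed=seed)
    for arm in cfg.arms.values():
        for v in ("age", "bmi", "total_cholesterol", "hdl", "sbp", "hba1c"):
            m, _ = getattr(arm, v)
            setattr(arm, v, (m, 0.0))
        arm.female = 0.0
        arm.caucasian = 1.0
        arm.smoker = 0.0
    cfg.followup = (5.0, 0.0)
    cfg.remeasurement_sd_fraction = 0.0
    return cfg


class TestGenerateCohort:
    def test_deterministic_given_seed(self, tmp_path):
        cfg = d.default_config(seed=7)
        a = d.generate_cohort(cfg)
        b = d.generate_cohort(cfg)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        d.cohort.write_cohort_csv(a, pa, cfg)
        d.cohort.write_cohort_csv(b, pb, cfg)
        assert pa.read_bytes() == pb.read_bytes()
        assert (tmp_path / "a.csv.yaml").read_text() == (tmp_path / "b.csv.yaml").read_text()

    def test_sample_moments_match_config(self):
        cfg = d.default_config(seed=11)
        cfg.arms["routine"].n = 6000
        cfg.arms["intensive"].n = 6000
        coh = d.generate_cohort(cfg)
        for arm in ("routine", "intensive"):
            sub = coh[coh["arm"] == arm]
            a = cfg.arms[arm]
            n = len(sub)
            for col, (mean, sd) in (
                ("age", a.age),
                ("sbp_y0", a.sbp),
                ("hba1c_y0", a.hba1c),
                ("total_cholesterol_y0", a.total_cholesterol),
            ):
                se = sd / np.sqrt(n)
                assert abs(sub[col].mean() - mean) < 3 * se, col
            for col, p in (
                (sub["sex"] == "female", a.female),
                (sub["ethnicity"] == "caucasian", a.caucasian),
                (sub["smoker_y0"] == 1, a.smoker),
            ):
                se = np.sqrt(p * (1 - p) / n)
                assert abs(col.mean() - p) < 3 * se

    def test_bmi_recovered_from_weight_and_height(self):
        cfg = d.default_config(seed=3)
        cfg.arms["routine"].n = 4000
        coh = d.generate_cohort(cfg)
        sub = coh[coh["arm"] == "routine"]
        bmi = sub["weight"] / sub["height"] ** 2
        m, sd = cfg.arms["routine"].bmi
        assert abs(bmi.mean() - m) < 3 * sd / np.sqrt(len(sub))

    def test_all_sd_zero_gives_identical_patients(self):
        coh = d.generate_cohort(degenerate_config())
        for arm in ("routine", "intensive"):
            sub = coh[coh["arm"] == arm]
            for col in ("age", "sbp_y0", "hba1c_y0", "followup_years", "weight"):
                assert sub[col].nunique() == 1
            assert set(sub["sex"]) == {"male"}
            assert set(sub["ethnicity"]) == {"caucasian"}

    def test_treatment_effect_shifts_years_1_and_5(self):
        cfg = degenerate_config()
        coh = d.generate_cohort(cfg)
        r = coh[coh["arm"] == "routine"].iloc[0]
        i = coh[coh["arm"] == "intensive"].iloc[0]
        assert i["sbp_y1"] - i["sbp_y0"] == pytest.approx(-1.5)
        assert i["hba1c_y5"] - i["hba1c_y0"] == pytest.approx(-0.06)
        assert r["sbp_y1"] == pytest.approx(r["sbp_y0"])

    def test_hdl_never_exceeds_cholesterol(self, small_cohort):
        for y in (0, 1, 5):
            assert (
                small_cohort[f"hdl_y{y}"] <= small_cohort[f"total_cholesterol_y{y}"]
            ).all()

    def test_invalid_config_rejected(self):
        cfg = d.default_config()
        cfg.arms["routine"].female = 1.5
        with pytest.raises(ValueError, match="proportion"):
            d.generate_cohort(cfg)

    def test_followup_mean_matched_under_truncation(self):
        mu, sigma = _matched_truncnorm_params(5.0, 1.1, 1.0, 6.0)
        m, _ = _trunc_moments(mu, sigma, 1.0, 6.0)
        assert m == pytest.approx(5.0, abs=1e-6)


class TestSimulateTrialEvents:
    def test_incidence_matches_hazard(self):
        cfg = d.default_config(seed=5)
        cfg.arms["routine"].n = 12000
        cfg.arms["intensive"].n = 10
        coh = d.generate_cohort(cfg)
        coh = d.simulate_trial_events(coh, 0.0159, 0.83, seed=6)
        r = coh[coh["arm"] == "routine"]
        events = (r["event_type"] != "").sum()
        py = np.minimum(r["event_year"].fillna(np.inf), r["followup_years"]).sum()
        rate = 1000 * events / py
        se = 1000 * np.sqrt(events) / py  # Poisson error on the count
        assert abs(rate - 15.9) < 3 * se

    def test_null_hazard_ratio_equalises_arms(self):
        cfg = d.default_config(seed=9)
        cfg.arms["routine"].n = 8000
        cfg.arms["intensive"].n = 8000
        coh = d.generate_cohort(cfg)
        coh = d.simulate_trial_events(coh, 0.0159, 1.0, seed=10)
        p = coh.groupby("arm")["event_type"].apply(lambda s: (s != "").mean())
        se = np.sqrt(2 * p.mean() * (1 - p.mean()) / 8000)
        assert abs(p["routine"] - p["intensive"]) < 3 * se

    def test_event_times_exponential(self):
        """KS agreement with the exponential at the configured hazard,
        using a follow-up long enough that censoring is negligible."""
        cfg = d.default_config(seed=13)
        cfg.arms["routine"].n = 3000
        cfg.arms["intensive"].n = 10
        cfg.followup = (400.0, 0.0)
        cfg.followup_bounds = (400.0, 401.0)
        coh = d.generate_cohort(cfg)
        coh = d.simulate_trial_events(coh, 0.0159, 0.83, seed=14)
        t = coh.loc[(coh["arm"] == "routine") & (coh["event_type"] != ""), "event_year"]
        ks = stats.kstest(t, "expon", args=(0, 1 / 0.0159))
        assert ks.pvalue > 0.01

    def test_event_invariants(self, small_cohort):
        ev = small_cohort[small_cohort["event_type"] != ""]
        assert (ev["event_year"] <= ev["followup_years"]).all()
        assert (ev["event_year"] >= 0).all()
        fatal = small_cohort["event_fatal"] == 1
        assert (small_cohort.loc[fatal, "event_type"] == "cvd_death").all()
        assert (small_cohort.loc[fatal, "alive"] == 0).all()

    def test_bad_hazard_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            d.simulate_trial_events(small_cohort, 0.0, 0.83, seed=1)


class TestInjectMissingness:
    def test_rate_zero_is_identity(self, small_cohort):
        out, truth = d.inject_missingness(small_cohort, 0.0, seed=1)
        pd.testing.assert_frame_equal(out, small_cohort)
        pd.testing.assert_frame_equal(truth, small_cohort)

    def test_rate_binomial(self):
        cfg = d.default_config(seed=21)
        cfg.arms["routine"].n = 3000
        cfg.arms["intensive"].n = 3000
        coh = d.generate_cohort(cfg)
        out, truth = d.inject_missingness(coh, 0.2, variables=("hba1c",), seed=22)
        frac = out["hba1c_y0"].isna().mean()
        se = np.sqrt(0.2 * 0.8 / len(out))
        assert abs(frac - 0.2) < 3 * se
        assert not out["sbp_y0"].isna().any()  # untargeted variables untouched
        assert not truth["hba1c_y0"].isna().any()  # truth copy retains values

    def test_all_variables_marked(self, small_cohort):
        out, _ = d.inject_missingness(small_cohort, 0.5, seed=23)
        from diabcea.imputation import imputable_columns

        for c in imputable_columns(out):
            assert out[c].isna().any(), c

    def test_rate_one_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            d.inject_missingness(small_cohort, 1.0, seed=1)


def test_csv_round_trip(tmp_path, small_cohort):
    masked, _ = d.inject_missingness(small_cohort, 0.1, seed=31)
    p = tmp_path / "cohort.csv"
    d.cohort.write_cohort_csv(masked, p)
    back = d.cohort.read_cohort_csv(p)
    assert back["sbp_y0"].isna().sum() == masked["sbp_y0"].isna().sum()
    assert (back["event_type"] == masked["event_type"]).all()
    np.testing.assert_allclose(back["hba1c_y0"], masked["hba1c_y0"], rtol=1e-9)
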