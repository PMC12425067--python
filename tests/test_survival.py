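import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from paneltrans.cohort import build_counting_process
from paneltrans.survival import (
    EXPOSURE_COLUMNS,
    MODEL_COVARIATES,
    add_exposure_columns,
    fit_cox_baseline,
    fit_cox_timevarying,
    incidence_rate,
    kaplan_meier,
    person_years,
    run_sensitivity,
    schoenfeld_ph_test,
    subgroup_interaction,
)


class TestIncidenceRate:
    def test_zero_events(self):
        rate, lo, hi = incidence_rate(0, 5000.0)
        assert rate == 0.0 and lo == 0.0

    def test_hand_formula(self):
        rate, lo, hi = incidence_rate(100, 10_000.0)
        assert rate == pytest.approx(10.0)
        assert lo == pytest.approx(8.04, abs=0.01)
        assert hi == pytest.approx(11.96, abs=0.01)

    def test_cohort_scale_example(self):
        # 1,429 events over 8,628 subjects followed 16.8 years on average
        rate, lo, hi = incidence_rate(1429, 8628 * 16.8)
        assert rate == pytest.approx(9.85, abs=0.02)
        assert lo < 9.85 < hi

    def test_validation(self):
        with pytest.raises(ValueError):
            incidence_rate(10, 0.0)


class TestKaplanMeier:
    def test_no_events_survival_one(self):
        iv = pd.DataFrame({"id": range(6), "start": 0.0, "stop": [3.0] * 6,
                           "event": False, "g": [0, 0, 0, 1, 1, 1]})
        curves, p = kaplan_meier(iv, "g")
        for km in curves.values():
            assert float(km.survival_function_.iloc[-1]) == 1.0

    def test_single_event_one_step(self):
        iv = pd.DataFrame({"id": range(5), "start": 0.0,
                           "stop": [2.0, 4.0, 4.0, 4.0, 4.0],
                           "event": [True, False, False, False, False],
                           "g": 1})
        curves, _ = kaplan_meier(iv, "g")
        km = curves[1]
        assert float(km.survival_function_at_times(2.0).iloc[0]) == pytest.approx(1 - 1 / 5)

    def test_logrank_power_under_hr2(self):
        detected = 0
        for rep in range(10):
            rng = np.random.default_rng(100 + rep)
            n = 500
            g = np.repeat([0, 1], n)
            T = rng.exponential(1 / (0.05 * 2.0**g))
            C = rng.uniform(0, 25, 2 * n)
            iv = pd.DataFrame({"id": range(2 * n), "start": 0.0,
                               "stop": np.minimum(T, C), "event": T <= C, "g": g})
            _, p = kaplan_meier(iv, "g")
            detected += p < 0.001
        assert detected >= 9


def brute_force_cox_beta(times, events, x, entries=None):
    """Independent 1-D partial-likelihood maximizer (distinct event times)."""
    times = np.asarray(times, float)
    x = np.asarray(x, float)
    entries = np.zeros_like(times) if entries is None else np.asarray(entries, float)

    def nll(b):
        ll = 0.0
        for t, e, xi in zip(times, events, x):
            if not e:
                continue
            risk = (entries < t) & (times >= t)
            ll += b * xi - np.log(np.sum(np.exp(b * x[risk])))
        return -ll

    return minimize_scalar(nll, bounds=(-8, 8), method="bounded",
                           options={"xatol": 1e-12}).x


class TestCoxTimeVarying:
    def test_matches_enumeration_oracle_three_subjects(self):
        iv = pd.DataFrame({"id": [1, 2, 3], "start": 0.0, "stop": [1.0, 2.0, 3.0],
                           "event": [True, True, True], "x": [1.0, 0.0, 1.0]})
        beta = brute_force_cox_beta(iv["stop"], iv["event"], iv["x"])
        fit = fit_cox_timevarying(iv, ["x"])
        assert fit.summary["coef"].iloc[0] == pytest.approx(beta, abs=1e-6)

    def test_matches_oracle_six_subjects_with_censoring(self):
        iv = pd.DataFrame({
            "id": range(6), "start": 0.0,
            "stop": [1.0, 1.5, 2.0, 2.5, 3.0, 4.0],
            "event": [True, False, True, True, False, True],
            "x": [0.0, 1.0, 1.0, 0.0, 1.0, 1.0],
        })
        beta = brute_force_cox_beta(iv["stop"], iv["event"], iv["x"])
        fit = fit_cox_timevarying(iv, ["x"])
        assert fit.summary["coef"].iloc[0] == pytest.approx(beta, abs=1e-6)

    def test_hr_is_exp_beta_and_ci_order(self, intervals):
        fit = fit_cox_timevarying(intervals, EXPOSURE_COLUMNS["any"] + MODEL_COVARIATES[1])
        s = fit.summary
        assert np.allclose(s["hr"], np.exp(s["coef"]))
        assert ((s["lo"] < s["hr"]) & (s["hr"] < s["hi"])).all()

    def test_null_covariate_within_two_se(self):
        ok = 0
        reps = 25
        for rep in range(reps):
            rng = np.random.default_rng(500 + rep)
            n = 400
            x = rng.binomial(1, 0.5, n).astype(float)
            T = rng.exponential(10.0, n)
            C = rng.uniform(0, 25, n)
            iv = pd.DataFrame({"id": range(n), "start": 0.0,
                               "stop": np.minimum(T, C), "event": T <= C, "x": x})
            s = fit_cox_timevarying(iv, ["x"]).summary.iloc[0]
            ok += abs(s["coef"]) < 2 * s["se"]
        assert ok >= 0.84 * reps

    def test_constant_covariate_rejected(self):
        iv = pd.DataFrame({"id": [1, 2], "start": 0.0, "stop": [1.0, 2.0],
                           "event": [True, True], "x": [1.0, 1.0]})
        with pytest.raises(ValueError, match="constant"):
            fit_cox_timevarying(iv, ["x"])

    def test_no_events_rejected(self):
        iv = pd.DataFrame({"id": [1, 2], "start": 0.0, "stop": [1.0, 2.0],
                           "event": [False, False], "x": [1.0, 0.0]})
        with pytest.raises(ValueError, match="no events"):
            fit_cox_timevarying(iv, ["x"])


class TestSchoenfeld:
    @staticmethod
    def _null_intervals(rng, n=150):
        x = rng.binomial(1, 0.4, n).astype(float)
        T = rng.exponential(10.0, n)
        C = rng.uniform(0, 15, n)
        return pd.DataFrame({"id": range(n), "start": 0.0, "stop": np.minimum(T, C),
                             "event": T <= C, "x": x})

    def test_single_covariate_global_equals_marginal(self):
        iv = self._null_intervals(np.random.default_rng(1))
        fit = fit_cox_timevarying(iv, ["x"])
        ph = schoenfeld_ph_test(fit, iv, ["x"])
        assert ph.set_index("term").loc["x", "p"] == pytest.approx(
            ph.set_index("term").loc["GLOBAL", "p"], abs=1e-10)

    def test_detects_sign_reversing_effect(self):
        detected = 0
        for rep in range(5):
            rng = np.random.default_rng(900 + rep)
            n = 1500
            x = rng.binomial(1, 0.5, n).astype(float)
            # hazard effect +0.8 before t=5, -0.8 after: classic PH violation
            h0 = 0.08
            T = np.empty(n)
            for i in range(n):
                h1 = h0 * np.exp(0.8 * x[i])
                t = rng.exponential(1 / h1)
                if t <= 5:
                    T[i] = t
                else:
                    h2 = h0 * np.exp(-0.8 * x[i])
                    T[i] = 5 + rng.exponential(1 / h2)
            C = rng.uniform(5, 30, n)
            iv = pd.DataFrame({"id": range(n), "start": 0.0,
                               "stop": np.minimum(T, C), "event": T <= C, "x": x})
            fit = fit_cox_timevarying(iv, ["x"])
            ph = schoenfeld_ph_test(fit, iv, ["x"])
            detected += ph.set_index("term").loc["x", "p"] < 0.05
        assert detected >= 4

    def test_too_few_events(self):
        iv = pd.DataFrame({"id": [1, 2], "start": 0.0, "stop": [1.0, 2.0],
                           "event": [True, False], "x": [1.0, 0.0]})
        fit_df = pd.DataFrame({"term": ["x"], "coef": [0.0], "hr": [1.0],
                               "se": [1.0], "lo": [0.1], "hi": [10.0], "p": [1.0]})
        from paneltrans.survival import CoxFit

        fake = CoxFit(summary=fit_df, log_likelihood=0.0, n_events=1, model="m")
        with pytest.raises(ValueError, match="fewer events"):
            schoenfeld_ph_test(fake, iv, ["x"])


def _two_group_intervals(rng, n, beta_by_stratum):
    """Single-interval survival data with a stratum-specific exposure effect."""
    g = rng.binomial(1, 0.5, n).astype(float)  # modifier
    x = rng.binomial(1, 0.4, n).astype(float)  # exposure
    beta = np.where(g == 1, beta_by_stratum[1], beta_by_stratum[0])
    T = rng.exponential(1 / (0.06 * np.exp(beta * x)))
    C = rng.uniform(0, 25, n)
    return pd.DataFrame({"id": range(n), "start": 0.0, "stop": np.minimum(T, C),
                         "event": T <= C, "x": x, "g": g})


class TestSubgroups:
    def test_null_interaction_rarely_rejects(self):
        ok = 0
        for rep in range(10):
            rng = np.random.default_rng(40 + rep)
            iv = _two_group_intervals(rng, 800, {0: 0.4, 1: 0.4})
            res = subgroup_interaction(iv, "g", exposure="x", adjust=[])
            ok += res["interaction_p"] > 0.05
        assert ok >= 8

    def test_detects_heterogeneous_effect(self):
        detected = 0
        for rep in range(5):
            rng = np.random.default_rng(70 + rep)
            iv = _two_group_intervals(rng, 2500, {0: 0.0, 1: 0.9})
            res = subgroup_interaction(iv, "g", exposure="x", adjust=[])
            detected += res["interaction_p"] < 0.05
            assert res["strata"][1.0]["hr"] > res["strata"][0.0]["hr"]
        assert detected >= 4

    def test_degenerate_exposure_is_clean_error(self):
        rng = np.random.default_rng(0)
        iv = _two_group_intervals(rng, 200, {0: 0.0, 1: 0.0})
        iv["x"] = 0.0
        with pytest.raises(ValueError):
            subgroup_interaction(iv, "g", exposure="x", adjust=[])

    def test_stratum_without_events_reported_non_estimable(self):
        rng = np.random.default_rng(3)
        iv = _two_group_intervals(rng, 300, {0: 0.0, 1: 0.0})
        iv.loc[iv["g"] == 1, "event"] = False
        res = subgroup_interaction(iv, "g", exposure="x", adjust=[])
        assert "non_estimable" in res["strata"][1.0]


class TestSensitivity:
    def test_variant1_identity_when_no_early_events(self, scored, sim_data):
        _, aces, _ = sim_data
        iv = add_exposure_columns(build_counting_process(scored, aces, horizon=22.0))
        early = set(iv.loc[iv["event"] & (iv["stop"] <= 2.0), "id"])
        trimmed = scored[~scored["id"].isin(early)]
        main = fit_cox_timevarying(
            add_exposure_columns(build_counting_process(trimmed, aces, horizon=22.0)),
            EXPOSURE_COLUMNS["any"] + MODEL_COVARIATES[3])
        sens = run_sensitivity(1, trimmed, aces, horizon=22.0)
        assert np.allclose(main.summary["coef"], sens.summary["coef"], atol=1e-10)

    def test_variant3_recovers_additive_disease_count(self):
        covered = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 1500
            count = rng.integers(0, 4, n).astype(float)
            T = rng.exponential(1 / (0.04 * np.exp(0.3 * count)))
            C = rng.uniform(0, 25, n)
            iv = pd.DataFrame({"id": range(n), "start": 0.0, "stop": np.minimum(T, C),
                               "event": T <= C, "disease_count": count})
            s = fit_cox_timevarying(iv, ["disease_count"]).summary.iloc[0]
            covered += s["coef"] - 1.96 * s["se"] < 0.3 < s["coef"] + 1.96 * s["se"]
        assert covered >= 4

    def test_variant4_equals_timevarying_when_nothing_varies(self):
        rng = np.random.default_rng(4)
        n = 300
        x = rng.binomial(1, 0.5, n).astype(float)
        T = rng.exponential(1 / (0.08 * np.exp(0.4 * x)))
        C = rng.uniform(0, 20, n)
        dur = np.minimum(T, C)
        ev = T <= C
        # split each subject's follow-up into two intervals with identical covariates
        rows = []
        for i in range(n):
            mid = dur[i] / 2
            rows.append({"id": i, "start": 0.0, "stop": mid, "event": False, "x": x[i]})
            rows.append({"id": i, "start": mid, "stop": dur[i], "event": bool(ev[i]),
                         "x": x[i]})
        iv = pd.DataFrame(rows)
        tv = fit_cox_timevarying(iv, ["x"])
        subj = pd.DataFrame({"duration": dur, "event": ev, "x": x})
        base = fit_cox_baseline(subj, ["x"])
        # identical partial likelihoods; agreement limited only by the two
        # solvers' stopping rules
        assert tv.summary["coef"].iloc[0] == pytest.approx(
            base.summary["coef"].iloc[0], abs=1e-6)

    def test_all_variants_run_on_synthetic_cohort(self, scored, sim_data):
        _, aces, _ = sim_data
        for variant in (1, 2, 3, 4, 5):
            fit = run_sensitivity(variant, scored, aces, horizon=22.0)
            assert fit.hr("any_ace") > 0
        with pytest.raises(ValueError, match="unknown sensitivity variant"):
            run_sensitivity(9, scored, aces)

    def test_person_years_accounting(self, intervals):
        assert person_years(intervals) == pytest.approx(
            (intervals["stop"] - intervals["start"]).sum())
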