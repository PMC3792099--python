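"""Cox partial likelihood, time-varying effects, PH diagnostics."""

import numpy as np
import pandas as pd
import pytest

import lifelines

from msmtx.cox import (CoxPH, fit_cox, fit_treatment_comparison,
                       fit_time_varying_effect, split_at_cutpoints,
                       ConvergenceError)
from msmtx.cox import test_proportional_hazards as ph_test
from msmtx.simulate import make_scenario_presets, simulate_cohort, \
    apply_registry_sampling, ScenarioParams
from msmtx.events import assemble_multistate_dataset
from msmtx.stepfun import DAYS_PER_YEAR
from conftest import grid_search_argmax


def two_sample_exponential(n, loghr, seed, censor=2.0):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(1.0 / np.exp(loghr * x))
    c = rng.exponential(censor, n)
    return pd.DataFrame({"entry": 0.0, "exit": np.minimum(t, c),
                         "status": (t <= c).astype(int), "x": x})


class TestFitCox:
    def test_grid_search_oracle(self, cox_fixture):
        fit = fit_cox(cox_fixture, ["x"])
        oracle = grid_search_argmax(fit.partial_loglik)
        assert abs(fit.coef_["x"] - oracle) <= 1e-4

    def test_score_is_zero_at_optimum(self, cox_fixture):
        fit = fit_cox(cox_fixture, ["x"])
        eps = 1e-6
        d = (fit.partial_loglik([fit.coef_["x"] + eps])
             - fit.partial_loglik([fit.coef_["x"] - eps])) / (2 * eps)
        assert abs(d) < 1e-4
        assert fit.loglik_ >= fit.loglik_null_

    def test_constant_covariate_unidentifiable(self):
        rows = two_sample_exponential(20, 0.0, 1).assign(x=1.0)
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_cox(rows, ["x"])

    def test_monotone_likelihood_detected(self):
        # complete separation: every x=1 event precedes all x=0 events
        rows = pd.DataFrame({
            "entry": 0.0,
            "exit": np.r_[np.linspace(0.1, 0.5, 10), np.linspace(2, 3, 10)],
            "status": 1,
            "x": np.r_[np.ones(10), np.zeros(10)],
        })
        with pytest.raises(ConvergenceError):
            fit_cox(rows, ["x"])

    def test_parameter_recovery_log2(self):
        rows = two_sample_exponential(1000, np.log(2), seed=77)
        fit = fit_cox(rows, ["x"])
        se = fit.summary_.loc["x", "se"]
        assert abs(fit.coef_["x"] - np.log(2)) < 3 * se

    def test_matches_lifelines_delayed_entry_no_ties(self):
        rng = np.random.default_rng(15)
        n = 250
        x = rng.normal(size=n)
        entry = rng.uniform(0, 0.4, n)
        t = entry + rng.exponential(1.0 / np.exp(0.3 * x))
        c = entry + rng.exponential(1.5, n)
        rows = pd.DataFrame({"entry": entry, "exit": np.minimum(t, c),
                             "status": (t <= c).astype(int), "x": x,
                             "id": np.arange(n)})
        fit = fit_cox(rows, ["x"])
        ctv = lifelines.CoxTimeVaryingFitter()
        ctv.fit(rows.rename(columns={"entry": "start", "exit": "stop",
                                     "status": "event"}),
                id_col="id", start_col="start", stop_col="stop",
                event_col="event")
        assert abs(fit.coef_["x"] - ctv.params_["x"]) < 1e-6

    def test_breslow_baseline_recovers_constant_hazard(self):
        rows = two_sample_exponential(4000, 0.0, seed=5, censor=3.0)
        fit = fit_cox(rows, ["x"])
        # with beta ~ 0 the baseline is the marginal cumulative hazard
        bh = fit.baseline_cumhaz_
        t0 = 1.0
        # x=0/1 mixture: average relative hazard exp(beta*x) ~ (1+e^b)/2
        scale = np.mean(np.exp(fit.coef_["x"]
                               * rows["x"].to_numpy()))
        assert bh(t0) * scale == pytest.approx(t0, rel=0.1)

    def test_stratified_fit_runs(self, cox_fixture):
        rows = pd.concat([cox_fixture.assign(g=0),
                          cox_fixture.assign(g=1, exit=cox_fixture["exit"] * 2)],
                         ignore_index=True)
        fit = fit_cox(rows, ["x"], strata="g")
        assert len(fit.baseline_cumhaz_) == 2
        assert np.isfinite(fit.coef_["x"])

    def test_no_events_errors(self):
        rows = two_sample_exponential(20, 0.0, 1).assign(status=0)
        with pytest.raises(ValueError, match="no events"):
            fit_cox(rows, ["x"])


class TestTreatmentComparison:
    def test_null_preset_gives_hr_near_one(self):
        p = make_scenario_presets(n=3000, seed=19)["s1-markov"]
        coh = simulate_cohort(p)
        tx, non_tx = apply_registry_sampling(coh)
        fit = fit_treatment_comparison(non_tx, tx)
        s = fit.summary_.loc["tx_state"]
        assert abs(s["coef"]) < 3 * s["se"]

    def test_tv_effect_average_hr_between_extremes(self):
        p = make_scenario_presets(n=3000, seed=20)["tv-effect"]
        coh = simulate_cohort(p)
        tx, non_tx = apply_registry_sampling(coh)
        fit = fit_treatment_comparison(non_tx, tx)
        hr = fit.summary_.loc["tx_state", "hr"]
        assert 1.0 < hr < 5.8

    def test_adjustment_covariates_accepted(self):
        p = ScenarioParams.from_dict(
            make_scenario_presets(n=2000, seed=4)["s1-markov"].to_dict())
        p.covariate_effects = {"13": {"age_gt60": 0.5},
                               "23": {"age_gt60": 0.5}}
        coh = simulate_cohort(p)
        tx, non_tx = apply_registry_sampling(coh)
        fit = fit_treatment_comparison(non_tx, tx,
                                       adjust=("age_gt60", "raebt"))
        assert {"tx_state", "age_gt60", "raebt"} <= set(fit.coef_.index)
        age = fit.summary_.loc["age_gt60"]
        assert abs(age["coef"] - 0.5) < 3 * age["se"]


class TestTimeVarying:
    def test_no_cutpoints_reduces_to_overall_fit(self):
        p = make_scenario_presets(n=800, seed=6)["s1-markov"]
        coh = simulate_cohort(p)
        tx, non_tx = apply_registry_sampling(coh)
        data = assemble_multistate_dataset(non_tx, tx)
        tve = fit_time_varying_effect(data.comparison_rows, cutpoints=())
        fit = fit_treatment_comparison(non_tx, tx)
        assert abs(tve.coef_table["coef"].iloc[0]
                   - fit.coef_["tx_state"]) < 1e-10

    def test_episode_splitting_preserves_exposure_and_events(self):
        rows = pd.DataFrame({"entry": [0.0, 50.0], "exit": [400.0, 120.0],
                             "status": [1, 0], "tx_state": [1, 0]})
        split = split_at_cutpoints(rows, (91.0, 365.0))
        assert split["status"].sum() == 1
        exposure = (split["exit"] - split["entry"]).sum()
        assert exposure == pytest.approx((400 - 0) + (120 - 50))
        # event sits in the piece containing the exit time
        ev = split[split["status"] == 1].iloc[0]
        assert ev["entry"] == 365.0 and ev["exit"] == 400.0

    def test_piecewise_recovery_on_tv_preset(self):
        p = make_scenario_presets(n=3000, seed=8)["tv-effect"]
        coh = simulate_cohort(p)
        tx, non_tx = apply_registry_sampling(coh)
        data = assemble_multistate_dataset(non_tx, tx)
        tve = fit_time_varying_effect(data.comparison_rows)
        first, last = tve.coef_table.iloc[0], tve.coef_table.iloc[-1]
        assert abs(first["coef"] - np.log(5.8)) < 3 * first["se"]
        assert abs(last["coef"]) < 3 * last["se"]

    def test_units_invariance_days_vs_years(self):
        p = make_scenario_presets(n=1000, seed=9)["tv-effect"]
        coh = simulate_cohort(p)
        tx, non_tx = apply_registry_sampling(coh)
        rows = assemble_multistate_dataset(non_tx, tx).comparison_rows
        tve_d = fit_time_varying_effect(rows, cutpoints=(91.0, 365.0))
        rows_y = rows.assign(entry=rows["entry"] / DAYS_PER_YEAR,
                             exit=rows["exit"] / DAYS_PER_YEAR)
        tve_y = fit_time_varying_effect(
            rows_y, cutpoints=(91.0 / DAYS_PER_YEAR, 365.0 / DAYS_PER_YEAR))
        np.testing.assert_allclose(tve_d.coef_table["coef"],
                                   tve_y.coef_table["coef"], atol=1e-8)

    def test_empty_interval_errors(self):
        rows = pd.DataFrame({"entry": [0.0] * 6, "exit": [10.0, 20, 30, 40, 50, 60],
                             "status": [1] * 6, "tx_state": [0, 1] * 3})
        with pytest.raises(ValueError, match="no event"):
            fit_time_varying_effect(rows, cutpoints=(1000.0,))

    def test_smooth_curve_ci_contains_point_estimate(self):
        p = make_scenario_presets(n=1500, seed=10)["s1-markov"]
        coh = simulate_cohort(p)
        tx, non_tx = apply_registry_sampling(coh)
        data = assemble_multistate_dataset(non_tx, tx)
        tve = fit_time_varying_effect(data.comparison_rows)
        sm = tve.smooth
        assert ((sm["lo"] <= sm["loghr"]) & (sm["loghr"] <= sm["hi"])).all()


class TestPHTest:
    def test_p_value_in_unit_interval(self, cox_fixture):
        fit = fit_cox(cox_fixture, ["x"])
        res = ph_test(fit)
        assert 0.0 <= res.p_value <= 1.0
        assert res.df == 1
        assert set(res.table.index) == {"x"}

    def test_rejects_on_strong_time_varying_effect(self):
        p = make_scenario_presets(n=3000, seed=14)["tv-effect"]
        coh = simulate_cohort(p)
        tx, non_tx = apply_registry_sampling(coh)
        fit = fit_treatment_comparison(non_tx, tx)
        assert ph_test(fit).p_value < 0.001

    def test_too_few_events_errors(self):
        rows = pd.DataFrame({"entry": [0.0, 0.0, 0.0],
                             "exit": [1.0, 2.0, 3.0],
                             "status": [1, 0, 0], "x": [0.5, 0.0, 1.0]})
        fit = fit_cox(rows, ["x"])
        with pytest.raises(ValueError, match=">= 2 events"):
            ph_test(fit)

    def test_transform_variants_agree_on_direction(self):
        p = make_scenario_presets(n=2000, seed=16)["tv-effect"]
        coh = simulate_cohort(p)
        tx, non_tx = apply_registry_sampling(coh)
        fit = fit_treatment_comparison(non_tx, tx)
        for tr in ("km", "rank", "log"):
            assert ph_test(fit, transform=tr).p_value < 0.01
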