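"""Kaplan-Meier / Nelson-Aalen / right truncation / competing risks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import lifelines

from msmtx.nonparametric import (
    KaplanMeierEstimator, NelsonAalenEstimator, RightTruncatedCDFEstimator,
    CompetingRisksCIFEstimator, kaplan_meier, nelson_aalen,
    right_truncated_cdf,
)
from msmtx.simulate import PiecewiseHazard, ScenarioParams, simulate_cohort, \
    apply_registry_sampling, make_scenario_presets
from msmtx.events import assemble_multistate_dataset
from msmtx.stepfun import DAYS_PER_YEAR


def rows_df(entry, exit_, status, **extra):
    return pd.DataFrame({"entry": entry, "exit": exit_, "status": status,
                         **extra})


class TestNelsonAalen:
    def test_hand_oracle_no_truncation(self):
        na = nelson_aalen(rows_df([0, 0, 0], [1.0, 2.0, 3.0], [1, 1, 1]))
        assert na(3.0) == pytest.approx(1 / 3 + 1 / 2 + 1)
        assert na(1.5) == pytest.approx(1 / 3)

    def test_hand_oracle_delayed_entry(self):
        na = nelson_aalen(rows_df([0, 1], [2.0, 3.0], [1, 1]))
        assert na(2.0) == pytest.approx(0.5)
        assert na(3.0) == pytest.approx(1.5)

    def test_all_censored_is_flat_zero(self):
        na = nelson_aalen(rows_df([0, 0], [1.0, 2.0], [0, 0]))
        assert na(5.0) == 0.0

    def test_degenerate_interval_errors(self):
        with pytest.raises(ValueError, match="entry < exit"):
            nelson_aalen(rows_df([0, 2.0], [1.0, 2.0], [0, 1]))

    def test_matches_lifelines_with_entry(self):
        rng = np.random.default_rng(1)
        n = 150
        entry = rng.uniform(0, 1, n)
        t = entry + rng.exponential(1.0, n)
        c = entry + rng.exponential(1.5, n)
        rows = rows_df(entry, np.minimum(t, c), (t <= c).astype(int))
        ours = nelson_aalen(rows)
        naf = lifelines.NelsonAalenFitter(nelson_aalen_smoothing=False)
        naf.fit(rows["exit"], rows["status"], entry=rows["entry"])
        theirs = naf.cumulative_hazard_.iloc[:, 0]
        grid = ours.knots
        np.testing.assert_allclose(ours(grid),
                                   theirs.asof(pd.Index(grid)).to_numpy(),
                                   atol=1e-10)

    def test_linear_in_time_under_constant_hazard(self):
        lam = 0.8
        rng = np.random.default_rng(4)
        n = 2000
        t = rng.exponential(1 / lam, n)
        c = rng.uniform(0.5, 3.0, n)
        na = NelsonAalenEstimator().fit(
            rows_df(np.zeros(n), np.minimum(t, c), (t <= c).astype(int)))
        knots, vals = na.cumhaz_.knots, na.cumhaz_.values
        keep = knots < 2.0
        slope = np.polyfit(knots[keep], vals[keep], 1)[0]
        se = lam / np.sqrt(na.n_events_)
        assert abs(slope - lam) < 3 * se


class TestKaplanMeier:
    def test_product_limit_by_hand(self):
        km = kaplan_meier(rows_df([0, 0], [1.0, 2.0], [1, 1]))
        assert km(1.0) == pytest.approx(0.5)
        assert km(2.0) == pytest.approx(0.0)

    def test_all_censored_median_not_reached(self):
        est = KaplanMeierEstimator().fit(rows_df([0, 0], [1.0, 2.0], [0, 0]))
        assert est.survival_(10.0) == 1.0
        assert np.isnan(est.median_)

    def test_km_vs_exp_nelson_aalen_bound(self):
        rng = np.random.default_rng(2)
        n = 400
        t = rng.exponential(1.0, n)
        c = rng.exponential(1.5, n)
        rows = rows_df(np.zeros(n), np.minimum(t, c), (t <= c).astype(int))
        km = KaplanMeierEstimator().fit(rows)
        na = NelsonAalenEstimator().fit(rows)
        inc = na.n_events_at_ / na.n_at_risk_
        gap = np.abs(km.survival_.values - np.exp(-na.cumhaz_.values)).max()
        assert gap <= np.sum(inc ** 2)

    def test_matches_lifelines_with_entry(self):
        rng = np.random.default_rng(3)
        n = 120
        entry = rng.uniform(0, 0.5, n)
        t = entry + rng.exponential(1.0, n)
        c = entry + rng.exponential(2.0, n)
        rows = rows_df(entry, np.minimum(t, c), (t <= c).astype(int))
        ours = kaplan_meier(rows)
        kmf = lifelines.KaplanMeierFitter()
        kmf.fit(rows["exit"], rows["status"], entry=rows["entry"])
        theirs = kmf.survival_function_.iloc[:, 0]
        np.testing.assert_allclose(
            ours(ours.knots), theirs.asof(pd.Index(ours.knots)).to_numpy(),
            atol=1e-10)

    def test_ignoring_delayed_entry_understates_early_hazard(self):
        """Forcing entry = 0 on left-truncated transplant data lowers the
        early cumulative hazard: the immortal-time direction."""
        p = make_scenario_presets(n=2000, seed=31)["s1-markov"]
        coh = simulate_cohort(p)
        tx, _ = apply_registry_sampling(coh)
        honest = nelson_aalen(rows_df(tx["t_tx_days"], tx["t_end_days"],
                                      tx["dead"]))
        naive = nelson_aalen(rows_df(np.zeros(len(tx)), tx["t_end_days"],
                                     tx["dead"]))
        for t in (0.5, 1.0, 2.0):
            td = t * DAYS_PER_YEAR
            assert naive(td) < honest(td)


class TestRightTruncatedCDF:
    def test_vacuous_truncation_equals_ecdf(self):
        wt = pd.DataFrame({"time": [1.0, 2.0, 3.0, 4.0], "rtrunc": 10.0})
        cdf = right_truncated_cdf(wt)
        np.testing.assert_allclose(cdf(np.array([1.0, 2.0, 3.0, 4.0])),
                                   [0.25, 0.5, 0.75, 1.0])

    def test_four_record_hand_enumeration(self):
        # (T, R) pairs with staggered truncation; reversed-time product
        # limit computed by hand
        wt = pd.DataFrame({"time": [1.0, 2.0, 2.5, 3.0],
                           "rtrunc": [2.0, 2.5, 4.0, 4.0]})
        cdf = right_truncated_cdf(wt)
        assert cdf(0.5) == pytest.approx(0.0)
        assert cdf(1.0) == pytest.approx(0.125)
        assert cdf(2.0) == pytest.approx(0.25)
        assert cdf(2.5) == pytest.approx(0.5)
        assert cdf(3.0) == pytest.approx(1.0)

    def test_truncation_violated_errors(self):
        with pytest.raises(ValueError, match="truncation"):
            right_truncated_cdf(pd.DataFrame({"time": [2.0], "rtrunc": [1.0]}))

    def test_degenerate_all_equal_allowed(self):
        cdf = right_truncated_cdf(pd.DataFrame({"time": [2.0, 2.0],
                                                "rtrunc": [3.0, 2.5]}))
        assert cdf(2.0) == 1.0 and cdf(1.9) == 0.0

    def test_sup_distance_to_true_conditional_cdf(self):
        # waiting ~ Exp(1/y), truncation ~ U(0.5, 3) y
        rng = np.random.default_rng(12)
        T = rng.exponential(1.0, 20000)
        R = rng.uniform(0.5, 3.0, 20000)
        keep = T <= R
        wt = pd.DataFrame({"time": T[keep][:1000], "rtrunc": R[keep][:1000]})
        est = RightTruncatedCDFEstimator().fit(wt)
        grid = np.linspace(0, est.tau_, 500)
        true = (1 - np.exp(-grid)) / (1 - np.exp(-est.tau_))
        sup = np.abs(np.asarray(est.cdf_(grid)) - true).max()
        assert sup <= 0.05

    def test_naive_ecdf_overrepresents_short_waits(self):
        rng = np.random.default_rng(13)
        T = rng.exponential(1.0, 20000)
        R = rng.uniform(0.5, 3.0, 20000)
        keep = T <= R
        wt = pd.DataFrame({"time": T[keep][:1000], "rtrunc": R[keep][:1000]})
        est = RightTruncatedCDFEstimator().fit(wt)
        naive = np.mean(wt["time"].to_numpy()[:, None]
                        <= np.array([0.5, 1.0]), axis=0)
        corrected = np.asarray(est.cdf_(np.array([0.5, 1.0])))
        assert (naive > corrected).all()


class TestCompetingRisks:
    @staticmethod
    def toy_rows():
        return pd.DataFrame({
            "id": list("abcd"),
            "entry": [0.0, 0.0, 0.0, 0.0],
            "exit": [1.0, 2.0, 3.0, 4.0],
            "status": [1, 1, 0, 1],
            "cause": ["relapse", "NRM", None, "relapse"],
        })

    def test_single_cause_reduces_to_one_minus_km(self):
        rows = self.toy_rows().assign(cause="NRM")
        est = CompetingRisksCIFEstimator().fit(rows)
        km = kaplan_meier(rows)
        np.testing.assert_allclose(est.cif_["NRM"].values,
                                   1 - km(est.cif_["NRM"].knots), atol=1e-12)

    def test_toy_brute_force(self):
        # CIF_k(t) = sum S(u-) d_k(u)/Y(u): at t=1 relapse jumps by 1/4;
        # at t=2 NRM by (3/4)(1/3); at t=4 relapse by (3/4)(2/3)(1/1)... with
        # censoring at 3 the last risk set is 1
        est = CompetingRisksCIFEstimator().fit(self.toy_rows())
        rel, nrm = est.cif_["relapse"], est.cif_["NRM"]
        assert rel(1.0) == pytest.approx(0.25)
        assert nrm(2.0) == pytest.approx(0.25)
        assert rel(4.0) == pytest.approx(0.25 + 0.75 * (2 / 3) * 0.5 / 0.5)

    def test_conservation_identity(self):
        est = CompetingRisksCIFEstimator().fit(self.toy_rows())
        total = est.event_free_.values.copy()
        for c in est.cif_.values():
            total = total + c(est.event_free_.knots)
        np.testing.assert_allclose(total, 1.0, atol=1e-12)

    def test_two_causes_for_one_subject_errors(self):
        rows = self.toy_rows()
        rows.loc[len(rows)] = ["a", 0.0, 5.0, 1, "NRM"]
        with pytest.raises(ValueError, match="more than one cause"):
            CompetingRisksCIFEstimator().fit(rows)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.lists(
    st.tuples(st.floats(0.0, 5.0), st.floats(0.01, 10.0),
              st.booleans()),
    min_size=1, max_size=25))
def test_km_na_shape_invariants(spec):
    rows = pd.DataFrame({
        "entry": [e for e, d, _ in spec],
        "exit": [e + d for e, d, _ in spec],
        "status": [int(s) for _, _, s in spec],
    })
    try:
        km = kaplan_meier(rows)
        na = nelson_aalen(rows)
    except ValueError:
        return  # left-truncation gap: legitimately rejected
    assert np.all(np.diff(km.values) <= 1e-15)
    assert np.all((km.values >= 0) & (km.values <= 1))
    assert np.all(np.diff(na.values) >= -1e-15)
    assert np.all(na.values >= 0)
    assert km(0.0) == 1.0 and na(0.0) == 0.0


def test_km_equals_state1_occupation_single_transition():
    """Cross-module oracle: with one transition the product integral is the
    product limit."""
    from msmtx.multistate import aalen_johansen
    from msmtx.stepfun import StepFunction

    rng = np.random.default_rng(9)
    n = 50
    t = rng.exponential(1.0, n)
    c = rng.exponential(1.2, n)
    rows = rows_df(np.zeros(n), np.minimum(t, c), (t <= c).astype(int))
    na = nelson_aalen(rows)
    km = kaplan_meier(rows)
    zero = StepFunction(knots=np.array([na.knots.max()]),
                        values=np.array([0.0]), kind="cumhaz")
    pmat = aalen_johansen(zero, na, zero)
    p11 = pmat.probs[:, 0, 0]
    np.testing.assert_allclose(p11, km(pmat.times), atol=1e-12)
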