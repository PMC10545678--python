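import numpy as np
import pandas as pd
import pytest

from prskit.dca import (CauseSpecificExponentialRisk, cif, decision_table,
                        fit_risk_models, fp_reduction_per100, nb_treat_all,
                        net_benefit, snb_bootstrap)
from prskit.simulate import SimTruth, cif_two_exponential, simulate_cohort


class TestCIF:
    def test_reduces_to_ecdf_without_competing_or_censoring(self):
        rng = np.random.default_rng(131)
        t = rng.exponential(5.0, 500)
        e = np.ones(500, dtype=int)
        assert cif(t, e, 4.0) == pytest.approx(np.mean(t <= 4.0))

    def test_all_deaths_first_gives_zero(self):
        t = np.array([1.0, 2.0, 3.0])
        e = np.array([2, 2, 2])
        assert cif(t, e, 10.0) == 0.0

    def test_hand_aalen_johansen_example(self):
        t = np.array([1.0, 2.0, 3.0, 5.0])
        e = np.array([1, 2, 0, 1])
        assert cif(t, e, 4.0) == pytest.approx(0.25, abs=1e-15)

    def test_matches_lifelines(self):
        from lifelines import AalenJohansenFitter
        rng = np.random.default_rng(132)
        n = 400
        t = np.round(rng.exponential(8.0, n), 3)
        e = rng.choice([0, 1, 2], n, p=[0.3, 0.4, 0.3])
        t = t + rng.random(n) * 1e-6  # break ties so the oracle does not jitter
        ajf = AalenJohansenFitter(calculate_variance=False)
        ajf.fit(t, e, event_of_interest=1)
        at = 6.0
        expected = float(ajf.cumulative_density_.loc[:at].iloc[-1].iloc[0])
        assert cif(t, e, at) == pytest.approx(expected, abs=1e-10)

    def test_ties_at_event_times_handled(self):
        t = np.array([1.0, 1.0, 1.0, 2.0])
        e = np.array([1, 2, 0, 1])
        # at t=1: 2 events among 4 at risk, one of cause 1 -> 0.25; S(1)=0.5
        # at t=2: 1 cause-1 event among 1 at risk -> + 0.5
        assert cif(t, e, 2.0) == pytest.approx(0.75)


class TestRiskModels:
    def _cohort(self, n, seed, **kw):
        truth = SimTruth(variant_effects={}, **kw)
        return truth, simulate_cohort(truth, n, {"EUR": 1.0}, 10.0, seed=seed)

    def test_intercept_only_risks_equal_marginal(self):
        truth, coh = self._cohort(20000, 141, beta_prs=0.0, famhx_log_or=0.0,
                                  baseline_risk_10yr=0.02)
        X = np.zeros((len(coh), 1))
        y = np.column_stack([coh["time"], coh["event"]])
        m = CauseSpecificExponentialRisk().fit(X, y)
        risks = m.predict_risk(X, 10.0)
        assert np.ptp(risks) < 1e-9
        lam1 = (coh["event"] == 1).sum() / coh["time"].sum()
        lam2 = (coh["event"] == 2).sum() / coh["time"].sum()
        assert risks[0] == pytest.approx(cif_two_exponential(lam1, lam2, 10.0), rel=1e-6)

    def test_famhx_only_model_two_distinct_risks(self):
        _, coh = self._cohort(10000, 142, baseline_risk_10yr=0.02)
        risks = fit_risk_models(coh, 10.0)
        assert len(np.unique(np.round(risks["famhx"], 12))) == 2

    def test_self_recovery_of_generating_risks(self):
        truth, coh = self._cohort(50000, 143, baseline_risk_10yr=0.01)
        risks = fit_risk_models(coh, 10.0)["famhx_prs"]
        fam = (coh["famhx"] == "yes").to_numpy(float)
        lam1 = truth.baseline_hazard * np.exp(truth.beta_prs * coh["prs"].to_numpy()
                                              + truth.famhx_log_or * fam)
        true_risk = np.array([cif_two_exponential(l, truth.death_hazard, 10.0)
                              for l in lam1])
        rel_err = np.abs(risks - true_risk) / true_risk
        assert rel_err.mean() < 0.10

    def test_missing_famhx_rejected(self):
        _, coh = self._cohort(500, 144)
        coh.loc[0, "famhx"] = "missing"
        with pytest.raises(ValueError, match="missing"):
            fit_risk_models(coh, 10.0)

    def test_logistic_fallback_runs(self):
        _, coh = self._cohort(10000, 145, baseline_risk_10yr=0.02)
        risks = fit_risk_models(coh, 10.0, model="logistic")
        assert np.all((risks["famhx_prs"] >= 0) & (risks["famhx_prs"] <= 1))


class TestNetBenefit:
    def _uncensored(self, n, seed, p_event=0.3):
        rng = np.random.default_rng(seed)
        event = rng.binomial(1, p_event, n)
        time = np.where(event == 1, rng.uniform(0, 9, n), 10.0)
        risk = np.clip(rng.beta(2, 5, n) * 0.8 + 0.1 * event, 0, 1)
        return risk, time, event

    def test_counting_oracle_exact_toy(self):
        # no censoring, no deaths: NB must equal TP/N - FP/N * w exactly
        risk = np.array([0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1, 0.05])
        event = np.array([1, 1, 0, 1, 0, 0, 0, 1, 0, 0])
        time = np.where(event == 1, 5.0, 10.0)
        for rt in (0.15, 0.45, 0.75):
            row = net_benefit(risk, time, event, rt, 10.0)
            z = risk >= rt
            tp = (z & (event == 1)).sum()
            fp = (z & (event == 0)).sum()
            w = rt / (1 - rt)
            assert row.nb == pytest.approx(tp / 10 - fp / 10 * w, abs=1e-12)

    def test_counting_oracle_random_cohorts(self):
        for seed in (151, 152, 153):
            risk, time, event = self._uncensored(500, seed)
            for rt in (0.1, 0.3, 0.5):
                row = net_benefit(risk, time, event, rt, 10.0)
                z = risk >= rt
                n = len(risk)
                tp = (z & (event == 1)).sum() / n
                fp = (z & (event == 0)).sum() / n
                w = rt / (1 - rt)
                assert row.nb == pytest.approx(tp - fp * w, abs=1e-12)

    def test_treat_all_limit_and_treat_none(self):
        risk, time, event = self._uncensored(400, 154)
        p = cif(time, event, 10.0)
        row = net_benefit(np.ones(400), time, event, 1e-9, 10.0)
        assert row.nb == pytest.approx(p, rel=1e-6)
        assert row.snb == pytest.approx(1.0, rel=1e-6)
        assert nb_treat_all(p, 1e-9) == pytest.approx(p, rel=1e-6)

    def test_tp_fp_partition_identity(self):
        risk, time, event = self._uncensored(300, 155)
        event[:30] = 2  # add competing deaths
        for rt in np.linspace(0.05, 0.9, 8):
            row = net_benefit(risk, time, event, rt, 10.0)
            assert row.tp + row.fp == pytest.approx((risk >= rt).sum(), abs=1e-9)

    def test_fp_reduction_formula(self):
        assert fp_reduction_per100(0.001142, 0.000263, 0.0029) == pytest.approx(30.2, abs=0.05)
        assert fp_reduction_per100(0.5, 0.5, 0.1) == 0.0
        with pytest.raises(ValueError):
            fp_reduction_per100(0.1, 0.1, 0.0)

    def test_treat_all_nb_strictly_decreasing_and_crosses_zero(self):
        p = 0.003
        rts = np.linspace(0.0005, 0.006, 30)
        nbs = np.array([nb_treat_all(p, rt) for rt in rts])
        assert np.all(np.diff(nbs) < 0)
        # sign change brackets rt = p (w = p/(1-p))
        assert nbs[rts < p].min() > 0 > nbs[rts > p + 1e-9].max()


@pytest.fixture(scope="module")
def cohort():
    truth = SimTruth(variant_effects={}, baseline_risk_10yr=0.003)
    return simulate_cohort(truth, 20000, {"EUR": 1.0}, 10.0, seed=161,
                           age_range=(40, 49))


class TestDecisionTable:
    def test_full_table_contents(self, cohort):
        tab = decision_table(cohort, [0.002, 0.0029], 10.0)
        assert set(tab["model"]) == {"treat_all", "treat_none", "famhx", "famhx_prs"}
        assert len(tab) == 8
        assert (tab["snb"] <= 1.0 + 1e-12).all()
        assert (tab[tab["model"] == "treat_none"]["nb"] == 0).all()
        model_rows = tab[tab["model"].isin(["famhx", "famhx_prs"])]
        assert np.allclose(model_rows["net_interventions_avoided_per100"],
                           model_rows["fp_reduction_per100"])

    def test_nb_never_exceeds_p(self, cohort):
        tab = decision_table(cohort, [0.001, 0.0029, 0.004], 10.0)
        assert (tab["nb"] <= tab["p"] + 1e-12).all()

    def test_threshold_validation(self, cohort):
        with pytest.raises(ValueError):
            decision_table(cohort, [0.0, 0.1], 10.0)


class TestSNBBootstrap:
    def test_seeded_repeatability_and_identical_models(self):
        truth = SimTruth(variant_effects={}, baseline_risk_10yr=0.01)
        coh = simulate_cohort(truth, 4000, {"EUR": 1.0}, 10.0, seed=171)
        r1 = snb_bootstrap(coh, 0.0029, n_bootstrap=100, seed=7,
                           models=("famhx", "famhx"))
        r2 = snb_bootstrap(coh, 0.0029, n_bootstrap=100, seed=7,
                           models=("famhx", "famhx"))
        assert r1["famhx"]["ci95"] == r2["famhx"]["ci95"]
        assert r1["difference"]["p_value"] == pytest.approx(1.0)
        lo, hi = r1["difference"]["ci95"]
        assert lo <= 0 <= hi

    def test_ci_width_shrinks_with_n(self):
        truth = SimTruth(variant_effects={}, baseline_risk_10yr=0.01)
        widths = []
        for i, n in enumerate((2000, 8000, 32000)):
            coh = simulate_cohort(truth, n, {"EUR": 1.0}, 10.0, seed=180 + i)
            res = snb_bootstrap(coh, 0.0029, n_bootstrap=100, seed=i)
            lo, hi = res["famhx_prs"]["ci95"]
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]
        assert 2.0 < widths[0] / widths[2] < 8.0
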