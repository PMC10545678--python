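import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from prskit.risk import (adjusted_auc, age_bands, age_trend_test, compare_auc,
                         or_per_sd, pool_ivw, rr_calibration, rr_percentile_curve,
                         ORResult)


def brute_force_auc(x_cases, x_controls):
    """Pairwise Mann-Whitney count, ties 1/2 — oracle for small n."""
    total = 0.0
    for a in x_cases:
        for b in x_controls:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(x_cases) * len(x_controls))


class TestAdjustedAUC:
    def test_null_prs_auc_half(self):
        rng = np.random.default_rng(101)
        prs = rng.standard_normal(5000)
        case = rng.binomial(1, 0.3, 5000)
        res = adjusted_auc(prs, case, n_bootstrap=60, seed=1)
        assert abs(res.estimate - 0.5) < 0.02

    def test_binormal_closed_form(self):
        rng = np.random.default_rng(102)
        n1, n0 = 3000, 7000
        x = np.concatenate([rng.normal(1, 1, n1), rng.normal(0, 1, n0)])
        case = np.concatenate([np.ones(n1), np.zeros(n0)])
        res = adjusted_auc(x, case, n_bootstrap=60, seed=2)
        assert abs(res.estimate - stats.norm.cdf(1 / np.sqrt(2))) < 0.01

    def test_confounder_removal(self):
        # outcome driven by the covariate; PRS correlated with covariate only
        rng = np.random.default_rng(103)
        n = 20000
        c = rng.standard_normal(n)
        prs = 0.8 * c + 0.6 * rng.standard_normal(n)
        case = rng.binomial(1, 1 / (1 + np.exp(-(-1.5 + 1.2 * c))))
        unadj = adjusted_auc(prs, case, covariates=None, n_bootstrap=50, seed=3)
        adj = adjusted_auc(prs, case, covariates=c, n_bootstrap=50, seed=3)
        assert unadj.estimate > 0.55
        assert abs(adj.estimate - 0.5) < 0.02

    def test_matches_brute_force_oracle_with_ties(self):
        rng = np.random.default_rng(104)
        prs = np.round(rng.standard_normal(150), 1)  # rounding induces ties
        case = rng.binomial(1, 0.4, 150)
        res = adjusted_auc(prs, case, n_bootstrap=50, seed=4)
        oracle = brute_force_auc(prs[case == 1], prs[case == 0])
        assert res.estimate == pytest.approx(oracle, abs=1e-12)

    def test_single_class_error_and_bootstrap_warning(self):
        with pytest.raises(ValueError):
            adjusted_auc([1.0, 2.0], [1, 1], n_bootstrap=60)
        with pytest.warns(UserWarning):
            adjusted_auc(np.arange(40.0), np.tile([0, 1], 20), n_bootstrap=10, seed=1)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(105)
        prs = rng.standard_normal(400)
        case = rng.binomial(1, 0.3, 400)
        r1 = adjusted_auc(prs, case, n_bootstrap=80, seed=9)
        r2 = adjusted_auc(prs, case, n_bootstrap=80, seed=9)
        assert r1.se == r2.se and r1.ci95 == r2.ci95


class TestCompareAUC:
    def test_identical_scores_p_near_one(self):
        rng = np.random.default_rng(106)
        prs = rng.standard_normal(500)
        case = rng.binomial(1, 0.3, 500)
        assert compare_auc(prs, prs, case, n_bootstrap=100, seed=5) == pytest.approx(1.0)

    def test_power_against_degraded_score(self):
        wins = 0
        for rep in range(10):
            rng = np.random.default_rng(200 + rep)
            n = 10000
            signal = rng.standard_normal(n)
            case = rng.binomial(1, 1 / (1 + np.exp(-(-1.0 + 0.7 * signal))))
            degraded = 0.5 * signal + np.sqrt(1 - 0.25) * rng.standard_normal(n)
            p = compare_auc(signal, degraded, case, n_bootstrap=120, seed=rep)
            wins += p < 0.05
        assert wins >= 8

    def test_type_one_error_uniform_p(self):
        # permuted outcome: p-values should be uniform across replicates
        pvals = []
        for rep in range(120):
            rng = np.random.default_rng(400 + rep)
            n = 300
            prs1 = rng.standard_normal(n)
            prs2 = rng.standard_normal(n)
            case = rng.binomial(1, 0.3, n)
            pvals.append(compare_auc(prs1, prs2, case, n_bootstrap=80, seed=rep))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestPoolIVW:
    def test_passthrough_and_mean(self):
        assert pool_ivw([0.6], [0.02]) == (pytest.approx(0.6), pytest.approx(0.02))
        est, se = pool_ivw([0.2, 0.4, 0.6], [0.1, 0.1, 0.1])
        assert est == pytest.approx(0.4)
        assert se == pytest.approx(0.1 / np.sqrt(3))

    def test_hand_computation(self):
        est, se = pool_ivw([0.60, 0.70], [0.02, 0.04])
        assert est == pytest.approx(0.62)
        assert se == pytest.approx(0.017888543819998318)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            pool_ivw([], [])
        with pytest.raises(ValueError):
            pool_ivw([0.1, 0.2], [0.1, -0.1])


class TestORPerSD:
    def _cohort(self, n, beta, seed, base=-3.5):
        rng = np.random.default_rng(seed)
        prs = rng.standard_normal(n)
        case = rng.binomial(1, 1 / (1 + np.exp(-(base + beta * prs))))
        return prs, case

    def test_permuted_prs_or_near_one(self):
        prs, case = self._cohort(20000, 0.0, 110, base=-2.0)
        res = or_per_sd(prs, case)[0]
        assert res.ci95[0] < 1.0 < res.ci95[1]

    def test_recovers_generating_or(self):
        prs, case = self._cohort(30000, np.log(1.67), 111, base=-2.5)
        res = or_per_sd(prs, case)[0]
        assert res.ci95[0] < 1.67 < res.ci95[1]
        assert res.or_per_sd == pytest.approx(1.67, rel=0.1)

    def test_small_or_degenerate_strata_skipped(self):
        prs, case = self._cohort(2000, 0.3, 112, base=-1.0)
        labels = np.where(np.arange(2000) < 30, "tiny", "big").astype(object)
        case2 = case.copy()
        case2[:30] = 1  # all-case stratum
        res = or_per_sd(prs, case2, strata={"grp": labels})
        names = {r.stratum for r in res}
        assert "grp:big" in names and "grp:tiny" not in names

    def test_missing_level_excluded(self):
        prs, case = self._cohort(4000, 0.3, 113, base=-1.0)
        fam = np.random.default_rng(114).choice(["yes", "no", "missing"], 4000)
        res = or_per_sd(prs, case, strata={"famhx": fam})
        assert {r.stratum for r in res} == {"overall", "famhx:yes", "famhx:no"}


class TestAgeTrend:
    def _res(self, ors, ses):
        out = []
        for o, s in zip(ors, ses):
            lo, hi = np.exp(np.log(o) - 1.96 * s), np.exp(np.log(o) + 1.96 * s)
            out.append(ORResult(o, (lo, hi), 0.5, "age"))
        return out

    def test_flat_ors_p_near_one(self):
        slope, p = age_trend_test(self._res([1.5] * 5, [0.1] * 5))
        assert abs(slope) < 1e-12 and p == pytest.approx(1.0)

    def test_strong_decreasing_trend(self):
        ors = np.exp(np.linspace(0.6, 0.2, 5))
        slope, p = age_trend_test(self._res(ors, [0.001] * 5))
        assert slope < 0 and p < 1e-6

    def test_reversal_flips_slope_keeps_p(self):
        ors = [1.9, 1.7, 1.55, 1.5, 1.4]
        res = self._res(ors, [0.05] * 5)
        s1, p1 = age_trend_test(res)
        s2, p2 = age_trend_test(res[::-1])
        assert s2 == pytest.approx(-s1)
        assert p2 == pytest.approx(p1)

    def test_age_band_labels(self):
        bands = age_bands([45, 50, 59, 60, 69.5, 79, 80, 95])
        assert list(bands) == ["<50", "50-59", "50-59", "60-69", "60-69",
                               "70-79", ">80", ">80"]

    def test_too_few_strata_error(self):
        with pytest.raises(ValueError):
            age_trend_test(self._res([1.5, 1.4], [0.1, 0.1]))


class TestRRPercentile:
    def test_crossing_point_is_exactly_one(self):
        beta = np.log(1.5)
        p_cross = stats.norm.cdf(beta / 2)
        assert rr_percentile_curve(1.5, [p_cross])[0] == pytest.approx(1.0, abs=1e-12)

    def test_or_one_gives_flat_curve(self):
        np.testing.assert_allclose(rr_percentile_curve(1.0, [0.1, 0.5, 0.9]), 1.0)

    @settings(derandomize=True, max_examples=30)
    @given(orr=st.floats(1.01, 3.0))
    def test_strictly_increasing_for_or_above_one(self, orr):
        ps = np.linspace(0.05, 0.95, 19)
        rr = rr_percentile_curve(orr, ps)
        assert np.all(np.diff(rr) > 0)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            rr_percentile_curve(0.0, [0.5])
        with pytest.raises(ValueError):
            rr_percentile_curve(1.5, [0.0])


class TestRRCalibration:
    def _cohort(self, n, beta, seed, p0=0.02):
        # log-linear (relative-risk) generating model, matching the
        # model-based expected OR under a rare outcome
        rng = np.random.default_rng(seed)
        prs = rng.standard_normal(n)
        case = rng.binomial(1, np.minimum(p0 * np.exp(beta * prs), 1.0))
        return prs, case

    def test_reference_stratum_is_unity(self):
        prs, case = self._cohort(20000, 0.4, 120)
        tab = rr_calibration(prs, case, or_per_sd=np.exp(0.4))
        ref = tab[tab["is_reference"]]
        assert len(ref) == 2
        assert (ref["observed_or"] == 1.0).all()
        assert np.allclose(ref["expected_or"], 1.0, atol=0.05)

    def test_well_specified_model_calibrated(self):
        prs, case = self._cohort(50000, 0.5, 121)
        tab = rr_calibration(prs, case, or_per_sd=np.exp(0.5))
        non_ref = tab[~tab["is_reference"]]
        covered = ((non_ref["ci_low"] <= non_ref["expected_or"])
                   & (non_ref["expected_or"] <= non_ref["ci_high"]))
        assert covered.sum() >= 17

    def test_null_model_expected_one_and_covered(self):
        prs, case = self._cohort(50000, 0.0, 122, p0=0.05)
        tab = rr_calibration(prs, case, or_per_sd=1.0)
        assert np.allclose(tab["expected_or"], 1.0)
        non_ref = tab[~tab["is_reference"]]
        covered = (non_ref["ci_low"] <= 1.0) & (1.0 <= non_ref["ci_high"])
        assert covered.sum() >= 17

    def test_twenty_bins_and_counts(self):
        prs, case = self._cohort(10000, 0.3, 123)
        tab = rr_calibration(prs, case, or_per_sd=np.exp(0.3))
        assert len(tab) == 20
        assert tab["n_cases"].sum() + tab["n_controls"].sum() == 10000
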