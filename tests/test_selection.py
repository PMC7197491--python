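import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tempopg import (
    detection_design,
    estimate_sigma_s2,
    fit_mu_s,
    interval_s_estimates,
    predicted_var_s,
    sparse_design,
    two_point_s,
    zeta,
)
from tempopg.selection import _sigma_s2_panel, round_sig

from conftest import make_fs


def p_from_zeta(z):
    return 1.0 / (1.0 + np.exp(np.asarray(z)))


class TestZeta:
    def test_values(self):
        assert zeta(0.5) == 0.0
        np.testing.assert_allclose(zeta(0.1), np.log(9), rtol=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(min_value=1e-6, max_value=1 - 1e-6))
    def test_antisymmetry(self, p):
        np.testing.assert_allclose(zeta(p), -zeta(1 - p), atol=1e-9)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
    def test_boundaries_rejected(self, p):
        with pytest.raises(ValueError):
            zeta(p)


class TestFitMuS:
    def test_noiseless_line_recovered_exactly(self):
        t = np.arange(10)
        fs = make_fs(p_from_zeta(2.0 - 0.01 * t))
        fit = fit_mu_s(fs)
        np.testing.assert_allclose(fit.s_hat, 0.01, atol=1e-12)
        assert fit.se_ols < 1e-12 and not fit.dropped

    def test_constant_frequencies_give_zero(self):
        fit = fit_mu_s(make_fs(np.full(6, 0.3)))
        np.testing.assert_allclose(fit.s_hat, 0.0, atol=1e-15)

    def test_boundary_frequency_drops_site(self):
        fit = fit_mu_s(make_fs([0.2, 0.0, 0.3, 0.4]))
        assert fit.dropped and np.isnan(fit.s_hat)

    @pytest.mark.parametrize("s", [1e-3, 5e-3, 1e-2])
    def test_deterministic_trajectory_recovers_log1p_s(self, s):
        # genic update: zeta declines by exactly ln(1+s) per generation
        p = [0.2]
        for _ in range(20):
            p.append(p[-1] * (1 + s) / (1 + p[-1] * s))
        fit = fit_mu_s(make_fs(p))
        np.testing.assert_allclose(fit.s_hat, np.log1p(s), atol=1e-12)
        assert abs(fit.s_hat - s) <= s**2 / 2 + 1e-12

    def test_ols_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        p = np.clip(0.4 + rng.normal(0, 0.03, 15), 0.05, 0.95)
        fs = make_fs(p)
        fit = fit_mu_s(fs)
        t = np.arange(15, dtype=float)
        res = sm.OLS(np.log((1 - p) / p), sm.add_constant(t)).fit()
        np.testing.assert_allclose(fit.s_hat, -res.params[1], rtol=1e-10)
        np.testing.assert_allclose(fit.se_ols, res.bse[1], rtol=1e-10)


class TestPredictedVarS:
    def test_printed_T49_coefficient(self):
        # full-survey design value: variance ~ 0.000050/[n p0 (1-p0)]
        n, p0 = 100.0, 0.5
        np.testing.assert_allclose(
            predicted_var_s(49, n, p0) * n * p0 * (1 - p0), 5.0e-5, rtol=0.03
        )

    def test_hand_evaluated_with_fluctuation_term(self):
        np.testing.assert_allclose(
            predicted_var_s(5, 100, 0.5, 0.01), 0.0045, rtol=1e-12
        )

    def test_large_n_limit(self):
        assert predicted_var_s(10, 1e12, 0.5) < 1e-13

    @pytest.mark.parametrize(
        "kwargs", [dict(T=1), dict(n=0.5), dict(p0=0.0), dict(sigma_s2=-1e-3)]
    )
    def test_domain_errors(self, kwargs):
        args = dict(T=10, n=100, p0=0.5, sigma_s2=0.0)
        args.update(kwargs)
        with pytest.raises(ValueError):
            predicted_var_s(**args)


class TestTwoPoint:
    def test_hand_evaluated_variance(self):
        p = np.full(11, 0.5)
        res = two_point_s(make_fs(p, n=100))
        np.testing.assert_allclose(res.var2, 8e-4, rtol=1e-12)
        assert res.s_hat2 == 0.0

    def test_min_se_gain_doubles_and_quadruples(self):
        p24 = np.full(25, 0.4)
        p96 = np.full(97, 0.4)
        np.testing.assert_allclose(two_point_s(make_fs(p24)).min_se_gain, 2.0)
        np.testing.assert_allclose(two_point_s(make_fs(p96)).min_se_gain, 4.0)

    def test_variance_ratio_formula(self):
        res = two_point_s(make_fs(np.linspace(0.5, 0.3, 13)))
        pq0, pqT = 0.25, 0.21
        np.testing.assert_allclose(
            res.ratio_vs_full, (12 / 6) * (1 + pq0 / pqT), rtol=1e-12
        )

    def test_boundary_rejected(self):
        with pytest.raises(ValueError):
            two_point_s(make_fs([0.5, 0.4, 0.0]))


class TestSparseDesign:
    def test_identity_when_dense(self):
        assert sparse_design(30, 1, 30).inflation_se == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "T_prime, D, expect", [(24, 2, 1.5), (12, 4, 2.1)]
    )
    def test_printed_inflations(self, T_prime, D, expect):
        infl = sparse_design(T_prime, D, 49).inflation_se
        assert round_sig(infl, 2) == expect


class TestIntervalEstimates:
    def test_arithmetic(self):
        s = interval_s_estimates(make_fs(p_from_zeta([0.0, 0.1, 0.05])))
        np.testing.assert_allclose(s, [-0.1, 0.05], atol=1e-12)

    def test_constant_series_all_zero(self):
        s = interval_s_estimates(make_fs(np.full(5, 0.4)))
        np.testing.assert_allclose(s, 0.0, atol=1e-15)

    def test_boundary_interval_flagged(self):
        s = interval_s_estimates(make_fs([0.2, 0.0, 0.3]))
        assert np.isnan(s[0]) and np.isnan(s[1])


class TestSigmaS2:
    def test_hand_evaluated_var_e(self):
        # constant p=0.5, n=100, T=4: phi=0.02 everywhere,
        # Var(e) = (1/4)(0.04 + (8/3)*0.06) = 0.05
        est = estimate_sigma_s2(make_fs(np.full(5, 0.5), n=100))
        np.testing.assert_allclose(est.var_e, 0.05, rtol=1e-12)
        assert est.tau == 2

    def test_identity_var_s_minus_var_e(self, rng):
        p = np.clip(0.5 + rng.normal(0, 0.05, (20, 11)), 0.05, 0.95)
        var_s, var_e, sig2, ok, _ = _sigma_s2_panel(
            p, np.full(p.shape, 100), 2
        )
        assert ok.all()
        np.testing.assert_allclose(sig2, var_s - var_e, rtol=0, atol=0)

    def test_noiseless_constant_s_large_n_gives_zero(self):
        p = [0.3]
        for _ in range(10):
            p.append(p[-1] * 1.01 / (1 + p[-1] * 0.01))
        est = estimate_sigma_s2(make_fs(p, n=10**12))
        assert abs(est.sigma_s2_hat) < 1e-10
        assert est.var_s_hat < 1e-20  # all interval estimates equal ln(1.01)

    def test_negative_flag_not_clipped(self):
        # pure sampling noise often yields Var(s_hat) < Var(e)
        est = estimate_sigma_s2(make_fs([0.5, 0.5, 0.5, 0.5, 0.5], n=100))
        assert est.negative_flag == (est.sigma_s2_hat < 0)
        assert est.sigma_s2_hat == est.var_s_hat - est.var_e

    def test_odd_T_warns_and_truncates(self):
        with pytest.warns(UserWarning, match="odd"):
            est = estimate_sigma_s2(make_fs(np.full(6, 0.5)))
        assert est.tau == 2

    def test_boundary_frequency_raises(self):
        with pytest.raises(ValueError):
            estimate_sigma_s2(make_fs([0.5, 0.0, 0.5, 0.5, 0.5]))

    def test_var_e_matches_pure_sampling_noise(self, rng):
        # no drift, no selection: empirical variance of single-interval
        # estimates vs the closed-form average sampling variance
        n, p, T, reps = 1000, 0.5, 50, 10_000
        phat = rng.binomial(2 * n, p, size=(reps, T + 1)) / (2 * n)
        z = np.log((1 - phat) / phat)
        s_i = z[:, :-1] - z[:, 1:]
        # non-overlapping intervals are independent: their variance is the
        # average sampling variance Var(e) estimates
        emp = s_i[:, ::2].var(ddof=1)
        _, var_e, _, ok, _ = _sigma_s2_panel(phat, np.full(phat.shape, n), 2)
        assert ok.all()
        assert abs(var_e.mean() / emp - 1) < 0.05


class TestDetectionDesign:
    def test_p0_half_gives_96_over_mu2(self):
        res = detection_design(0.01, 0.5, 100)
        np.testing.assert_allclose(res.critical_T3n, 96 / 0.01**2, rtol=1e-12)

    def test_rare_allele_inflates_by_2_8(self):
        r = detection_design(0.01, 0.1).critical_T3n / \
            detection_design(0.01, 0.5).critical_T3n
        assert round_sig(r, 2) == 2.8

    def test_critical_durations(self):
        assert detection_design(0.01, 0.5, 100).critical_T_rounded == 21
        # the weaker coefficient needs on the order of a hundred generations
        T = detection_design(0.001, 0.5, 100).critical_T
        assert abs(T - 100) <= 2

    def test_monotone_in_mu_s_and_pq(self):
        assert (
            detection_design(0.02, 0.5).critical_T3n
            < detection_design(0.01, 0.5).critical_T3n
        )
        assert (
            detection_design(0.01, 0.5).critical_T3n
            < detection_design(0.01, 0.2).critical_T3n
        )

    def test_domain_error(self):
        with pytest.raises(ValueError):
            detection_design(-0.01)
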