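"""Unit tests for the analytic logistic response model."""

import numpy as np
import pytest
from scipy import stats

from popcircuit.logistic import (LogisticFit, f_half_from_threshold,
                                 fit_logistic, local_sensitivity, mean_rate,
                                 pair_correlation, q_from_threshold,
                                 rate_contour, threshold_for_rate,
                                 threshold_from_fit)

LOGIT_QT = np.log(0.01 / 0.99)   # about -4.5951


class TestThresholdConversion:
    @pytest.mark.parametrize("beta,f_half,expected", [
        (1.0, 0.0, LOGIT_QT),                  # ln(1/99) ~ -4.5951
        (2.0, 0.3, 0.3 + LOGIT_QT / 2.0),      # -1.9976
        (10.0, -1.0, -1.0 + LOGIT_QT / 10.0),
    ])
    def test_closed_form(self, beta, f_half, expected):
        fit = LogisticFit(beta=beta, f_half=f_half)
        assert threshold_from_fit(fit) == pytest.approx(expected, abs=1e-12)

    def test_qthresh_half_gives_midpoint(self):
        fit = LogisticFit(beta=3.0, f_half=0.7, q_thresh=0.5)
        assert threshold_from_fit(fit) == pytest.approx(0.7)

    def test_beta_zero_flagged(self):
        fit = LogisticFit(beta=0.0, f_half=0.0)
        assert np.isnan(threshold_from_fit(fit))

    def test_roundtrip(self):
        th = threshold_from_fit(LogisticFit(beta=4.0, f_half=0.2))
        assert f_half_from_threshold(4.0, th) == pytest.approx(0.2)


class TestMeanRate:
    @pytest.mark.parametrize("beta", [0.5, 2.0, 10.0])
    def test_symmetry_midpoint_zero(self, beta):
        # q(f) + q(-f) = 1 under a symmetric density => mu = 1/2
        th = 0.0 + LOGIT_QT / beta
        assert mean_rate(beta, th) == pytest.approx(0.5, abs=1e-9)

    def test_step_limit_matches_gaussian_tail(self):
        # beta -> inf: q is a unit step at f_half, so mu = Phi(-f_half)
        f_half = 1.2816
        th = f_half + LOGIT_QT / 1e4
        assert mean_rate(1e4, th) == pytest.approx(stats.norm.sf(f_half),
                                                   rel=1e-3)

    def test_flat_curve(self):
        assert mean_rate(0.0, 5.0) == 0.5
        assert mean_rate(0.0, -17.0) == 0.5

    def test_gauss_matches_adaptive_for_moderate_slopes(self):
        # fixed-node Gauss-Hermite degrades slowly as the curve steepens
        for beta, th, tol in [(1.0, -1.0, 5e-6), (5.0, 0.5, 5e-5),
                              (20.0, 1.0, 1e-3)]:
            assert mean_rate(beta, th, method="gauss") == pytest.approx(
                mean_rate(beta, th, method="adaptive"), abs=tol)

    def test_monotone_decreasing_in_threshold(self):
        mus = [mean_rate(3.0, th) for th in np.linspace(-2, 2, 9)]
        assert np.all(np.diff(mus) < 0)


class TestPairCorrelation:
    def test_flat_neurons_uncorrelated(self):
        assert pair_correlation(0.0, 0.0) == 0.0

    def test_step_pair_fully_correlated(self):
        # step neurons at any rate: E[q^2] = mu => cov = var => corr = 1
        th = threshold_for_rate(1e4, 0.3)
        assert pair_correlation(1e4, th) == pytest.approx(1.0, abs=1e-3)

    def test_matches_monte_carlo(self, rng):
        beta, f_half = 2.0, 1.0
        th = f_half + LOGIT_QT / beta
        f = rng.standard_normal(4_000_000)
        q = q_from_threshold(f, beta, th)
        mu = q.mean()
        cov = (q**2).mean() - mu**2
        mc = cov / (mu * (1 - mu))
        se = 3 * q.std() / np.sqrt(f.size)   # generous MC error scale
        assert pair_correlation(beta, th) == pytest.approx(mc, abs=max(se, 1e-3))

    def test_heterogeneous_pair_normalization(self):
        # corr(a, b)^2 <= corr(a, a) * corr(b, b) (Cauchy-Schwarz on cov)
        ca = pair_correlation(3.0, 0.5)
        cb = pair_correlation(8.0, 1.0)
        cab = pair_correlation(3.0, 0.5, 8.0, 1.0)
        assert 0 < cab
        assert cab**2 <= ca * cb + 1e-12

    def test_saturated_neuron_flagged_zero(self):
        # a neuron with mu ~ 1 has no variance: correlation reported as 0
        assert pair_correlation(1e4, -40.0) == 0.0


class TestRateContour:
    def test_half_rate_contour_thresholds(self):
        # mu = 0.5 forces f_half = 0, so f_thresh = logit(q_t)/beta
        out = rate_contour(0.5, np.array([1.0, 2.0, 5.0]))
        for beta, th, _ in out:
            assert th == pytest.approx(LOGIT_QT / beta, abs=1e-7)

    def test_contour_rate_is_exact(self):
        out = rate_contour(0.1, np.logspace(-1, 1.2, 7))
        for beta, th, _ in out:
            assert mean_rate(beta, th) == pytest.approx(0.1, abs=1e-7)

    def test_correlation_monotone_in_slope(self):
        out = rate_contour(0.1, np.logspace(-1, np.log10(50), 15))
        corrs = [c for _, _, c in out]
        assert np.all(np.diff(corrs) > 0)

    def test_step_limit_correlation_approaches_one(self):
        out = rate_contour(0.1, np.array([200.0, 500.0]))
        assert out[-1][2] > 0.97

    def test_rejects_bad_grid(self):
        with pytest.raises(ValueError):
            rate_contour(0.1, np.array([1.0, 0.5]))
        with pytest.raises(ValueError):
            rate_contour(1.5, np.array([1.0, 2.0]))


class TestLocalSensitivity:
    @pytest.mark.parametrize("beta,th", [(2.0, 0.5), (4.0, 1.0), (8.0, 2.0)])
    def test_signs_in_physiological_region(self, beta, th):
        s = local_sensitivity(beta, th)
        assert s["dmu_dtheta"] < 0 and s["dcorr_dtheta"] < 0
        assert s["dmu_dbeta"] > 0 and s["dcorr_dbeta"] > 0

    def test_threshold_derivative_matches_analytic_integrand(self):
        beta, th = 3.0, 0.8
        # dq/dtheta = -beta q (1 - q); integrate against the drive density
        f = np.polynomial.hermite_e.hermegauss(301)
        x, w = f[0], f[1] / f[1].sum()
        q = q_from_threshold(x, beta, th)
        analytic = float(np.dot(w, -beta * q * (1 - q)))
        s = local_sensitivity(beta, th, h=1e-4)
        assert s["dmu_dtheta"] == pytest.approx(analytic, abs=1e-5)

    def test_central_difference_second_order(self):
        beta, th = 3.0, 0.8
        f = np.polynomial.hermite_e.hermegauss(301)
        x, w = f[0], f[1] / f[1].sum()
        q = q_from_threshold(x, beta, th)
        truth = float(np.dot(w, -beta * q * (1 - q)))
        e1 = abs(local_sensitivity(beta, th, h=0.08)["dmu_dtheta"] - truth)
        e2 = abs(local_sensitivity(beta, th, h=0.04)["dmu_dtheta"] - truth)
        assert e2 < e1 / 2.5   # O(h^2) shrinkage, with slack

    def test_one_sided_flag_near_zero_slope(self):
        s = local_sensitivity(1e-4, 0.5, h=1e-3)
        assert s["one_sided_beta"]


class TestFitLogistic:
    def test_parameter_recovery(self, rng):
        beta, f_half = 4.0, 0.2
        f = np.linspace(-0.8, 1.2, 11)
        q = 1 / (1 + np.exp(-beta * (f - f_half)))
        k = rng.binomial(100, q)
        fit = fit_logistic(f, k, np.full(f.size, 100))
        assert fit.valid and not fit.separated
        # binomial-ML sampling error at 100 trials/level
        assert fit.beta == pytest.approx(beta, abs=1.0)
        assert fit.f_half == pytest.approx(f_half, abs=0.06)
        assert np.isfinite(fit.f_thresh)

    def test_balanced_data_flagged(self):
        f = np.linspace(0, 1, 6)
        fit = fit_logistic(f, np.full(6, 50), np.full(6, 100))
        assert fit.degenerate

    @pytest.mark.parametrize("k", [0, 100])
    def test_all_silent_or_saturated_flagged(self, k):
        f = np.linspace(0, 1, 6)
        fit = fit_logistic(f, np.full(6, k), np.full(6, 100))
        assert fit.degenerate

    def test_perfect_step_capped(self):
        f = np.linspace(0, 1, 8)
        k = np.where(f > 0.5, 100, 0)
        fit = fit_logistic(f, k, np.full(8, 100))
        assert fit.separated
        assert fit.beta <= 1e4

    def test_rejects_single_level(self):
        with pytest.raises(ValueError):
            fit_logistic([0.5, 0.5], [1, 2], [10, 10])
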