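"""Likelihood fits, Akaike comparison, G-test, and log-binning."""

import numpy as np
import pytest
from scipy import integrate

from forage import (
    compare_models,
    fit_all,
    fit_exponential,
    fit_exponential_bounded,
    fit_powerlaw,
    fit_powerlaw_bounded,
    g_test,
    log_bin_slope,
)
from forage.distributions import (
    ParetoTail,
    ShiftedExponential,
    TruncatedExponential,
    TruncatedPareto,
)
from forage.errors import FitError, InsufficientDataError
from forage.heavytail_fit import g_statistic


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(7)


class TestClosedForms:
    def test_mu_two_on_log_one_sample(self):
        # sum(ln(x/a)) = n exactly when every x = a*e, so mu = 2
        fit = fit_powerlaw(np.full(50, np.e), a=1.0)
        assert fit.params["mu"] == pytest.approx(2.0, abs=1e-12)

    def test_mu_on_log_two_sample(self):
        fit = fit_powerlaw(np.full(50, np.e**2), a=1.0)
        assert fit.params["mu"] == pytest.approx(1.5, abs=1e-12)

    def test_exponential_rate(self):
        x = np.array([1.0, 3.0])  # mean 2, a = 1 -> lam = 1
        assert fit_exponential(x, a=1.0).params["lam"] == pytest.approx(1.0)

    def test_divergence_errors(self):
        with pytest.raises(FitError):
            fit_powerlaw(np.full(10, 2.0), a=2.0)
        with pytest.raises(FitError):
            fit_exponential(np.full(10, 2.0), a=2.0)
        with pytest.raises(ValueError):
            fit_powerlaw([0.5, 2.0, 3.0], a=1.0)

    def test_aic_identity(self):
        fit = fit_powerlaw(np.array([2.0, 3.0, 5.0]), a=1.0)
        assert fit.AIC == pytest.approx(-2 * fit.logL + 2 * fit.k)


class TestParameterRecovery:
    def test_powerlaw(self, rng):
        x = ParetoTail(2.5, 1.0).rvs(100_000, rng)
        assert fit_powerlaw(x, a=1.0).params["mu"] == pytest.approx(2.5, abs=0.02)

    def test_powerlaw_bounded(self, rng):
        x = TruncatedPareto(1.2, 1.0, 100.0).rvs(20_000, rng)
        fit = fit_powerlaw_bounded(x, a=1.0, b=100.0)
        assert fit.params["mu"] == pytest.approx(1.2, abs=0.05)

    def test_bounded_uniform_gives_mu_zero(self, rng):
        # uniform on [a, b] is the truncated power law with mu = 0
        x = rng.uniform(1.0, 100.0, 20_000)
        fit = fit_powerlaw_bounded(x, a=1.0, b=100.0)
        assert fit.params["mu"] == pytest.approx(0.0, abs=0.05)

    def test_exponential(self, rng):
        x = ShiftedExponential(0.5, 1.0).rvs(10_000, rng)
        assert fit_exponential(x, a=1.0).params["lam"] == pytest.approx(0.5, abs=0.02)

    def test_bounded_exponential(self, rng):
        x = TruncatedExponential(0.05, 1.0, 110.0).rvs(20_000, rng)
        fit = fit_exponential_bounded(x, a=1.0, b=110.0)
        assert fit.params["lam"] == pytest.approx(0.05, abs=0.005)

    def test_plb_matches_grid_search_oracle(self, rng):
        """Numerical MLE agrees with a brute-force likelihood grid."""
        x = TruncatedPareto(1.7, 1.0, 50.0).rvs(2_000, rng)
        n, slog = len(x), np.sum(np.log(x))

        def loglik(mu):
            if abs(mu - 1) < 1e-12:
                logc = -np.log(np.log(50.0))
            else:
                logc = np.log(abs(mu - 1)) - np.log(abs(1.0 - 50.0 ** (1 - mu)))
            return n * logc - mu * slog

        grid = np.linspace(-5, 5, 200_001)
        mu_grid = grid[np.argmax([loglik(m) for m in grid])]
        fit = fit_powerlaw_bounded(x, a=1.0, b=50.0)
        assert fit.params["mu"] == pytest.approx(mu_grid, abs=1e-4)


class TestLimitEquivalence:
    def test_plb_to_pl(self, rng):
        x = ParetoTail(2.0, 1.0).rvs(50_000, rng)
        mu_b = fit_powerlaw_bounded(x, b=1e6 * x.max()).params["mu"]
        mu_u = fit_powerlaw(x).params["mu"]
        assert mu_b == pytest.approx(mu_u, abs=1e-3)

    def test_expb_to_exp(self, rng):
        x = ShiftedExponential(0.5, 1.0).rvs(10_000, rng)
        lam_b = fit_exponential_bounded(x, b=1e6 * x.max()).params["lam"]
        lam_u = fit_exponential(x).params["lam"]
        assert lam_b == pytest.approx(lam_u, abs=1e-4)


class TestDensityNormalization:
    @pytest.mark.parametrize(
        "dist, support",
        [
            (ParetoTail(2.2, 1.0), (1.0, np.inf)),
            (TruncatedPareto(1.2, 1.0, 110.0), (1.0, 110.0)),
            (TruncatedPareto(1.0, 1.0, 110.0), (1.0, 110.0)),
            (TruncatedPareto(-0.5, 2.0, 50.0), (2.0, 50.0)),
            (ShiftedExponential(0.3, 1.0), (1.0, np.inf)),
            (TruncatedExponential(0.05, 1.0, 110.0), (1.0, 110.0)),
            (TruncatedExponential(-0.02, 1.0, 110.0), (1.0, 110.0)),
        ],
    )
    def test_pdf_integrates_to_one(self, dist, support):
        total, _ = integrate.quad(lambda x: float(dist.pdf(x)), *support)
        assert total == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize(
        "dist",
        [
            TruncatedPareto(1.5, 1.0, 110.0),
            TruncatedExponential(0.1, 1.0, 110.0),
            ParetoTail(2.0, 1.0),
            ShiftedExponential(0.5, 1.0),
        ],
    )
    def test_ppf_inverts_cdf(self, dist):
        q = np.linspace(0.01, 0.99, 25)
        np.testing.assert_allclose(dist.cdf(dist.ppf(q)), q, atol=1e-9)


class TestCompareModels:
    def test_symmetric_pair(self, rng):
        x = TruncatedPareto(2.0, 1.0, 110.0).rvs(500, rng)
        f1 = fit_powerlaw(x, a=1.0)
        f2 = type(f1)("other", f1.params, f1.a, None, f1.logL, f1.k, f1.n)
        comp = compare_models([f1, f2])
        assert comp.weights["PL"] == pytest.approx(0.5)
        assert comp.evidence_ratios["other"] == pytest.approx(1.0)

    def test_delta_two_gives_ratio_e(self, rng):
        x = TruncatedPareto(2.0, 1.0, 110.0).rvs(500, rng)
        f1 = fit_powerlaw(x, a=1.0)
        f2 = type(f1)("worse", f1.params, f1.a, None, f1.logL - 1.0, f1.k, f1.n)
        comp = compare_models([f1, f2])
        assert comp.evidence_ratios["worse"] == pytest.approx(np.e)

    def test_weights_sum_to_one_and_best_ratio_is_one(self, rng):
        x = TruncatedPareto(1.5, 1.0, 110.0).rvs(2_000, rng)
        comp = compare_models(fit_all(x))
        assert sum(comp.weights.values()) == pytest.approx(1.0)
        assert comp.evidence_ratios[comp.best_model] == 1.0
        assert all(r >= 1.0 for r in comp.evidence_ratios.values())

    def test_mismatched_sizes_rejected(self, rng):
        x = TruncatedPareto(2.0, 1.0, 110.0).rvs(500, rng)
        f1 = fit_powerlaw(x, a=1.0)
        f2 = fit_powerlaw(x[:-1], a=1.0)
        with pytest.raises(ValueError, match="sample sizes"):
            compare_models([f1, f2])


class TestGTest:
    def test_hand_computed_statistic(self):
        # 2*(5 ln 0.5 + 15 ln 1.5) = 5.2325...
        assert g_statistic([5, 15], [10, 10]) == pytest.approx(5.2325, abs=1e-4)

    def test_perfect_fit_gives_zero(self):
        assert g_statistic([10, 10], [10, 10]) == 0.0

    def test_on_true_model(self, rng):
        x = TruncatedPareto(1.2, 1.0, 110.0).rvs(2_000, rng)
        fit = fit_powerlaw_bounded(x, a=1.0, b=110.0)
        gof = g_test(x, fit, n_bins=20)
        assert gof.G >= 0
        assert 0 <= gof.p_value <= 1
        assert gof.expected.min() >= 5
        assert gof.observed.sum() == len(x)

    def test_undefined_when_df_vanishes(self, rng):
        x = TruncatedPareto(1.5, 1.0, 110.0).rvs(12, rng)
        fit = fit_powerlaw_bounded(x, a=1.0, b=110.0)
        with pytest.raises(FitError):
            g_test(x, fit, n_bins=2)


class TestLogBinning:
    def test_slope_recovers_exponent(self, rng):
        x = ParetoTail(2.0, 1.0).rvs(100_000, rng)
        fit = log_bin_slope(x)
        assert fit.slope == pytest.approx(-2.0, abs=0.1)

    def test_scale_free(self, rng):
        x = ParetoTail(2.0, 1.0).rvs(20_000, rng)
        s1 = log_bin_slope(x).slope
        s2 = log_bin_slope(2.0 * x).slope
        assert s1 == pytest.approx(s2, abs=1e-9)

    def test_narrow_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            log_bin_slope(np.linspace(1.0, 1.5, 100))

    def test_bin_widths_increase(self, rng):
        x = ParetoTail(2.0, 1.0).rvs(5_000, rng)
        fit = log_bin_slope(x)
        assert (np.diff(np.diff(fit.bin_edges)) > 0).all()
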