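import numpy as np
import pytest
from scipy import integrate, optimize, stats

from pgsrange._lorentz import fit_lorentz_batch, lorentz_jacobian, lorentz_model
from pgsrange.silicon_detection import (
    OXYGEN_LINE_MEV,
    SILICON_LINE_MEV,
    DetectionConfig,
    _bounds,
    _initial_restricted,
    extract_window,
    f_critical,
    f_statistic,
    fit_restricted,
    fit_unrestricted,
    test_record as detect_record,
    test_silicon as detect_silicon,
)
from pgsrange.synthetic_data import SpectrumModel


CFG = DetectionConfig()


def _window_energies():
    centers = SpectrumModel().bin_centers()
    return centers[(centers >= 1.58) & (centers < 1.84)]


class TestWindowExtraction:
    def test_default_axis_gives_65_points(self):
        model = SpectrumModel()
        e, c = extract_window(model.bin_centers(), np.ones(model.bin_count))
        assert e.size == c.size == 65
        assert e[0] >= 1.58 and e[-1] < 1.84

    def test_degenerate_windows_rejected(self):
        model = SpectrumModel()
        with pytest.raises(ValueError, match="positive width"):
            extract_window(model.bin_centers(), np.ones(model.bin_count), (1.7, 1.7))
        with pytest.raises(ValueError, match="does not cover"):
            extract_window(np.linspace(3.0, 4.0, 100), np.ones(100), (1.58, 1.84))


class TestModelAndEngine:
    def test_jacobian_matches_finite_differences(self):
        x = _window_energies()
        theta = np.array([210.0, 800.0, 1.64, 0.02, 50.0, 1.78, 0.015])
        jac = lorentz_jacobian(x, theta[None, :])[0]
        eps = 1e-7
        for j in range(theta.size):
            up, dn = theta.copy(), theta.copy()
            up[j] += eps
            dn[j] -= eps
            fd = (lorentz_model(x, up) - lorentz_model(x, dn)) / (2 * eps)
            np.testing.assert_allclose(jac[:, j], fd, rtol=1e-4, atol=1e-6)

    def test_engine_matches_scipy_least_squares(self):
        """Independent optimizer cross-check on noisy windows."""
        x = _window_energies()
        truth = lorentz_model(x, np.array([210.0, 800.0, OXYGEN_LINE_MEV, 0.0181]))
        rng = np.random.default_rng(17)
        y = truth + 18.0 * rng.standard_normal((20, x.size))
        theta0 = _initial_restricted(x, y, CFG)
        lo, hi = _bounds(CFG, 1)
        theta, ssr, _ = fit_lorentz_batch(x, y, theta0, lo, hi)
        for i in range(20):
            ref = optimize.least_squares(
                lambda t: lorentz_model(x, t) - y[i], theta0[i], bounds=(lo, hi)
            )
            assert ssr[i] <= np.sum(ref.fun**2) * (1 + 1e-6)


class TestRestrictedFit:
    def test_noiseless_recovery(self):
        x = _window_energies()
        truth = np.array([150.0, 900.0, 1.638, 0.019])
        model = fit_restricted(x, lorentz_model(x, truth))
        np.testing.assert_allclose(model.theta(), truth, rtol=1e-5)
        assert model.ssr < 1e-6
        assert model.n_params == 4

    def test_pure_constant_gives_zero_amplitude(self):
        x = _window_energies()
        model = fit_restricted(x, np.full(x.size, 42.0))
        assert abs(model.components[0][0]) < 1e-6
        assert model.ssr < 1e-9

    def test_oxygen_mean_recovered_at_realistic_noise(self):
        x = _window_energies()
        rng = np.random.default_rng(5)
        y = lorentz_model(x, np.array([210.0, 800.0, 1.635, 0.0181]))
        y = y + 18.0 * rng.standard_normal(x.size)
        model = fit_restricted(x, y)
        amp, mean, scale = model.components[0]
        assert abs(mean - 1.635) < scale

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 6"):
            fit_restricted(np.arange(5.0), np.arange(5.0))


class TestUnrestrictedFit:
    def test_both_lines_recovered(self):
        x = _window_energies()
        truth = np.array([100.0, 700.0, 1.635, 0.018, 250.0, 1.781, 0.019])
        restricted = fit_restricted(x, lorentz_model(x, truth))
        model = fit_unrestricted(x, lorentz_model(x, truth), restricted)
        np.testing.assert_allclose(model.theta(), truth, rtol=1e-3)
        assert model.n_params == 7

    def test_zero_silicon_gives_nested_equality(self):
        x = _window_energies()
        rng = np.random.default_rng(6)
        y = lorentz_model(x, np.array([210.0, 800.0, 1.635, 0.0181]))
        y = y + 18.0 * rng.standard_normal(x.size)
        restricted = fit_restricted(x, y)
        model = fit_unrestricted(x, y, restricted)
        assert model.ssr <= restricted.ssr
        amp2 = model.components[1][0]
        assert abs(amp2) < 0.2 * abs(restricted.components[0][0])

    def test_silicon_amplitude_scales_linearly(self):
        x = _window_energies()
        base = np.array([100.0, 700.0, 1.635, 0.018, 120.0, 1.78, 0.019])
        double = base.copy()
        double[4] *= 2
        fits = []
        for truth in (base, double):
            y = lorentz_model(x, truth)
            fits.append(fit_unrestricted(x, y, fit_restricted(x, y)))
        a1 = fits[0].components[1][0]
        a2 = fits[1].components[1][0]
        assert a2 / a1 == pytest.approx(2.0, rel=1e-3)

    def test_nesting_holds_across_random_windows(self):
        x = _window_energies()
        rng = np.random.default_rng(7)
        truth = lorentz_model(x, np.array([210.0, 800.0, 1.635, 0.0181]))
        for _ in range(25):
            y = truth + 18.0 * rng.standard_normal(x.size)
            r = fit_restricted(x, y)
            u = fit_unrestricted(x, y, r)
            assert u.ssr <= r.ssr


class TestFStatistic:
    def test_direct_arithmetic(self):
        assert f_statistic(100.0, 100.0, 3, 58) == 0.0
        assert f_statistic(130.0, 100.0, 3, 58) == pytest.approx(5.8)

    def test_degrees_of_freedom_bookkeeping(self):
        assert CFG.df_ur(65) == 58
        printed = DetectionConfig(df_convention="printed")
        assert printed.df_ur(65) == 49

    def test_clamping_and_sentinels(self):
        with pytest.warns(UserWarning, match="nesting"):
            assert f_statistic(90.0, 100.0, 3, 58) == 0.0
        with pytest.warns(UserWarning, match="zero"):
            assert f_statistic(1.0, 0.0, 3, 58) == np.inf
        with pytest.raises(ValueError):
            f_statistic(1.0, 1.0, 0, 58)


class TestFCritical:
    def test_median_below_mean(self):
        med = f_critical(0.5, 3, 58)
        mean = 58 / 56  # F mean d2/(d2-2)
        assert med < mean

    def test_matches_numerical_cdf_inversion(self):
        """Quadrature + bisection oracle, independent of scipy.stats.f.ppf."""
        q, d2, alpha = 3, 58, 0.05

        def cdf(z):
            val, _ = integrate.quad(lambda t: stats.f(q, d2).pdf(t), 0, z)
            return val

        lo, hi = 0.0, 100.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if cdf(mid) < 1 - alpha:
                lo = mid
            else:
                hi = mid
        assert f_critical(alpha, q, d2) == pytest.approx(0.5 * (lo + hi), abs=1e-6)

    def test_monotone_in_alpha(self):
        values = [f_critical(a, 3, 58) for a in (0.1, 0.01, 1e-3, 1e-4)]
        assert values == sorted(values)
        with pytest.raises(ValueError):
            f_critical(0.0, 3, 58)


class TestDetection:
    def test_silicon_rich_record_rejects(self, deep_erb_record):
        result = detect_record(deep_erb_record, "BGO")
        assert result.reject
        assert result.n == 65 and result.df_ur == 58 and result.q == 3
        assert result.ssr_ur <= result.ssr_r

    def test_prostate_record_does_not_reject(self, prostate_record):
        result = detect_record(prostate_record, "BGO")
        assert not result.reject

    def test_suppressed_layer_outperforms_raw(self, runs_by_dend):
        # stronger background rejection -> larger F at equal line
        # content; clearest at weak signal, so average a few replicates
        # of the balloon-entry run
        from pgsrange.synthetic_data import simulate_spectrum_record

        f_all, f_raw = [], []
        for seed in range(5):
            rec = simulate_spectrum_record(runs_by_dend[4.4], seed=seed)
            f_all.append(detect_record(rec, "All").f_value)
            f_raw.append(detect_record(rec, "Raw").f_value)
        assert np.mean(f_all) > np.mean(f_raw)

    def test_power_is_monotone_in_silicon_amplitude(self):
        x = _window_energies()
        rng = np.random.default_rng(23)
        reps = 400
        crit = f_critical(1e-4, 3, 58)
        rates = []
        for amp in (0.0, 30.0, 60.0, 90.0, 120.0):
            truth = lorentz_model(
                x, np.array([210.0, 800.0, 1.635, 0.0181, amp, 1.78, 0.0177])
            )
            y = truth + 18.0 * rng.standard_normal((reps, x.size))
            th0 = _initial_restricted(x, y, CFG)
            lo_r, hi_r = _bounds(CFG, 1)
            th_r, ssr_r, _ = fit_lorentz_batch(x, y, th0, lo_r, hi_r)
            th0u = np.concatenate(
                [th_r, np.zeros((reps, 1)), np.full((reps, 1), SILICON_LINE_MEV),
                 th_r[:, 3:4]],
                axis=1,
            )
            lo_u, hi_u = _bounds(CFG, 2)
            _, ssr_u, _ = fit_lorentz_batch(x, y, th0u, lo_u, hi_u)
            f = (np.maximum(ssr_r - ssr_u, 0.0) / 3) / (ssr_u / 58)
            rates.append((f > crit).mean())
        sd = np.sqrt(0.25 / reps)
        assert all(b >= a - 3 * sd for a, b in zip(rates, rates[1:]))
        assert rates[0] < 0.05 and rates[-1] > 0.95
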