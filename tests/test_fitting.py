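import numpy as np
import pytest
from scipy.integrate import quad

from bubblerelax import (CorrelationSeries, StretchedExponentialModel,
                         amplitude_linear_fit, bootstrap_uncertainty,
                         fit_stretched_exponential, format_uncertainty,
                         integrated_relaxation_time, select_fit_start,
                         tau_average, width_trend_fit)
from bubblerelax.fitting import TrendFit, kww
from bubblerelax.synthetic import synth_kww_ensemble

TRUE = (0.002, 1.0, 0.8, 0.00185)  # (A, tau_ns, beta, chi)


def noiseless_series(true=TRUE, t_end_ns=20.0):
    fx = synth_kww_ensemble(true, n_runs=2, noise_scale=0.0, seed=0, t_end_ns=t_end_ns)
    s = fx.series()
    # zero sem: the fit falls back to unweighted least squares
    return s


class TestTauAverage:
    def test_known_values(self):
        assert tau_average(1.0, 1.0) == pytest.approx(1.0)  # Gamma(1) = 1
        assert tau_average(1.0, 0.5) == pytest.approx(2.0)  # Gamma(2)/0.5
        assert tau_average(1.0, 2.0) == pytest.approx(np.sqrt(np.pi) / 2)

    def test_matches_integral_of_stretched_exponential(self):
        # tau_av is by definition the area under exp(-(t/tau)^beta)
        rng = np.random.default_rng(21)
        for _ in range(20):
            tau = rng.uniform(0.1, 5.0)
            beta = rng.uniform(0.3, 1.8)
            integral, _ = quad(lambda t: np.exp(-((t / tau) ** beta)), 0, np.inf, limit=200)
            assert tau_average(tau, beta) == pytest.approx(integral, rel=1e-8)

    def test_monotone_in_tau(self):
        taus = np.linspace(0.1, 5, 20)
        vals = [tau_average(t, 0.7) for t in taus]
        assert np.all(np.diff(vals) > 0)

    def test_invalid_beta_rejected(self):
        with pytest.raises(ValueError):
            tau_average(1.0, 0.0)


class TestIntegratedRelaxationTime:
    def test_matches_truncated_integral_of_kww(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            a0, tau, beta, chi = 0.01, rng.uniform(0.3, 2.0), rng.uniform(0.5, 1.5), 0.002
            t = np.linspace(0.0, 20.0, 40001)  # ns
            s = CorrelationSeries(t * 1e3, kww(t, a0, tau, beta, chi),
                                  np.zeros_like(t), chi, "energy", 2)
            truncated, _ = quad(lambda u: np.exp(-((u / tau) ** beta)), 0, 20.0, limit=200)
            assert integrated_relaxation_time(s) == pytest.approx(truncated, rel=1e-4)

    def test_equals_tau_av_when_tail_is_negligible(self):
        t = np.linspace(0.0, 50.0, 100001)
        s = CorrelationSeries(t * 1e3, kww(t, 0.01, 1.0, 0.8, 0.0),
                              np.zeros_like(t), 0.0, "energy", 2)
        assert integrated_relaxation_time(s) == pytest.approx(tau_average(1.0, 0.8), rel=1e-3)

    def test_no_initial_excess_rejected(self):
        t = np.linspace(0.0, 1.0, 11)
        s = CorrelationSeries(t * 1e3, np.full_like(t, 0.5), np.zeros_like(t),
                              0.5, "energy", 2)
        with pytest.raises(ValueError):
            integrated_relaxation_time(s)


class TestStretchedExponentialFit:
    def test_exact_recovery_from_noiseless_curve(self):
        fit = fit_stretched_exponential(noiseless_series(), t_start=0.0)
        assert fit.A == pytest.approx(TRUE[0], rel=1e-6)
        assert fit.tau == pytest.approx(TRUE[1], rel=1e-6)
        assert fit.beta == pytest.approx(TRUE[2], rel=1e-6)
        assert fit.chi == TRUE[3]

    def test_pure_exponential_nested_case(self):
        s = noiseless_series(true=(0.01, 2.0, 1.0, 0.001))
        fit = fit_stretched_exponential(s, t_start=0.0)
        assert abs(fit.beta - 1.0) < 0.01
        assert fit.tau_av == pytest.approx(fit.tau, rel=1e-6)

    def test_fitted_curve_reaches_chi_with_the_data(self):
        s = noiseless_series()
        fit = fit_stretched_exponential(s, t_start=0.0)
        tail = s.times[-10:] * 1e-3
        assert fit.predict(tail) == pytest.approx(s.mean[-10:], abs=1e-9)

    def test_t_start_beyond_data_raises(self):
        with pytest.raises(ValueError, match="t_start"):
            fit_stretched_exponential(noiseless_series(), t_start=1e4)

    def test_summary_mentions_parameters(self):
        fit = fit_stretched_exponential(noiseless_series(), t_start=0.0)
        text = fit.summary()
        assert "tau_av" in text and "chi (fixed)" in text


class TestSelectFitStart:
    def test_strictly_decreasing_starts_at_first_point(self):
        s = noiseless_series()
        assert select_fit_start(s) == s.times[0] * 1e-3

    def test_crossover_after_damped_oscillations(self):
        # oscillatory stage dying out at ~20 ps, then a KWW decay
        times = np.concatenate([[0.0], np.geomspace(0.01, 2e4, 400)])  # ps
        t_ns = times * 1e-3
        osc = 0.004 * np.exp(-times / 8.0) * np.cos(2 * np.pi * times / 2.5)
        curve = kww(t_ns, *TRUE) + osc
        s = CorrelationSeries(times, curve, np.full_like(times, 1e-7), TRUE[3], "energy", 100)
        t_start = select_fit_start(s)
        assert 0.015 <= t_start <= 0.06  # just past the oscillatory stage (ns)

    def test_no_monotone_tail_raises(self):
        times = np.concatenate([[0.0], np.geomspace(0.01, 100.0, 100)])
        rising = np.linspace(1.0, 2.0, times.size)
        s = CorrelationSeries(times, rising, np.full_like(times, 1e-9), 0.0, "energy", 10)
        with pytest.raises(ValueError, match="monotone"):
            select_fit_start(s)


class TestParameterRecovery:
    def test_beta_recovered_from_noisy_ensemble(self):
        fx = synth_kww_ensemble(TRUE, n_runs=500, noise_scale=2e-4, seed=42)
        fit = StretchedExponentialModel(fx.series(), t_start=0.0).fit()
        assert abs(fit.beta - TRUE[2]) < 0.05

    def test_tau_av_median_error_under_five_percent(self):
        # scan a parameter grid at 200 runs with realistic correlated noise
        errs = []
        for i, (a0, tau, beta) in enumerate([(0.002, 0.5, 0.6), (0.002, 1.0, 0.8),
                                             (0.005, 2.0, 1.0), (0.001, 1.5, 0.7)]):
            true = (a0, tau, beta, 0.00185)
            fx = synth_kww_ensemble(true, n_runs=200, noise_scale=2e-4, seed=100 + i)
            fit = StretchedExponentialModel(fx.series(), t_start=0.0).fit()
            errs.append(abs(fit.tau_av - tau_average(tau, beta)) / tau_average(tau, beta))
        assert np.median(errs) < 0.05


class TestBootstrap:
    def test_zero_noise_gives_vanishing_uncertainty(self):
        fx = synth_kww_ensemble(TRUE, n_runs=20, noise_scale=0.0, seed=1)
        out = bootstrap_uncertainty(fx.curves, times=fx.times, chi=TRUE[3],
                                    t_start=0.0, n_boot=100, seed=5)
        assert out["tau_av"] < 1e-9 and out["beta"] < 1e-9

    def test_reproducible_under_seed(self):
        fx = synth_kww_ensemble(TRUE, n_runs=50, noise_scale=2e-4, seed=2)
        kw = dict(times=fx.times, chi=TRUE[3], t_start=0.0, n_boot=100)
        a = bootstrap_uncertainty(fx.curves, seed=9, **kw)
        b = bootstrap_uncertainty(fx.curves, seed=9, **kw)
        assert a == b

    def test_minimum_resamples_enforced(self):
        fx = synth_kww_ensemble(TRUE, n_runs=10, noise_scale=0.0, seed=3)
        with pytest.raises(ValueError):
            bootstrap_uncertainty(fx.curves, times=fx.times, chi=TRUE[3], n_boot=10)

    def test_consistent_with_generative_scatter(self):
        # fit many independent ensembles: the spread of their tau_av is the
        # "true" uncertainty the bootstrap should estimate
        tau_avs = []
        for i in range(12):
            fx = synth_kww_ensemble(TRUE, n_runs=100, noise_scale=3e-4, seed=300 + i)
            tau_avs.append(StretchedExponentialModel(fx.series(), t_start=0.0).fit().tau_av)
        generative = np.std(tau_avs, ddof=1)
        fx = synth_kww_ensemble(TRUE, n_runs=100, noise_scale=3e-4, seed=300)
        boot = bootstrap_uncertainty(fx.curves, times=fx.times, chi=TRUE[3],
                                     t_start=0.0, n_boot=150, seed=1)
        assert boot["tau_av"] == pytest.approx(generative, rel=0.5)


class TestTrendFits:
    def test_exact_line_recovered(self):
        pts = [(h, 1.0 + 0.5 * h, 0.01) for h in (2.5, 3.5, 4.5, 5.5)]
        tf = amplitude_linear_fit(pts, width=9)
        assert tf.tau0 == pytest.approx(1.0, abs=1e-10)
        assert tf.alpha == pytest.approx(0.5, abs=1e-10)

    def test_constant_tau_av_gives_zero_slope(self):
        pts = [(h, 2.0, 0.01) for h in (2.5, 3.5, 4.5)]
        assert amplitude_linear_fit(pts, width=9).alpha == pytest.approx(0.0, abs=1e-10)

    def test_weighted_equals_unweighted_for_equal_sigmas(self):
        rng = np.random.default_rng(8)
        pts_w = [(h, 1 + 0.3 * h + rng.normal(0, 0.05), 0.2) for h in (2.5, 3.0, 4.0, 5.0)]
        pts_u = [(h, t, None) for h, t, _ in pts_w]
        a = amplitude_linear_fit(pts_w, width=11)
        b = amplitude_linear_fit(pts_u, width=11)
        assert a.alpha == pytest.approx(b.alpha, rel=1e-10)
        assert a.tau0 == pytest.approx(b.tau0, rel=1e-10)

    def test_degenerate_amplitudes_rejected(self):
        with pytest.raises(ValueError):
            amplitude_linear_fit([(3.0, 1.0, 0.1)] * 4, width=9)

    def test_width_lines_recover_exact_synthetic_trend(self):
        # tau_av(w, h) = (0.07 w - 0.6) + 0.24 h exactly
        trends = [TrendFit(width=w, tau0=0.07 * w - 0.6, alpha=0.24,
                           tau0_err=0.01, alpha_err=0.01)
                  for w in (9, 11, 13, 15, 17, 19)]
        tau0_line, alpha_line = width_trend_fit(trends)
        assert tau0_line.slope == pytest.approx(0.07, abs=1e-10)
        assert tau0_line.intercept == pytest.approx(-0.6, abs=1e-10)
        assert alpha_line.slope == pytest.approx(0.0, abs=1e-10)
        assert alpha_line.intercept == pytest.approx(0.24, abs=1e-10)

    def test_too_few_widths_rejected(self):
        with pytest.raises(ValueError):
            width_trend_fit([TrendFit(9, 1, 0.2, 0.1, 0.1), TrendFit(11, 1.2, 0.2, 0.1, 0.1)])


class TestFormatting:
    @pytest.mark.parametrize("value,err,expected", [
        (0.238, 0.082, "0.24(8)"),
        (23.0, 5.0, "23(5)"),
        (-120.0, 70.0, "-120(70)"),
        (0.07, 0.02, "0.07(2)"),
        (0.0, 0.006, "0.000(6)"),
    ])
    def test_parenthesis_notation(self, value, err, expected):
        assert format_uncertainty(value, err) == expected
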