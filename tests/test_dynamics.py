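import numpy as np
import pytest

from bubblerelax import (ChainState, IntegratorConfig, evolve, initial_state,
                         kinetic_temperature, log_time_grid, relative_energy_drift,
                         symplectic_step, total_energy)
from bubblerelax import units
from bubblerelax.dynamics import rk4_advance
from bubblerelax.synthetic import dispersion_omega, phonon_fixture
from bubblerelax._kernels import SRKN6B_A, SRKN6B_B


def _dominant_frequency(times_ps, signal):
    """Oscillation frequency (1/ps): FFT peak refined by a cosine fit."""
    from scipy.optimize import curve_fit

    sig = signal - signal.mean()
    spec = np.abs(np.fft.rfft(sig))
    freqs = np.fft.rfftfreq(sig.size, d=times_ps[1] - times_ps[0])
    f0 = freqs[spec.argmax()]
    amp0 = float(np.abs(sig).max())
    popt, _ = curve_fit(lambda t, a, f, ph, c: a * np.cos(2 * np.pi * f * t + ph) + c,
                        times_ps, signal, p0=[amp0, f0, 0.0, signal.mean()])
    return abs(popt[1])


class TestScheme:
    def test_coefficients_are_consistent(self):
        assert np.sum(SRKN6B_B) * 2 - SRKN6B_B[-1] == pytest.approx(1.0, abs=1e-15)
        assert 2 * np.sum(SRKN6B_A) == pytest.approx(1.0, abs=1e-15)

    def test_rest_state_is_fixed_point(self, at_params):
        st = ChainState(np.zeros(8), np.zeros(8))
        new = symplectic_step(st, at_params, dt=10.0)
        assert np.all(new.y == 0.0) and np.all(new.p == 0.0)

    def test_fourth_order_convergence(self, at_params):
        rng = np.random.default_rng(5)
        st = ChainState(rng.normal(0, 0.2, 16), rng.normal(0, 2, 16))
        fine, _ = evolve(st, at_params, IntegratorConfig(dt=0.25), duration=0.002)
        errs = []
        for dt in (16.0, 8.0, 4.0):
            cur = st.copy()
            for _ in range(int(round(2000.0 / dt))):
                cur = symplectic_step(cur, at_params, dt)
            errs.append(np.abs(cur.y - fine.y).max())
        # halving dt must shrink the error by >= 2^4
        assert errs[0] / errs[1] > 14 and errs[1] / errs[2] > 14

    def test_blowup_raises_with_diagnostic(self, at_params):
        st = ChainState(np.full(8, 0.1), np.full(8, 1.0))
        with pytest.raises(FloatingPointError, match="timestep"):
            symplectic_step(st, at_params, dt=1e7)

    def test_time_reversal(self, at_params, thermal_at_state):
        cfg = IntegratorConfig()
        fwd, _ = evolve(thermal_at_state, at_params, cfg, duration=0.01)
        back, _ = evolve(ChainState(fwd.y, -fwd.p), at_params, cfg, duration=0.01)
        assert np.abs(back.y - thermal_at_state.y).max() < 1e-6


class TestPhonons:
    def test_harmonic_limit_frequency(self, at_params):
        # uniform small-amplitude mode: omega = a sqrt(2D/m)
        state, omega = phonon_fixture(at_params, q=0.0, amplitude=1e-3, n_sites=16)
        assert omega == pytest.approx(at_params.a * np.sqrt(2 * at_params.D / at_params.mass))
        # grid spacing = one 2 fs step, so the sampling stays uniform
        grid = np.linspace(0.0, 4.0, 2001)
        _, rec = evolve(state, at_params, IntegratorConfig(dt=2.0), duration=4e-3,
                        record_times=grid, window=(1, 1))
        f_meas = _dominant_frequency(rec.times, rec.y_window[:, 0])
        f_pred = omega / (2 * np.pi) / units.INTERNAL_TO_PS
        assert f_meas == pytest.approx(f_pred, rel=1e-3)

    @pytest.mark.parametrize("k_mode", [4, 8])  # q = pi/2 and pi on N=16
    def test_dispersion_relation(self, at_params, k_mode):
        n = 16
        q = 2 * np.pi * k_mode / n
        state, omega = phonon_fixture(at_params, q=q, amplitude=1e-3, n_sites=n)
        grid = np.linspace(0.0, 4.0, 4001)
        _, rec = evolve(state, at_params, IntegratorConfig(dt=1.0), duration=4e-3,
                        record_times=grid, window=(1, 1))
        f_meas = _dominant_frequency(rec.times, rec.y_window[:, 0])
        f_pred = omega / (2 * np.pi) / units.INTERNAL_TO_PS
        assert f_meas == pytest.approx(f_pred, rel=1e-3)

    def test_dispersion_monotone_up_to_zone_edge(self, at_params):
        qs = np.linspace(0, np.pi, 30)
        om = [dispersion_omega(at_params, q) for q in qs]
        assert np.all(np.diff(om) > 0)


class TestConservation:
    def test_symplectic_drift_bounded_vs_rk4_control(self, at_params):
        rng = np.random.default_rng(9)
        st = initial_state(16, 0.043, seed=9, mass=at_params)
        st, _ = evolve(st, at_params, IntegratorConfig(), duration=0.02)
        h0 = total_energy(st, at_params)
        grid = np.linspace(0, 400.0, 41)
        _, rec = evolve(st, at_params, IntegratorConfig(dt=10.0), duration=0.4,
                        record_times=grid)
        srkn_drift = relative_energy_drift(rec)
        assert srkn_drift <= 1e-7
        # same-order non-symplectic control at the same timestep drifts
        # monotonically and ends orders of magnitude worse
        rk_drifts = []
        cur = st
        for _ in range(4):
            cur = rk4_advance(cur, at_params, dt_fs=10.0, n_steps=10000)
            rk_drifts.append(abs(total_energy(cur, at_params) - h0) / h0)
        assert np.all(np.diff(rk_drifts) > 0)
        assert rk_drifts[-1] > 100 * srkn_drift

    def test_centre_of_mass_momentum_not_conserved(self, at_params, thermal_at_state):
        # the on-site Morse term breaks translation invariance, so the total
        # momentum must fluctuate rather than stay constant
        p0 = thermal_at_state.p.sum()
        moved, _ = evolve(thermal_at_state, at_params, IntegratorConfig(), duration=0.02)
        assert abs(moved.p.sum() - p0) > 1e-6


class TestDiagnostics:
    def test_kinetic_temperature_definitions(self, at_params):
        n = 50
        assert kinetic_temperature(ChainState(np.zeros(n), np.zeros(n)), at_params) == 0.0
        target = 310.0
        p = np.full(n, np.sqrt(at_params.mass * units.KB_EV * target))
        st = ChainState(np.zeros(n), p)
        assert kinetic_temperature(st, at_params) == pytest.approx(target, rel=1e-12)
        with pytest.raises(ValueError):
            kinetic_temperature([], at_params)

    def test_relative_energy_drift_arithmetic(self):
        class R:  # noqa: D401 - tiny stand-in carrying only H_series
            pass

        assert relative_energy_drift(np.array([2.0, 2.0, 2.0])) == 0.0
        assert relative_energy_drift(np.array([1.0, 1.0 + 1e-8])) == pytest.approx(1e-8)
        with pytest.raises(ValueError):
            relative_energy_drift(np.array([0.0, 1.0]))

    def test_log_grid_properties(self):
        g = log_time_grid(1e4, points_per_decade=50)
        assert g[0] == 0.0 and g[-1] == pytest.approx(1e4)
        assert np.all(np.diff(g) > 0)
        # ~50 points per decade over 6 decades
        assert 250 <= g.size <= 350

    def test_evolve_zero_duration_is_identity(self, at_params, thermal_at_state):
        out, rec = evolve(thermal_at_state, at_params, IntegratorConfig(), duration=0.0)
        assert np.array_equal(out.y, thermal_at_state.y)
        assert len(rec) == 0

    def test_recorded_times_snap_to_steps_and_increase(self, at_params, thermal_at_state):
        grid = [0.0, 0.013, 0.5, 3.33, 9.99]
        _, rec = evolve(thermal_at_state, at_params, IntegratorConfig(), duration=0.01,
                        record_times=grid, window=(140, 160))
        assert np.all(np.diff(rec.times) > 0)
        assert rec.y_window.shape == (len(rec), 21)
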