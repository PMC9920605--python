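"""Synthetic inputs with known ground truth.

Three generators make the analysis layers testable without (or with very
little) molecular dynamics:

* KWW ensembles -- noisy stretched-exponential decay curves with known
  (A, tau, beta, chi), mimicking the per-realisation autocorrelation data.
  The per-run noise is AR(1)-correlated along the time grid (lag-1
  correlation 0.5), because real per-run autocorrelation curves are smooth:
  independent noise would make the fitting problem unrealistically easy.
* phonon fixtures -- small-amplitude plane waves whose oscillation frequency
  follows the linearised dispersion relation
  omega(q)^2 = (2 D a^2 + 2 K (1 + rho) (1 - cos q)) / m.
* mini ensembles -- the full bubble protocol at reduced thermalisation and
  run length, for end-to-end smoke checks.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .correlation import CorrelationSeries, ensemble_stats
from .dynamics import IntegratorConfig
from .fitting import kww
from .model import ChainState, ModelParameters
from .protocol import BubbleSpec, RealisationResult, run_realisation

__all__ = ["KWWFixture", "synth_kww_ensemble", "phonon_fixture", "dispersion_omega", "mini_ensemble"]


@dataclass
class KWWFixture:
    """Ensemble of noisy KWW curves with known generating parameters."""

    true_params: tuple  # (A, tau, beta, chi), tau in ns
    times: np.ndarray  # ps
    curves: np.ndarray  # (n_runs, n_times)
    n_runs: int

    def series(self) -> CorrelationSeries:
        """Ensemble mean/SEM with chi fixed at the generating truth."""
        return ensemble_stats(self.times, self.curves, self.true_params[3], "energy")


def synth_kww_ensemble(true_params: tuple, n_runs: int, noise_scale: float, seed,
                       t_end_ns: float = 20.0, t_min_ps: float = 0.01,
                       points_per_decade: int = 50, ar1: float = 0.5) -> KWWFixture:
    """Noisy stretched-exponential ensemble on a log time grid.

    Each run is kww(t) plus stationary AR(1) noise (lag-1 correlation
    `ar1`, marginal std `noise_scale`).  tau is in ns, the grid in ps.
    """
    A, tau, beta, chi = true_params
    if tau <= 0 or not (0 < beta <= 2):
        raise ValueError("need tau > 0 and beta in (0, 2]")
    if noise_scale < 0:
        raise ValueError("noise_scale must be non-negative")
    if not (0 <= ar1 < 1):
        raise ValueError("ar1 must lie in [0, 1)")
    n_pts = max(2, int(np.ceil(np.log10(t_end_ns * 1e3 / t_min_ps) * points_per_decade)) + 1)
    times = np.concatenate([[0.0], np.geomspace(t_min_ps, t_end_ns * 1e3, n_pts)])
    clean = kww(times * 1e-3, A, tau, beta, chi)
    rng = np.random.default_rng(seed)
    curves = np.tile(clean, (n_runs, 1))
    if noise_scale > 0:
        eps = rng.standard_normal((n_runs, times.size))
        noise = np.empty_like(eps)
        noise[:, 0] = eps[:, 0]
        c = np.sqrt(1.0 - ar1 ** 2)
        for k in range(1, times.size):
            noise[:, k] = ar1 * noise[:, k - 1] + c * eps[:, k]
        curves = curves + noise_scale * noise
    return KWWFixture(true_params=tuple(true_params), times=times, curves=curves, n_runs=n_runs)


def dispersion_omega(params: ModelParameters, q: float) -> float:
    """Angular frequency (rad per internal time unit) of the linearised mode q."""
    om2 = (2.0 * params.D * params.a ** 2
           + 2.0 * params.K * (1.0 + params.rho) * (1.0 - np.cos(q))) / params.mass
    return float(np.sqrt(om2))


def phonon_fixture(params: ModelParameters, q: float, amplitude: float,
                   n_sites: int = 32) -> tuple[ChainState, float]:
    """Standing plane wave y_n = amplitude*cos(q n), p = 0, plus its frequency.

    q must be a lattice wavenumber 2 pi k / N for the pattern to be an exact
    normal mode of the periodic chain.  Amplitudes above 0.01 Angstrom leave
    the linear regime of the Morse well (a warning is emitted).
    """
    if amplitude > 0.01:
        warnings.warn("amplitude beyond the linear regime; the dispersion "
                      "prediction degrades", RuntimeWarning, stacklevel=2)
    k = q * n_sites / (2.0 * np.pi)
    if abs(k - round(k)) > 1e-9:
        raise ValueError("q must be a multiple of 2*pi/n_sites")
    n = np.arange(n_sites)
    state = ChainState(amplitude * np.cos(q * n), np.zeros(n_sites))
    return state, dispersion_omega(params, q)


def mini_ensemble(params: ModelParameters, spec: BubbleSpec, n_runs: int, seed,
                  short_ns: float = 2.0, therm_ns: float = 0.5, n_sites: int = 300,
                  cfg: IntegratorConfig | None = None) -> list[RealisationResult]:
    """Scaled-down end-to-end ensemble (default 0.5 ns thermalisation,
    2 ns relaxation) for fast smoke checks; deterministic in `seed`."""
    if n_runs < 2:
        raise ValueError("need at least 2 runs")
    cfg = cfg or IntegratorConfig()
    ss = np.random.SeedSequence(seed)
    out = []
    for i, child in enumerate(ss.spawn(n_runs)):
        res = run_realisation(params, cfg, spec, child, post_duration=short_ns,
                              therm_duration=therm_ns, n_sites=n_sites)
        res.seed = i
        out.append(res)
    return out
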