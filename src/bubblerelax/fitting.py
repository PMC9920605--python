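"""Stretched-exponential relaxation fits and bubble-shape trend fits.

The decay stage of an ensemble autocorrelation function is described by the
Kohlrausch-Williams-Watts (KWW) form

    C(t) = A exp(-(t/tau)^beta) + chi,

where chi is *fixed* at the independently known limiting value of the
autocorrelation function and only A (pre-exponential), tau (characteristic
time) and beta (stretched exponent) are free.  A single comparable
relaxation-time scale per curve is the mean of the underlying
relaxation-time distribution,

    tau_av = Gamma(1/beta) / beta * tau,

which equals the integral of exp(-(t/tau)^beta) from 0 to infinity.

Trends of tau_av across bubble shapes are quantified by weighted straight
lines: tau_av = tau0 + alpha * h per width w, then tau0(w) and alpha(w) by
straight lines in w, composing a closed-form tau_av(w, h).

Uncertainties on the KWW parameters are bootstrap standard deviations,
resampling whole realisations with replacement and refitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy.ndimage import median_filter
from scipy.optimize import curve_fit
from scipy.special import gamma as _gamma

from .correlation import CorrelationSeries, ensemble_stats, limiting_chi, per_run_autocorrelation

__all__ = [
    "RelaxationFit",
    "TrendFit",
    "TrendLine",
    "StretchedExponentialModel",
    "fit_stretched_exponential",
    "select_fit_start",
    "tau_average",
    "integrated_relaxation_time",
    "bootstrap_uncertainty",
    "amplitude_linear_fit",
    "width_trend_fit",
    "format_uncertainty",
]


def kww(t, A, tau, beta, chi):
    """A exp(-(t/tau)^beta) + chi, t and tau in the same unit."""
    t = np.asarray(t, dtype=np.float64)
    return A * np.exp(-np.power(t / tau, beta)) + chi


def tau_average(fit_or_tau, beta: float | None = None) -> float:
    """Mean relaxation time tau_av = Gamma(1/beta)/beta * tau (same unit as tau)."""
    if beta is None:
        tau, beta = fit_or_tau.tau, fit_or_tau.beta
    else:
        tau = fit_or_tau
    if beta <= 0:
        raise ValueError("beta must be positive")
    return float(_gamma(1.0 / beta) / beta * tau)


def integrated_relaxation_time(series: CorrelationSeries) -> float:
    """Model-free relaxation scale: trapezoidal integral of the normalised
    excess correlation over the recorded window (ns),

        tau_int = integral_0^T [C(t) - chi] dt / [C(0) - chi].

    For a KWW decay whose tail is negligible beyond the window this equals
    tau_av; unlike the fitted tau_av it is bounded by the window length and
    has finite variance at small ensemble sizes, at the price of missing
    any tail mass beyond T.  Requires a positive initial excess C(0) > chi.
    """
    t_ns = np.asarray(series.times, dtype=np.float64) / 1e3
    excess = np.asarray(series.mean, dtype=np.float64) - series.chi
    if excess[0] <= 0:
        raise ValueError("C(0) does not exceed the limiting value chi")
    return float(np.trapezoid(excess, t_ns) / excess[0])


@dataclass
class RelaxationFit:
    """Fitted KWW parameters for one autocorrelation curve (times in ns).

    `uncertainties` holds bootstrap standard deviations when
    :func:`bootstrap_uncertainty` has been run; `bse` are the
    covariance-based standard errors of the weighted least-squares fit.
    """

    A: float
    tau: float
    beta: float
    chi: float
    t_start: float
    tau_av: float = field(init=False)
    bse: dict = field(default_factory=dict)
    uncertainties: dict = field(default_factory=dict)
    n_points: int = 0
    kind: str = "energy"

    def __post_init__(self) -> None:
        if not (self.tau > 0 and 0 < self.beta <= 2):
            raise ValueError("fit outside the physical domain (tau > 0, 0 < beta <= 2)")
        self.tau_av = tau_average(self.tau, self.beta)

    def predict(self, times_ns) -> np.ndarray:
        return kww(np.asarray(times_ns), self.A, self.tau, self.beta, self.chi)

    def summary(self) -> str:
        unit = "eV^2" if self.kind == "energy" else "A^2"
        lines = [
            "Stretched-exponential relaxation fit",
            "=" * 52,
            f"{'kind':<22}{self.kind} autocorrelation",
            f"{'fit window start':<22}{self.t_start:.4g} ns",
            f"{'points fitted':<22}{self.n_points}",
            f"{'chi (fixed)':<22}{self.chi:.6g} {unit}",
            "-" * 52,
        ]
        for name, val, u in (("A", self.A, unit), ("tau", self.tau, "ns"),
                             ("beta", self.beta, ""), ("tau_av", self.tau_av, "ns")):
            err = self.uncertainties.get(name, self.bse.get(name))
            if err is not None and np.isfinite(err) and err > 0:
                lines.append(f"{name:<8}{format_uncertainty(val, err):>18}  {u}")
            else:
                lines.append(f"{name:<8}{val:>18.6g}  {u}")
        lines.append("=" * 52)
        return "\n".join(lines)


def select_fit_start(series: CorrelationSeries, smooth_points: int = 5,
                     rel_tol: float = 1e-3) -> float:
    """Start of the monotone rapid-decay stage, in ns.

    The ensemble mean is median-filtered over `smooth_points` grid points
    and the earliest grid time is returned after which the smoothed curve
    never rises significantly — a rise counts only if it exceeds both
    `rel_tol` of the curve's total range and the local SEM (so ensemble
    noise on the tail is not mistaken for oscillation).  Raises if no such
    time exists before the last fifth of the grid, which indicates the run
    is too short to have left the oscillatory stage.
    """
    smoothed = median_filter(series.mean, size=smooth_points, mode="nearest")
    rng = float(smoothed.max() - smoothed.min())
    if rng == 0.0:
        return float(series.times[0] * 1e-3)
    allowance = np.maximum(rel_tol * rng, 0.5 * (series.sem[1:] + series.sem[:-1]))
    rises = np.diff(smoothed) > allowance
    if not rises.any():
        return float(series.times[0] * 1e-3)
    last_rise = int(np.nonzero(rises)[0][-1]) + 1
    if last_rise >= int(0.8 * series.times.size):
        raise ValueError(
            "no monotone decay tail found: the series still rises in its last "
            "fifth; run longer simulations or set t_start explicitly"
        )
    return float(series.times[last_rise] * 1e-3)


class StretchedExponentialModel:
    """KWW relaxation model for an ensemble autocorrelation series.

    Parameters
    ----------
    series : CorrelationSeries
        Ensemble autocorrelation (times in ps) with SEM band.
    t_start : float, optional
        Start of the fit window in ns; default picked by
        :func:`select_fit_start`.
    chi : float, optional
        Fixed asymptote; defaults to the series' own limiting value.  It is
        never a free parameter.

    Points are taken as recorded on the log grid (no density re-weighting);
    weights are 1/sem^2 wherever the SEM is positive.
    """

    def __init__(self, series: CorrelationSeries, t_start: float | None = None,
                 chi: float | None = None):
        self.series = series
        self.chi = series.chi if chi is None else float(chi)
        self.t_start = select_fit_start(series) if t_start is None else float(t_start)
        t_ns = series.times * 1e-3
        mask = t_ns >= self.t_start
        if mask.sum() < 10:
            raise ValueError(
                f"only {int(mask.sum())} points at t >= {self.t_start} ns; "
                "need at least 10 (is t_start beyond the data?)"
            )
        self.t_ns = t_ns[mask]
        self.c = series.mean[mask]
        sem = series.sem[mask]
        self.sigma = sem if np.all(sem > 0) else None

    def _initial_guess(self) -> tuple[float, float, float]:
        a0 = max(self.c[0] - self.chi, 1e-12)
        drop = self.c - self.chi <= a0 / math.e
        tau0 = float(self.t_ns[np.argmax(drop)]) if drop.any() else float(np.median(self.t_ns))
        return a0, max(tau0, self.t_ns[0] if self.t_ns[0] > 0 else 1e-4), 0.7

    def fit(self, maxfev: int = 20000) -> RelaxationFit:
        p0 = self._initial_guess()
        try:
            popt, pcov = curve_fit(
                lambda t, A, tau, beta: kww(t, A, tau, beta, self.chi),
                self.t_ns, self.c, p0=p0, sigma=self.sigma,
                bounds=([0.0, 1e-12, 1e-3], [np.inf, np.inf, 2.0]),
                maxfev=maxfev,
            )
        except RuntimeError as exc:
            resid = float(np.sum((kww(self.t_ns, *p0, self.chi) - self.c) ** 2))
            raise RuntimeError(
                f"KWW fit did not converge (initial guess A={p0[0]:.3g}, "
                f"tau={p0[1]:.3g} ns, beta={p0[2]:.2g}; ssr at guess {resid:.3g})"
            ) from exc
        if not np.all(np.isfinite(popt)):
            raise RuntimeError("KWW fit returned non-finite parameters")
        perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(3, np.nan)
        return RelaxationFit(
            A=float(popt[0]), tau=float(popt[1]), beta=float(popt[2]),
            chi=self.chi, t_start=self.t_start,
            bse={"A": float(perr[0]), "tau": float(perr[1]), "beta": float(perr[2])},
            n_points=self.t_ns.size, kind=self.series.kind,
        )


def fit_stretched_exponential(series: CorrelationSeries, t_start: float | None = None,
                              chi: float | None = None) -> RelaxationFit:
    """Fit A exp(-(t/tau)^beta) + chi to the series tail (t_start in ns)."""
    return StretchedExponentialModel(series, t_start=t_start, chi=chi).fit()


def bootstrap_uncertainty(results_or_matrix, t_start: float | None = None,
                          n_boot: int = 1000, seed=0, kind: str = "energy",
                          chi: float | None = None, times: np.ndarray | None = None,
                          max_failure_fraction: float = 0.1) -> dict:
    """Bootstrap stds of (A, tau, beta, tau_av) by resampling realisations.

    Accepts either a list of RealisationResult (the autocorrelation and its
    limiting value are rebuilt for every resample) or a per-run correlation
    matrix together with `times` (ps) and a fixed `chi`.  Resampling is
    reproducible through `seed`.  Raises if more than
    `max_failure_fraction` of the refits fail to converge.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    if isinstance(results_or_matrix, np.ndarray):
        if times is None or chi is None:
            raise ValueError("matrix input requires times and a fixed chi")
        per_run = results_or_matrix
        chi_terms = None
    else:
        results = list(results_or_matrix)
        times, per_run = per_run_autocorrelation(results, kind)
        if kind == "energy":
            eps_eq = results[0].energy_per_site
            chi_terms = np.array([float(np.mean(r.e0_window)) * eps_eq for r in results])
        else:
            y_eq = float(np.mean([r.pre_insertion_mean_y for r in results]))
            chi_terms = np.array([float(np.mean(r.y0_window)) * y_eq for r in results])
    n_runs = per_run.shape[0]
    if t_start is None:
        base_chi = chi if chi_terms is None else float(np.mean(chi_terms))
        t_start = select_fit_start(ensemble_stats(times, per_run, base_chi, kind))
    rng = np.random.default_rng(seed)
    draws = {"A": [], "tau": [], "beta": [], "tau_av": []}
    failures = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n_runs, size=n_runs)
        chi_b = chi if chi_terms is None else float(np.mean(chi_terms[idx]))
        series_b = ensemble_stats(times, per_run[idx], chi_b, kind)
        try:
            fit = StretchedExponentialModel(series_b, t_start=t_start).fit()
        except (RuntimeError, ValueError):
            failures += 1
            continue
        draws["A"].append(fit.A)
        draws["tau"].append(fit.tau)
        draws["beta"].append(fit.beta)
        draws["tau_av"].append(fit.tau_av)
    if failures > max_failure_fraction * n_boot:
        raise RuntimeError(f"{failures}/{n_boot} bootstrap refits failed")
    return {k: float(np.std(v, ddof=1)) for k, v in draws.items()}


@dataclass(frozen=True)
class TrendLine:
    """One straight line y = intercept + slope * x with standard errors."""

    slope: float
    intercept: float
    slope_err: float
    intercept_err: float

    def __call__(self, x):
        return self.intercept + self.slope * np.asarray(x)


@dataclass(frozen=True)
class TrendFit:
    """tau_av = tau0 + alpha h at one bubble width (times in ns, h in Angstrom)."""

    width: int
    tau0: float
    alpha: float
    tau0_err: float
    alpha_err: float


def _weighted_line(x: np.ndarray, y: np.ndarray, yerr: np.ndarray | None) -> TrendLine:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points for a trend line")
    if np.ptp(x) == 0:
        raise ValueError("degenerate abscissa: all x values identical")
    X = sm.add_constant(x)
    if yerr is not None and np.all(np.asarray(yerr) > 0):
        res = sm.WLS(y, X, weights=1.0 / np.asarray(yerr, dtype=float) ** 2).fit()
    else:
        res = sm.OLS(y, X).fit()
    return TrendLine(slope=float(res.params[1]), intercept=float(res.params[0]),
                     slope_err=float(res.bse[1]), intercept_err=float(res.bse[0]))


def amplitude_linear_fit(points: Sequence[tuple], width: int) -> TrendFit:
    """Weighted straight line tau_av = tau0 + alpha h at fixed width.

    `points` are (h, tau_av, sigma_tau_av) triples; sigma may be None for an
    unweighted fit.  At least 3 distinct amplitudes are required.
    """
    h = np.array([p[0] for p in points], dtype=float)
    tav = np.array([p[1] for p in points], dtype=float)
    err = None
    if all(len(p) > 2 and p[2] is not None and p[2] > 0 for p in points):
        err = np.array([p[2] for p in points], dtype=float)
    line = _weighted_line(h, tav, err)
    return TrendFit(width=int(width), tau0=line.intercept, alpha=line.slope,
                    tau0_err=line.intercept_err, alpha_err=line.slope_err)


def width_trend_fit(trends: Sequence[TrendFit]) -> tuple[TrendLine, TrendLine]:
    """Straight lines tau0(w) and alpha(w) across bubble widths.

    Composes the closed-form relaxation-time surface
    tau_av(w, h) = tau0(w) + alpha(w) h.
    """
    trends = sorted(trends, key=lambda t: t.width)
    w = np.array([t.width for t in trends], dtype=float)
    tau0_line = _weighted_line(w, np.array([t.tau0 for t in trends]),
                               np.array([t.tau0_err for t in trends]) if all(t.tau0_err > 0 for t in trends) else None)
    alpha_line = _weighted_line(w, np.array([t.alpha for t in trends]),
                                np.array([t.alpha_err for t in trends]) if all(t.alpha_err > 0 for t in trends) else None)
    return tau0_line, alpha_line


def format_uncertainty(value: float, err: float) -> str:
    """Parenthesis notation: 0.238 +/- 0.082 -> '0.24(8)', 23 +/- 5 -> '23(5)'."""
    if not (np.isfinite(value) and np.isfinite(err)) or err <= 0:
        return f"{value:g}"
    exp = math.floor(math.log10(err))
    first = round(err / 10 ** exp)
    if first == 10:  # 0.096 rounds up to 0.1
        first, exp = 1, exp + 1
    if exp >= 0:
        return f"{value:.0f}({first * 10 ** exp:.0f})"
    return f"{value:.{-exp}f}({first})"
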