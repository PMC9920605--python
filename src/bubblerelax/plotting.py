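"""Plot helpers for autocorrelation curves and trend fits."""

from __future__ import annotations

import numpy as np

from .correlation import CorrelationSeries
from .fitting import RelaxationFit, TrendFit


def plot_correlation(series: CorrelationSeries, fit: RelaxationFit | None = None, ax=None):
    """Log-log autocorrelation with its SEM band, limiting value and fit."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = series.times
    pos = t > 0
    ax.fill_between(t[pos], (series.mean - series.sem)[pos], (series.mean + series.sem)[pos],
                    alpha=0.3, lw=0)
    ax.plot(t[pos], series.mean[pos], label=f"mean of {series.n_runs} runs")
    ax.axhline(series.chi, ls="--", color="k", lw=0.8, label=r"$\chi$")
    if fit is not None:
        tt = np.geomspace(max(fit.t_start * 1e3, t[pos].min()), t.max(), 200)
        ax.plot(tt, fit.predict(tt * 1e-3), "k:",
                label=rf"KWW fit ($\tau_{{av}}$ = {fit.tau_av:.3g} ns)")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("t (ps)")
    unit = r"eV$^2$" if series.kind == "energy" else r"$\AA^2$"
    ax.set_ylabel(rf"$C_{{{'E' if series.kind == 'energy' else 'D'}}}(t)$ ({unit})")
    ax.legend()
    return ax


def plot_tau_trends(trend_fits: list[TrendFit], cell_table, ax=None):
    """tau_av vs amplitude per width, with the fitted straight lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for tf in trend_fits:
        sub = cell_table[cell_table["w"] == tf.width].sort_values("h")
        ax.errorbar(sub["h"], sub["tau_av_ns"], yerr=sub["tau_av_err"],
                    fmt="o", label=f"w = {tf.width}")
        hh = np.linspace(sub["h"].min(), sub["h"].max(), 10)
        ax.plot(hh, tf.tau0 + tf.alpha * hh, "-", color=ax.lines[-1].get_color())
    ax.set_xlabel(r"bubble amplitude $h$ ($\AA$)")
    ax.set_ylabel(r"$\tau_{av}$ (ns)")
    ax.legend()
    return ax
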