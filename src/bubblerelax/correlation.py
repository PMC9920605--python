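"""Ensemble autocorrelation functions over the bubble window.

For each realisation the non-normalised, t=0-anchored products

    C_D(t) = (1/w) sum_{i in window} y_i(0) y_i(t)
    C_E(t) = (1/w) sum_{i in window} eps_i(0) eps_i(t)

are computed over the w sites where the bubble was inserted, then averaged
over the ensemble with a standard-error-of-the-mean band.  No mean is
subtracted and nothing is normalised: the raw product form is what makes
the limiting (long-time) values meaningful,

    chi_D = <(1/w) sum y_i(0)> * y_eq,     chi_E = <(1/w) sum eps_i(0)> * eps_eq,

where y_eq is the chain- and ensemble-averaged thermal displacement before
insertion and eps_eq is simply the configured energy per base pair (0.043 eV
for AT, 0.045 eV for GC).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .protocol import RealisationResult

__all__ = [
    "CorrelationSeries",
    "per_run_autocorrelation",
    "displacement_autocorrelation",
    "energy_autocorrelation",
    "limiting_chi",
    "ensemble_stats",
]


@dataclass
class CorrelationSeries:
    """Ensemble mean autocorrelation with its SEM band and limiting value.

    Units: Angstrom^2 for kind="displacement", eV^2 for kind="energy";
    times in ps on the recording grid.
    """

    times: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    chi: float
    kind: str
    n_runs: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.sem = np.asarray(self.sem, dtype=np.float64)
        if not (self.times.shape == self.mean.shape == self.sem.shape):
            raise ValueError("times, mean and sem must share a shape")
        if np.any(self.sem < 0):
            raise ValueError("sem must be non-negative")
        if not np.isfinite(self.chi):
            raise ValueError("chi must be finite")
        if self.kind not in ("displacement", "energy"):
            raise ValueError("kind must be 'displacement' or 'energy'")

    def to_csv(self, path: str | Path) -> None:
        """CSV (time_ps, mean, sem) plus a JSON sidecar with metadata."""
        path = Path(path)
        pd.DataFrame({"time_ps": self.times, "mean": self.mean, "sem": self.sem}).to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps({"kind": self.kind, "chi": self.chi, "n_runs": self.n_runs}))

    @classmethod
    def from_csv(cls, path: str | Path) -> "CorrelationSeries":
        path = Path(path)
        df = pd.read_csv(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(times=df["time_ps"].to_numpy(), mean=df["mean"].to_numpy(),
                   sem=df["sem"].to_numpy(), **meta)


def _check_compatible(results: Sequence[RealisationResult]) -> np.ndarray:
    if not results:
        raise ValueError("no realisations supplied")
    times = results[0].record.times
    for r in results[1:]:
        if r.record.times.shape != times.shape or not np.allclose(r.record.times, times):
            raise ValueError("realisations recorded on different time grids")
        if r.record.window != results[0].record.window:
            raise ValueError("realisations recorded over different windows")
    return times


def per_run_autocorrelation(results: Sequence[RealisationResult], kind: str) -> tuple[np.ndarray, np.ndarray]:
    """(times, matrix) of per-run autocorrelation series, one row per run."""
    times = _check_compatible(results)
    rows = []
    for r in results:
        block = r.record.y_window if kind == "displacement" else r.record.e_window
        init = r.y0_window if kind == "displacement" else r.e0_window
        rows.append(block @ init / init.size)
    return times, np.asarray(rows)


def limiting_chi(results: Sequence[RealisationResult], kind: str,
                 y_eq: float | None = None) -> float:
    """Long-time limit of the ensemble autocorrelation function.

    displacement: requires the thermal equilibrium displacement y_eq; by
    default it is estimated as the ensemble average of each run's
    pre-insertion chain-averaged displacement.  energy: the equilibrium
    local energy equals the configured energy per base pair.
    """
    _check_compatible(results)
    if kind == "displacement":
        if y_eq is None:
            pre = [r.pre_insertion_mean_y for r in results]
            if all(v == 0.0 for v in pre):
                raise ValueError("no pre-insertion displacement data to estimate y_eq")
            y_eq = float(np.mean(pre))
        init_means = [float(np.mean(r.y0_window)) for r in results]
        return float(np.mean(init_means)) * y_eq
    if kind == "energy":
        eps_eq = {r.energy_per_site for r in results}
        if len(eps_eq) != 1:
            raise ValueError("realisations have inconsistent energies per site")
        init_means = [float(np.mean(r.e0_window)) for r in results]
        return float(np.mean(init_means)) * eps_eq.pop()
    raise ValueError("kind must be 'displacement' or 'energy'")


def ensemble_stats(times: np.ndarray, per_run: np.ndarray, chi: float, kind: str) -> CorrelationSeries:
    """Mean and SEM across runs of per-run correlation series (>= 2 runs)."""
    per_run = np.asarray(per_run, dtype=np.float64)
    if per_run.ndim != 2 or per_run.shape[0] < 2:
        raise ValueError("need at least 2 runs to form an SEM band")
    mean = per_run.mean(axis=0)
    sem = per_run.std(axis=0, ddof=1) / np.sqrt(per_run.shape[0])
    return CorrelationSeries(times=times, mean=mean, sem=sem, chi=chi,
                             kind=kind, n_runs=per_run.shape[0])


def displacement_autocorrelation(results: Sequence[RealisationResult],
                                 y_eq: float | None = None) -> CorrelationSeries:
    """Ensemble C_D(t) with SEM band and limiting value chi_D."""
    times, per_run = per_run_autocorrelation(results, "displacement")
    chi = limiting_chi(results, "displacement", y_eq=y_eq)
    return ensemble_stats(times, per_run, chi, "displacement")


def energy_autocorrelation(results: Sequence[RealisationResult]) -> CorrelationSeries:
    """Ensemble C_E(t) with SEM band and limiting value chi_E."""
    times, per_run = per_run_autocorrelation(results, "energy")
    chi = limiting_chi(results, "energy")
    return ensemble_stats(times, per_run, chi, "energy")
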