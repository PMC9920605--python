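"""The bubble-relaxation experiment protocol.

One realisation is: random-momentum initialisation at a prescribed total
energy -> microcanonical thermalisation -> insertion of a Gaussian
denaturation bubble at the chain centre with the chain's total energy
restored by bisection -> recorded relaxation with a logarithmic time grid,
the insertion instant defining t = 0.

The bubble replaces the displacements of a window of w (odd) consecutive
base pairs by

    y(x) = h exp(-(x - c)^2 / (2 sigma^2)),   sigma = w / 6,

so the inserted profile decays to ~1% of h at the window edges.  Because
the bubble adds potential energy, the displacements of all *other* sites
are shrunk by a common factor lambda (found by bisection on the total
energy) until the pre-insertion Hamiltonian is recovered to within
1e-10 eV.  Momenta are untouched, so the kinetic temperature is unchanged
across the insertion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dynamics import IntegratorConfig, TrajectoryRecord, evolve, kinetic_temperature, log_time_grid
from .model import ChainState, ModelParameters, local_energies, total_energy

__all__ = [
    "BubbleSpec",
    "RealisationResult",
    "initial_state",
    "thermalise",
    "bubble_profile",
    "insert_bubble",
    "run_realisation",
]

ENERGY_MATCH_TOL_EV = 1e-10
TARGET_TEMPERATURE_K = 310.0


@dataclass(frozen=True)
class BubbleSpec:
    """Gaussian bubble: amplitude h (Angstrom), width w (odd base pairs).

    The centre c is 1-based; None places the bubble at site N/2 at
    insertion time.  sigma = w/6 exactly.
    """

    h: float
    w: int
    c: int | None = None

    def __post_init__(self) -> None:
        if self.w < 3 or self.w % 2 == 0:
            raise ValueError("bubble width w must be an odd integer >= 3")
        if self.h <= 0:
            raise ValueError("bubble amplitude h must be positive")

    @property
    def sigma(self) -> float:
        return self.w / 6.0

    def centre(self, n_sites: int) -> int:
        return self.c if self.c is not None else n_sites // 2

    def window(self, n_sites: int) -> tuple[int, int]:
        """1-based inclusive site range covered by the bubble."""
        if self.w >= n_sites:
            raise ValueError("bubble wider than the chain")
        c = self.centre(n_sites)
        half = (self.w - 1) // 2
        lo, hi = c - half, c + half
        if lo < 1 or hi > n_sites:
            raise ValueError("bubble window extends past the chain ends")
        return lo, hi


@dataclass
class RealisationResult:
    """Recorded relaxation of one realisation (t=0 is the insertion instant)."""

    seed: int
    record: TrajectoryRecord
    y0_window: np.ndarray
    e0_window: np.ndarray
    pre_insertion_mean_y: float
    spec: BubbleSpec
    params: ModelParameters
    energy_per_site: float
    rescale_lambda: float = 1.0


def initial_state(n_sites: int, energy_per_site: float, seed,
                  mass: float | ModelParameters = 300.0) -> ChainState:
    """Zero displacements, Gaussian momenta rescaled to the exact energy.

    All sites start at the Morse minimum and a zero-mean normal momentum
    draw is multiplied by a single scalar so that sum p^2/2m equals
    n_sites * energy_per_site exactly (the microcanonical energy of the
    run).  `mass` may be a number in amu or a ModelParameters.
    """
    if energy_per_site < 0:
        raise ValueError("energy_per_site must be non-negative")
    m = mass.mass if isinstance(mass, ModelParameters) else float(mass)
    rng = np.random.default_rng(seed)
    y = np.zeros(n_sites)
    if energy_per_site == 0.0:
        return ChainState(y, np.zeros(n_sites))
    p = rng.standard_normal(n_sites)
    while not np.any(p):  # probability-zero degenerate draw
        p = rng.standard_normal(n_sites)
    p *= np.sqrt(n_sites * energy_per_site * 2.0 * m / np.sum(p * p))
    return ChainState(y, p)


def _thermalise_with_tail(state: ChainState, params: ModelParameters, cfg: IntegratorConfig,
                          duration: float, tail_ns: float = 1.0,
                          tail_samples: int = 256) -> tuple[ChainState, TrajectoryRecord | None]:
    if duration < 0:
        raise ValueError("duration must be non-negative")
    if duration == 0:
        return state, None
    tail = min(tail_ns, duration)
    head = duration - tail
    if head > 0:
        state, _ = evolve(state, params, cfg, head)
    grid = np.linspace(0.0, tail * 1e3, tail_samples)
    state, rec = evolve(state, params, cfg, tail, record_times=grid, window=(1, 1))
    return state, rec


def thermalise(state: ChainState, params: ModelParameters, cfg: IntegratorConfig,
               duration: float = 10.0, check_temperature: bool = True) -> ChainState:
    """Evolve for `duration` ns to equilibrate the random initial momenta.

    The kinetic temperature over the final 1 ns (or the whole run if
    shorter) is checked against 310 K; a deviation beyond 10% emits a
    warning but is not fatal.
    """
    state, rec = _thermalise_with_tail(state, params, cfg, duration)
    if rec is not None and check_temperature:
        temp = kinetic_temperature(rec)
        if abs(temp - TARGET_TEMPERATURE_K) > 0.1 * TARGET_TEMPERATURE_K:
            warnings.warn(
                f"kinetic temperature {temp:.1f} K deviates more than 10% from "
                f"{TARGET_TEMPERATURE_K:.0f} K after {duration} ns thermalisation",
                RuntimeWarning, stacklevel=2,
            )
    return state


def bubble_profile(spec: BubbleSpec, sites: Sequence[int] | np.ndarray,
                   n_sites: int | None = None) -> np.ndarray:
    """Gaussian displacement profile evaluated at 1-based site indices."""
    x = np.asarray(sites, dtype=np.float64)
    c = spec.c if spec.c is not None else (n_sites // 2 if n_sites else None)
    if c is None:
        raise ValueError("spec has no centre; pass n_sites")
    return spec.h * np.exp(-((x - c) ** 2) / (2.0 * spec.sigma ** 2))


def insert_bubble(state: ChainState, spec: BubbleSpec, params: ModelParameters,
                  tol: float = ENERGY_MATCH_TOL_EV, max_iter: int = 200,
                  lambda_max: float = 8.0) -> tuple[ChainState, float]:
    """Replace the central window by the bubble, restoring H by bisection.

    All non-bubble displacements are multiplied by a single factor lambda,
    bracketed and bisected on H'(lambda) until |H' - H| < tol (1e-10 eV).
    Momenta are untouched.  Returns (new_state, lambda).

    Raises RuntimeError when no lambda in [0, lambda_max] can restore the
    energy, i.e. the bubble's potential energy exceeds what removing the
    rest of the chain's displacement energy can compensate.
    """
    n = state.n_sites
    lo, hi = spec.window(n)
    window = slice(lo - 1, hi)
    target = total_energy(state, params)
    profile = bubble_profile(spec, np.arange(lo, hi + 1), n_sites=n)

    base = state.y.copy()
    base[window] = profile
    outside = np.ones(n, dtype=bool)
    outside[window] = False
    y_out = state.y[outside]

    def energy_at(lam: float) -> float:
        y = base.copy()
        y[outside] = lam * y_out
        return total_energy(ChainState(y, state.p), params)

    def mismatch(lam: float) -> float:
        return energy_at(lam) - target

    f1 = mismatch(1.0)
    if abs(f1) <= tol:
        lam = 1.0
    else:
        a_br, b_br = 0.0, 1.0
        fa, fb = mismatch(0.0), f1
        if fa > tol:
            raise RuntimeError(
                "bubble insertion infeasible: even with all other displacements "
                f"zeroed the chain energy exceeds the target by {fa:.3e} eV"
            )
        while fb < 0 and b_br < lambda_max:
            a_br, fa = b_br, fb
            b_br = min(2.0 * b_br, lambda_max)
            fb = mismatch(b_br)
        if fb < -tol and b_br >= lambda_max:
            raise RuntimeError(
                "bubble insertion infeasible: no rescaling factor in "
                f"[0, {lambda_max}] restores the energy (short by {-fb:.3e} eV)"
            )
        lam = 0.5 * (a_br + b_br)
        for _ in range(max_iter):
            fm = mismatch(lam)
            if abs(fm) <= tol:
                break
            if fm > 0:
                b_br = lam
            else:
                a_br = lam
            lam = 0.5 * (a_br + b_br)
        else:
            raise RuntimeError(
                f"bisection failed to reach |H'-H| <= {tol} eV in {max_iter} iterations"
            )

    y_new = base.copy()
    y_new[outside] = lam * y_out
    new_state = ChainState(y_new, state.p.copy())
    achieved = total_energy(new_state, params) - target
    if abs(achieved) > tol:
        raise RuntimeError(f"energy mismatch {achieved:.3e} eV after rescaling")
    return new_state, lam


def run_realisation(params: ModelParameters, cfg: IntegratorConfig, spec: BubbleSpec,
                    seed, post_duration: float, therm_duration: float = 10.0,
                    n_sites: int = 300, energy_per_site: float | None = None,
                    points_per_decade: int = 50, t_min_ps: float = 0.01,
                    check_temperature: bool = False) -> RealisationResult:
    """Full protocol for one seed; t=0 of the returned record is insertion.

    post_duration and therm_duration are in ns.  The recorded window is the
    bubble region; displacements, local energies and the total energy are
    stored on a log grid (plus t=0) of `points_per_decade` points per decade
    from `t_min_ps`.
    """
    eps = params.energy_per_site if energy_per_site is None else energy_per_site
    state = initial_state(n_sites, eps, seed, mass=params)
    state, tail = _thermalise_with_tail(state, params, cfg, therm_duration)
    pre_mean_y = float(np.mean(tail.y_mean)) if tail is not None else 0.0
    if tail is not None and check_temperature:
        temp = kinetic_temperature(tail)
        if abs(temp - TARGET_TEMPERATURE_K) > 0.1 * TARGET_TEMPERATURE_K:
            warnings.warn(f"seed {seed}: temperature {temp:.1f} K off target",
                          RuntimeWarning, stacklevel=2)
    state, lam = insert_bubble(state, spec, params)
    window = spec.window(n_sites)
    grid = log_time_grid(post_duration * 1e3, points_per_decade, t_min_ps)
    try:
        state, record = evolve(state, params, cfg, post_duration,
                               record_times=grid, window=window)
    except FloatingPointError as exc:
        raise RuntimeError(f"realisation with seed {seed} failed: {exc}") from exc
    return RealisationResult(
        seed=seed if isinstance(seed, int) else -1,
        record=record,
        y0_window=record.y_window[0].copy(),
        e0_window=record.e_window[0].copy(),
        pre_insertion_mean_y=pre_mean_y,
        spec=spec,
        params=params,
        energy_per_site=eps,
        rescale_lambda=lam,
    )
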