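"""Peyrard-Bishop-Dauxois (PBD) lattice model of homopolymer DNA.

One transverse coordinate per base pair: ``y_n`` is the stretching of pair
``n`` from its equilibrium hydrogen-bond distance (Angstrom), ``p_n`` the
conjugate momentum.  The Hamiltonian, with periodic closure ``y_0 = y_N``, is

    H = sum_n  p_n^2 / 2m  +  V1(y_n)  +  V2(y_n, y_{n-1})

with the Morse on-site pairing potential

    V1(y) = D (exp(-a y) - 1)^2

and the anharmonic nearest-neighbour stacking interaction

    V2(y, y') = (K/2) (1 + rho exp(-b (y + y'))) (y - y')^2 .

The stacking stiffness drops from K(1+rho) when both pairs are closed to K
when either opens, which is what produces the sharp, cooperative
denaturation behaviour of the model.

Energies are in eV, lengths in Angstrom, masses in amu (see
:mod:`bubblerelax.units`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "ModelParameters",
    "ChainState",
    "morse_potential",
    "stacking_potential",
    "total_energy",
    "local_energies",
    "forces",
]


@dataclass(frozen=True)
class ModelParameters:
    """PBD constants for one homopolymer type.

    Parameters
    ----------
    D : float
        Morse depth in eV (hydrogen-bond dissociation plateau).
    a : float
        Morse inverse width in 1/Angstrom.
    K : float
        Stacking force constant in eV/Angstrom^2.
    rho : float
        Dimensionless stacking anharmonicity (stiffness enhancement of
        closed pairs).
    b : float
        Stacking decay constant in 1/Angstrom.
    mass : float
        Base-pair reduced mass in amu.
    sequence : str
        Label of the homopolymer ("AT", "GC" or "custom").
    boundary : str
        "periodic" (default; y_0 = y_N closure) or "free" (open chain ends).
    """

    D: float
    a: float
    K: float
    rho: float = 2.0
    b: float = 0.35
    mass: float = 300.0
    sequence: str = "custom"
    boundary: str = "periodic"

    def __post_init__(self) -> None:
        if not (self.D > 0 and self.a > 0 and self.K > 0 and self.b > 0):
            raise ValueError("D, a, K and b must be positive")
        if self.rho < 0:
            raise ValueError("rho must be non-negative")
        if self.mass <= 0:
            raise ValueError("mass must be positive")
        if self.boundary not in ("periodic", "free"):
            raise ValueError("boundary must be 'periodic' or 'free'")

    @property
    def periodic(self) -> bool:
        return self.boundary == "periodic"

    @classmethod
    def at(cls, **overrides) -> "ModelParameters":
        """Poly(dA)-poly(dT) homopolymer preset."""
        p = cls(D=0.05, a=4.2, K=0.0228, sequence="AT")
        return replace(p, **overrides) if overrides else p

    @classmethod
    def gc(cls, **overrides) -> "ModelParameters":
        """Poly(dG)-poly(dC) homopolymer preset."""
        p = cls(D=0.075, a=6.9, K=0.0192, sequence="GC")
        return replace(p, **overrides) if overrides else p

    @classmethod
    def from_sequence(cls, sequence: str, **overrides) -> "ModelParameters":
        seq = sequence.upper()
        if seq == "AT":
            return cls.at(**overrides)
        if seq == "GC":
            return cls.gc(**overrides)
        raise ValueError(f"unknown homopolymer sequence {sequence!r}; use 'AT' or 'GC'")

    @classmethod
    def from_config(cls, source: str | Path | Mapping) -> "ModelParameters":
        """Build parameters from a YAML/JSON-style mapping or file.

        The mapping must contain ``sequence`` ("AT" or "GC") and may override
        any of ``D, a, K, rho, b, mass``.
        """
        if isinstance(source, (str, Path)):
            with open(source) as fh:
                source = yaml.safe_load(fh)
        cfg = dict(source)
        seq = cfg.pop("sequence", "custom")
        allowed = {"D", "a", "K", "rho", "b", "mass"}
        unknown = set(cfg) - allowed
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        if seq.upper() in ("AT", "GC"):
            return cls.from_sequence(seq, **cfg)
        missing = {"D", "a", "K"} - set(cfg)
        if missing:
            raise ValueError(f"custom parameters require {sorted(missing)}")
        return cls(sequence="custom", **cfg)

    @property
    def energy_per_site(self) -> float:
        """Average microcanonical energy per base pair (eV) giving ~310 K.

        0.043 eV for AT and 0.045 eV for GC homopolymers.
        """
        if self.sequence == "AT":
            return 0.043
        if self.sequence == "GC":
            return 0.045
        raise ValueError("energy_per_site is defined only for the AT/GC presets")


@dataclass
class ChainState:
    """Displacements and momenta of all N base pairs at one instant.

    ``y`` in Angstrom, ``p`` in amu*Angstrom per internal time unit.  Sites
    are stored 0-based internally; user-facing site indices are 1-based.
    """

    y: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64)
        self.p = np.asarray(self.p, dtype=np.float64)
        if self.y.ndim != 1 or self.y.shape != self.p.shape:
            raise ValueError("y and p must be 1-d arrays of equal length")
        if self.n_sites < 3:
            raise ValueError("chain needs at least 3 base pairs")

    @property
    def n_sites(self) -> int:
        return self.y.size

    def copy(self) -> "ChainState":
        return ChainState(self.y.copy(), self.p.copy())


def morse_potential(y, params: ModelParameters):
    """On-site Morse pairing energy V1(y) = D (exp(-a y) - 1)^2 in eV."""
    e = np.exp(-params.a * np.asarray(y, dtype=np.float64))
    return params.D * (e - 1.0) ** 2


def stacking_potential(y_n, y_prev, params: ModelParameters):
    """Anharmonic stacking energy V2(y_n, y_prev) in eV (symmetric)."""
    y_n = np.asarray(y_n, dtype=np.float64)
    y_prev = np.asarray(y_prev, dtype=np.float64)
    env = 1.0 + params.rho * np.exp(-params.b * (y_n + y_prev))
    return 0.5 * params.K * env * (y_n - y_prev) ** 2


def _kinetic(p: np.ndarray, params: ModelParameters) -> np.ndarray:
    return p * p / (2.0 * params.mass)


def _bond_energies(y: np.ndarray, params: ModelParameters) -> np.ndarray:
    """Stacking energy of bond (i, i-1); the wrap bond is zeroed for free ends."""
    v2 = stacking_potential(y, np.roll(y, 1), params)
    if not params.periodic:
        v2[0] = 0.0
    return v2


def total_energy(state: ChainState, params: ModelParameters) -> float:
    """Total Hamiltonian (eV) under the configured boundary condition."""
    y = state.y
    v2 = _bond_energies(y, params)
    terms = np.concatenate([_kinetic(state.p, params), morse_potential(y, params), v2])
    # fsum: the bubble-insertion contract compares H to 1e-10 eV absolute
    return math.fsum(terms)


def local_energies(state: ChainState, params: ModelParameters) -> np.ndarray:
    """Per-site energy density (eV, length N).

    eps_i = p_i^2/2m + V1(y_i) + (V2(y_{i+1}, y_i) + V2(y_i, y_{i-1})) / 2

    Each stacking bond is split evenly between its two sites, so the local
    energies sum exactly to the total Hamiltonian.
    """
    y = state.y
    v2 = _bond_energies(y, params)  # bond (i, i-1)
    return _kinetic(state.p, params) + morse_potential(y, params) + 0.5 * (v2 + np.roll(v2, -1))


def forces(state_or_y, params: ModelParameters) -> np.ndarray:
    """Force -dH/dy_n per site (eV/Angstrom).

    Includes both neighbour stacking bonds and the gradient of the
    exp(-b (y_n + y_{n-1})) stiffness envelope; the wrap-around bond is
    dropped for free boundaries.
    """
    y = state_or_y.y if isinstance(state_or_y, ChainState) else np.asarray(state_or_y, dtype=np.float64)
    D, a, K, rho, b = params.D, params.a, params.K, params.rho, params.b
    em = np.exp(-a * y)
    f = 2.0 * a * D * em * (em - 1.0)
    yl = np.roll(y, 1)  # y_{i-1}
    d = y - yl
    env = np.exp(-b * (y + yl))
    u = K * (1.0 + rho * env) * d  # harmonic-like bond force magnitude
    v = 0.5 * K * b * rho * env * d * d  # envelope-gradient term
    if not params.periodic:
        u[0] = v[0] = 0.0
    f += (v - u)  # bond (i, i-1) acting on i
    f += np.roll(v + u, -1)  # bond (i+1, i) acting on i
    return f
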