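"""Numba-compiled integration kernels.

The production integrator is the 6-stage symplectic Runge-Kutta-Nystrom
method SRKNb6 of Blanes & Moan (J. Comput. Appl. Math. 142, 313 (2002)),
a 4th-order "BAB" composition optimised for Hamiltonians of the form
H = p^2/2m + V(y).  Adjacent momentum kicks of consecutive steps are fused,
so one step costs six force evaluations.

A velocity-Verlet kernel is kept as a cheaper, lower-order cross-check.
All kernels work in internal units (eV, Angstrom, amu, t0).
"""

import numpy as np
from numba import njit

# Blanes & Moan (2002), Table 3: SRKNb6 (palindromic BAB composition).
# Kicks: b1 b2 b3 b4 b3 b2 b1; drifts between them: a1 a2 a3 a3 a2 a1.
SRKN6B_B = np.array(
    [
        0.0829844064174052,
        0.3963098014983680,
        -0.0390563049223486,
        0.1195241940131508,  # = 1 - 2*(b1+b2+b3)
    ]
)
SRKN6B_A = np.array(
    [
        0.245298957184271,
        0.604872665711080,
        -0.350171622895351,  # = 1/2 - (a1+a2)
    ]
)

_KICKS = np.concatenate([SRKN6B_B, SRKN6B_B[-2::-1]])  # length 7
_DRIFTS = np.concatenate([SRKN6B_A, SRKN6B_A[::-1]])  # length 6


@njit(cache=True, fastmath=True)
def _eval_forces(y, f, tb, D, a, K, rho, b, periodic):
    n = y.shape[0]
    # one exp per site: the stacking envelope exp(-b(y_i+y_j)) factorises as
    # tb[i]*tb[j] with tb = exp(-b y); when a is an integer multiple of b
    # (AT: a = 12 b to machine precision) the Morse factor is a power of tb
    k12 = np.abs(a - 12.0 * b) < 1e-12 * a
    if k12:
        for i in range(n):
            t = np.exp(-b * y[i])
            tb[i] = t
            t3 = t * t * t
            t6 = t3 * t3
            e = t6 * t6
            f[i] = 2.0 * a * D * e * (e - 1.0)
    else:
        for i in range(n):
            tb[i] = np.exp(-b * y[i])
            e = np.exp(-a * y[i])
            f[i] = 2.0 * a * D * e * (e - 1.0)
    # bond (i, i-1): u is the harmonic-like part, v the envelope gradient;
    # accumulated in two branch-free passes so the loops stay vectorisable
    kb = 0.5 * K * b * rho
    for i in range(1, n):
        d = y[i] - y[i - 1]
        env = tb[i] * tb[i - 1]
        u = K * (1.0 + rho * env) * d
        v = kb * env * d * d
        f[i] += v - u
        f[i - 1] += v + u
    if periodic:
        d = y[0] - y[n - 1]
        env = tb[0] * tb[n - 1]
        u = K * (1.0 + rho * env) * d
        v = kb * env * d * d
        f[0] += v - u
        f[n - 1] += v + u
    return f


@njit(cache=True)
def srkn6b_advance(y, p, n_steps, dt, D, a, K, rho, b, mass, kicks, drifts, periodic=True):
    """Advance (y, p) in place by n_steps of the SRKNb6 scheme."""
    if n_steps <= 0:
        return
    n = y.shape[0]
    f = np.empty(n)
    tb = np.empty(n)
    dtm = dt / mass
    _eval_forces(y, f, tb, D, a, K, rho, b, periodic)
    c0 = kicks[0] * dt
    for i in range(n):
        p[i] += c0 * f[i]
    for s in range(n_steps):
        for st in range(6):
            cd = drifts[st] * dtm
            for i in range(n):
                y[i] += cd * p[i]
            _eval_forces(y, f, tb, D, a, K, rho, b, periodic)
            # fuse the trailing b1 kick with the leading b1 of the next step
            ck = kicks[st + 1] * dt
            if st == 5 and s < n_steps - 1:
                ck = 2.0 * kicks[6] * dt
            for i in range(n):
                p[i] += ck * f[i]


@njit(cache=True)
def verlet_advance(y, p, n_steps, dt, D, a, K, rho, b, mass, periodic=True):
    """Velocity-Verlet (2nd order) fallback, kicks fused across steps."""
    if n_steps <= 0:
        return
    n = y.shape[0]
    f = np.empty(n)
    tb = np.empty(n)
    dtm = dt / mass
    _eval_forces(y, f, tb, D, a, K, rho, b, periodic)
    half = 0.5 * dt
    for i in range(n):
        p[i] += half * f[i]
    for s in range(n_steps):
        for i in range(n):
            y[i] += dtm * p[i]
        _eval_forces(y, f, tb, D, a, K, rho, b, periodic)
        ck = dt if s < n_steps - 1 else half
        for i in range(n):
            p[i] += ck * f[i]
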