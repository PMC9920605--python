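# bubblerelax

Relaxation dynamics of large denaturation bubbles in homopolymer DNA,
simulated with the coarse-grained Peyrard–Bishop–Dauxois (PBD) lattice
model.

Local openings of the double helix ("bubbles") — produced by rare thermal
fluctuations, engineered perturbations, or protein activity — leave an
imprint on the molecule's dynamics long after they appear.  This package
measures *how long*: it inserts an out-of-equilibrium Gaussian bubble of
amplitude `h` (Å) and width `w` (base pairs) into a thermalised
poly(dA)·poly(dT) or poly(dG)·poly(dC) chain at fixed total energy, follows
the microcanonical relaxation, and extracts a characteristic relaxation
time from ensemble autocorrelation functions.  It is aimed at researchers
in mesoscopic DNA modelling and nonlinear lattice dynamics.

## Model and statistic

The PBD Hamiltonian (one stretching coordinate `y_n` per base pair,
periodic closure) is

    H = Σ_n [ p_n²/2m + D(e^{−a y_n} − 1)² + (K/2)(1 + ρ e^{−b(y_n+y_{n−1})})(y_n − y_{n−1})² ]

integrated with the 4th-order symplectic Runge–Kutta–Nyström scheme SRKNb6
(relative energy drift < 10⁻⁷ over the whole run).  After 10 ns of
thermalisation (~310 K), the central `w` displacements are replaced by
`y(x) = h·e^{−(x−c)²/2σ²}`, σ = w/6, and the remaining displacements are
rescaled by a bisection-determined common factor so the total energy is
restored to within 10⁻¹⁰ eV.  The relaxation is summarised by the
t=0-anchored, non-normalised window autocorrelation functions

    C_D(t) = ⟨(1/w) Σ y_i(0) y_i(t)⟩,    C_E(t) = ⟨(1/w) Σ ε_i(0) ε_i(t)⟩,

whose decay stage follows a stretched exponential (KWW) law

    C(t) = A exp(−(t/τ)^β) + χ,    τ_av = Γ(1/β) τ / β,

with χ fixed at the independently known limiting value.  τ_av — the mean
of the underlying relaxation-time distribution — is the single-number
relaxation scale whose trends in `h` and `w` the trend-fitting layer
quantifies as τ_av = τ₀(w) + α(w)·h.

## Worked example

```python
import numpy as np
from bubblerelax import (ModelParameters, IntegratorConfig, BubbleSpec,
                         energy_autocorrelation, fit_stretched_exponential)
from bubblerelax.synthetic import mini_ensemble

at = ModelParameters.at()                     # poly(dA)-poly(dT) constants
ens = mini_ensemble(at, BubbleSpec(h=5.0, w=11), n_runs=6, seed=3,
                    short_ns=1.0, therm_ns=0.3)   # scaled-down demo ensemble
ce = energy_autocorrelation(ens)
print(f"CE(0) = {ce.mean[0]:.4g} eV^2, chi_E = {ce.chi:.4g} eV^2")
fit = fit_stretched_exponential(ce)
print(fit.summary())
```

prints (seed 3, exactly reproducible)

```
CE(0) = 0.005626 eV^2, chi_E = 0.002983 eV^2
Stretched-exponential relaxation fit
====================================================
kind                  energy autocorrelation
fit window start      0 ns
points fitted         206
chi (fixed)           0.00298267 eV^2
----------------------------------------------------
A               0.00294(5)  eV^2
tau               0.071(4)  ns
beta               0.38(1)
tau_av            0.283849  ns
====================================================
```

The inserted bubble loads the 11-site window with excess energy density
(C_E(0) ≈ 1.9× its equilibrium limit χ_E) which relaxes away on the
sub-nanosecond scale — a six-run, 1 ns demo of the effect that full-scale ensembles
(hundreds to thousands of runs, 100 ns / 5 µs recordings, via
`bubblerelax run --profile at-full|gc-full`) resolve precisely: AT bubbles
relax in 0.5–2 ns while GC bubbles take two orders of magnitude longer.

The same pipeline runs from the shell:

```bash
bubblerelax run --sequence AT -w 9 -w 19 -h 2.5 -h 4.0 -h 5.5 \
    --runs 200 --post-ns 20 --seed 1 --out results/at-desk
bubblerelax summarise --dir results/at-desk
```

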