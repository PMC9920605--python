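"""Internal unit system and physical constants.

The Hamiltonian is written with energies in eV, lengths in Angstrom and
masses in amu, so the model constants keep their literature values
unchanged.  The derived internal time unit is

    t0 = sqrt(amu * A^2 / eV) = 10.1805 fs,

and all user-facing durations (fs/ps/ns) are converted to internal units at
the API boundary.  Momenta are in amu*A/t0, so p^2/2m is directly in eV.
"""

import math

import scipy.constants as _const

#: internal time unit in seconds: sqrt(amu * Angstrom^2 / eV)
TIME_UNIT_S: float = math.sqrt(_const.atomic_mass * 1e-20 / _const.eV)

#: internal time unit expressed in femtoseconds (~10.1805 fs)
TIME_UNIT_FS: float = TIME_UNIT_S / 1e-15

FS_TO_INTERNAL: float = 1.0 / TIME_UNIT_FS
PS_TO_INTERNAL: float = 1e3 * FS_TO_INTERNAL
NS_TO_INTERNAL: float = 1e6 * FS_TO_INTERNAL

INTERNAL_TO_FS: float = TIME_UNIT_FS
INTERNAL_TO_PS: float = TIME_UNIT_FS * 1e-3
INTERNAL_TO_NS: float = TIME_UNIT_FS * 1e-6

#: Boltzmann constant in eV/K
KB_EV: float = 8.617333262e-5
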