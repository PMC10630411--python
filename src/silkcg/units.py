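"""Unit system and physical constants.

The package works throughout in LAMMPS "real"-style units:

========  =================
quantity  unit
========  =================
energy    kcal/mol
length    angstrom (A)
mass      unified amu (u)
time      femtosecond (fs)
angle     degrees in files/APIs, radians internally for stiffnesses
stress    reported in GPa
pressure  targets in atm
========  =================
"""

from __future__ import annotations

#: Boltzmann constant, kcal mol^-1 K^-1
KB_KCAL: float = 0.0019872041

#: Avogadro constant, mol^-1
N_AVOGADRO: float = 6.02214076e23

#: 1 u * (A/fs)^2 expressed in kcal/mol (LAMMPS "mvv2e" for real units).
MVV2E: float = 2390.0573615334906

#: Acceleration conversion: a[A/fs^2] = FTM2A * F[kcal/mol/A] / m[u]
FTM2A: float = 1.0 / MVV2E

#: 1 kcal mol^-1 A^-3 expressed in GPa.
KCAL_A3_TO_GPA: float = 6.947694845598684

#: 1 GPa in atmospheres.
GPA_TO_ATM: float = 1.0e9 / 101325.0

#: 1 u/A^3 in g/cm^3 (mass density conversion).
AMU_A3_TO_G_CM3: float = 1.0 / (N_AVOGADRO * 1.0e-24)
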