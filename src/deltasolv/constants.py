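"""Unit system and physical constants.

Internal units everywhere: energy kJ/mol, length Å, mass u (unified atomic
mass unit), charge e.  Quantities entering from other conventions (eV-based
optimizer tolerances, SI spectroscopic constants) are converted once at the
boundary through the constants below.
"""

from __future__ import annotations

import scipy.constants as _sc

#: kJ/mol per eV (CODATA): 1 eV = 96.48533... kJ/mol
EV_TO_KJMOL: float = _sc.e * _sc.N_A / 1e3

#: Coulomb constant in kJ mol^-1 Å e^-2: e^2 N_A / (4 pi eps0 * 1 Å * 1 kJ)
COULOMB_KJMOL_A: float = _sc.e**2 * _sc.N_A / (4 * _sc.pi * _sc.epsilon_0 * 1e-10 * 1e3)

#: molar gas constant, kJ mol^-1 K^-1
R_KJMOL_K: float = _sc.R / 1e3

#: Planck constant (J s), Boltzmann constant (J/K), speed of light (cm/s)
PLANCK: float = _sc.h
BOLTZMANN: float = _sc.k
C_CM_S: float = _sc.c * 1e2

#: conversion of a mass-weighted Hessian eigenvalue (kJ mol^-1 Å^-2 u^-1)
#: to angular frequency squared in s^-2:  1e3/N_A [J] / (u [kg] * 1e-20 [m^2])
EIGVAL_TO_OMEGA2: float = (1e3 / _sc.N_A) / (_sc.atomic_mass * 1e-20)

#: wavenumber (cm^-1) of a mode with unit internal eigenvalue
WAVENUMBER_PER_SQRT_EIGVAL: float = EIGVAL_TO_OMEGA2**0.5 / (2 * _sc.pi * C_CM_S)

#: hc/k in K cm: vibrational temperature theta = THETA_PER_CM * wavenumber
THETA_PER_CM: float = _sc.h * C_CM_S / _sc.k

#: default optimizer force tolerance, 0.025 eV/Å expressed internally
DEFAULT_FMAX_KJMOL_A: float = 0.025 * EV_TO_KJMOL


def kjmol_to_ev(x: float) -> float:
    return x / EV_TO_KJMOL


def ev_to_kjmol(x: float) -> float:
    return x * EV_TO_KJMOL
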