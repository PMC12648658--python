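"""Unit conventions and physical constants.

Internal units throughout the package: energies in kcal/mol, lengths in
Angstrom, times in fs, temperatures in K, masses in amu.  The Boltzmann
constant ``KB_KCAL_MOL_K`` is the single source of truth; every other
thermal constant is derived from it (or from CODATA values via
``scipy.constants``) at import time.
"""

from __future__ import annotations

import scipy.constants as _sc

# Boltzmann constant, kcal mol^-1 K^-1 -- the package-wide reference value.
KB_KCAL_MOL_K = 0.0019872041

# Energy conversions into kcal/mol.
HARTREE_TO_KCAL_MOL = 627.5094740631
EV_TO_KCAL_MOL = _sc.electron_volt * _sc.Avogadro / (_sc.calorie * 1000.0)
KJ_MOL_TO_KCAL_MOL = 1.0 / _sc.calorie  # = 1/4.184
KCAL_MOL_TO_KJ_MOL = _sc.calorie

# Boltzmann constant in kJ mol^-1 K^-1 (used by the metadynamics module,
# whose free energies follow the kJ/mol convention of the FES literature).
KB_KJ_MOL_K = KB_KCAL_MOL_K * KCAL_MOL_TO_KJ_MOL

# Boltzmann constant in the mechanical unit system amu Angstrom^2 fs^-2 K^-1
# (kinetic energies of particles with amu masses and Angstrom/fs velocities).
_AMU_A2_FS2_IN_J = _sc.atomic_mass * 1e-20 / 1e-30  # one amu A^2/fs^2, in J
KB_AMU_A2_FS2_K = _sc.Boltzmann / _AMU_A2_FS2_IN_J

# kcal/mol per particle expressed in amu A^2 fs^-2.
KCAL_MOL_TO_AMU_A2_FS2 = (_sc.calorie * 1000.0 / _sc.Avogadro) / _AMU_A2_FS2_IN_J

# Diffusion: Angstrom^2/fs -> 1e-9 m^2 s^-1 (the unit diffusion constants
# are conventionally reported in for liquid water).
A2_PER_FS_TO_1E9_M2_S = 1e4

# Spectroscopy: h*c/kB, the second radiation constant, in cm*K.  For a mode
# at wavenumber nu (cm^-1), hbar*omega/(kB*T) = CM1_K_OVER_T * nu / T.
CM1_K = _sc.h * _sc.c * 100.0 / _sc.Boltzmann  # ~1.438777 cm K

# Bohr radius in Angstrom; C6 tables in atomic units (Hartree Bohr^6)
# convert to kcal/mol Angstrom^6 with AU_C6_TO_KCAL_A6.
BOHR_TO_ANGSTROM = _sc.physical_constants["Bohr radius"][0] * 1e10
AU_C6_TO_KCAL_A6 = HARTREE_TO_KCAL_MOL * BOHR_TO_ANGSTROM**6

ENERGY_UNIT_FACTORS = {
    "kcal/mol": 1.0,
    "kcal_mol": 1.0,
    "hartree": HARTREE_TO_KCAL_MOL,
    "ev": EV_TO_KCAL_MOL,
    "kj/mol": KJ_MOL_TO_KCAL_MOL,
    "kj_mol": KJ_MOL_TO_KCAL_MOL,
}


def energy_to_kcal(value: float, unit: str) -> float:
    """Convert *value* from *unit* (case-insensitive) to kcal/mol."""
    key = unit.strip().lower()
    try:
        return value * ENERGY_UNIT_FACTORS[key]
    except KeyError:
        raise ValueError(f"unknown energy unit {unit!r}") from None
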