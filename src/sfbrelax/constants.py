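"""Physical constants, unit conversions and the element mass table.

All internal computations are carried out in SI units; Angstrom and
atomic-mass-unit quantities appear only at the I/O boundary.
"""

from __future__ import annotations

import math

# --- fundamental constants (CODATA 2018) -------------------------------------
K_B = 1.380649e-23  # J/K
H_BAR = 1.054571817e-34  # J s
N_A = 6.02214076e23  # 1/mol
MU0_OVER_4PI = 1e-7  # T m / A

# gyromagnetic ratios, rad s^-1 T^-1
GAMMA_H1 = 267.52218744e6
GAMMA_C13 = 67.2828e6

# --- unit conversions ---------------------------------------------------------
ANGSTROM = 1e-10  # m
ATOMIC_MASS = 1.66053906660e-27  # kg
KCAL_PER_MOL = 4184.0 / N_A  # J

#: Hessian unit conversion factors to J/m^2, keyed by config tag.
HESSIAN_UNITS = {
    "kcal_mol_A2": KCAL_PER_MOL / ANGSTROM**2,
    "J_m2": 1.0,
    "N_m": 1.0,
}

#: Standard atomic weights (u), abridged IUPAC 2021 values.
ATOMIC_MASSES = {
    "H": 1.008,
    "D": 2.014,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "NA": 22.990,
    "MG": 24.305,
    "P": 30.974,
    "S": 32.06,
    "CL": 35.45,
    "K": 39.098,
    "CA": 40.078,
    "FE": 55.845,
    "ZN": 65.38,
    "BR": 79.904,
    "I": 126.90,
}


def element_mass(symbol: str) -> float:
    """Atomic mass in u for an element symbol (case-insensitive).

    Raises KeyError for unknown symbols.
    """
    return ATOMIC_MASSES[symbol.strip().upper()]


def larmor_frequencies(spectrometer_mhz: float) -> tuple[float, float]:
    """Return (omega_H, omega_C) in rad/s for a 1H spectrometer frequency in MHz."""
    omega_h = 2.0 * math.pi * spectrometer_mhz * 1e6
    omega_c = omega_h * GAMMA_C13 / GAMMA_H1
    return omega_h, omega_c
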