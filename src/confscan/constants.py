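"""Physical constants, unit conversions, and element tables.

All constants are CODATA-2018.  Every module converts units through this
file so that oracles and implementation share one constant set.
"""

from __future__ import annotations

# --- fundamental constants (SI) ---
PLANCK_H = 6.62607015e-34          # J s
SPEED_OF_LIGHT = 2.99792458e8      # m/s
BOLTZMANN_K = 1.380649e-23         # J/K
AVOGADRO_NA = 6.02214076e23        # 1/mol
ATOMIC_MASS_U = 1.66053906660e-27  # kg

# --- derived, in the package's working units ---
# gas constant in kcal mol^-1 K^-1
R_KCAL = 1.98720425864e-3
# thermochemical calorie
CAL_TO_J = 4.184
# 1 hartree in kcal/mol
HARTREE_TO_KCAL = 627.509474
# 1 cm^-1 in kcal/mol: h c NA / 4184, rounded to the shared 6-digit value
CM1_TO_KCAL = 2.85914e-3
# standard pressure (1 bar) in Pa
P_STANDARD = 1.0e5

ANGSTROM = 1.0e-10  # m

# IUPAC standard atomic weights (u), elements relevant to amino acids
# plus a few extras so toy fixtures are unconstrained.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "D": 2.014,
    "He": 4.002602,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998403163,
    "P": 30.973761998,
    "S": 32.06,
    "Cl": 35.45,
    "X": 1.0,  # massless-ish dummy for toy chains
}

# Covalent radii (Å), Cordero et al. consensus values; used for bond
# perception with a multiplicative cutoff scale.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31,
    "D": 0.31,
    "He": 0.28,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "F": 0.57,
    "P": 1.07,
    "S": 1.05,
    "Cl": 1.02,
    "X": 0.76,
}


def mass_of(element: str) -> float:
    """Standard atomic weight of *element* in u."""
    try:
        return ATOMIC_MASSES[element]
    except KeyError:
        raise KeyError(f"no atomic mass tabulated for element {element!r}") from None


def covalent_radius(element: str) -> float:
    try:
        return COVALENT_RADII[element]
    except KeyError:
        raise KeyError(f"no covalent radius tabulated for element {element!r}") from None
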