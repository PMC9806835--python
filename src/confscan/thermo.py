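"""Rigid-rotor / harmonic-oscillator (RRHO) statistical thermodynamics.

Ideal-gas, single-conformer state functions: translational enthalpy
(5/2)RT with Sackur–Tetrode entropy, classical rotational enthalpy
(3/2)RT with the asymmetric-top entropy (symmetry number 1 — every
species here is C1), and harmonic-oscillator vibrational terms over
all modes with the zero-point energy reported separately.  No
frequency scaling, no anharmonicity or hindered-rotor damping.

Units: enthalpies and free energies in kcal/mol, entropies in
cal mol⁻¹ K⁻¹, wavenumbers in cm⁻¹ (negative = imaginary), masses in
u, temperature in K, pressure in Pa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import (
    ATOMIC_MASS_U,
    AVOGADRO_NA,
    BOLTZMANN_K,
    CAL_TO_J,
    CM1_TO_KCAL,
    P_STANDARD,
    PLANCK_H,
    R_KCAL,
    SPEED_OF_LIGHT,
)
from .geometry import RotationalConstants

R_CAL = R_KCAL * 1000.0  # cal mol^-1 K^-1


class NotAMinimumError(ValueError):
    """Imaginary mode present where a true minimum is required."""


@dataclass(frozen=True)
class FrequencySet:
    """Harmonic wavenumbers of one conformer (cm⁻¹).

    Imaginary modes are encoded as negative numbers; thermochemistry
    refuses them.
    """

    wavenumbers: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "wavenumbers", tuple(float(w) for w in self.wavenumbers)
        )

    @property
    def n_imaginary(self) -> int:
        return sum(1 for w in self.wavenumbers if w < 0)

    def require_minimum(self) -> None:
        if self.n_imaginary:
            raise NotAMinimumError(
                f"{self.n_imaginary} imaginary mode(s); thermochemistry "
                "is defined only at minima"
            )


def zero_point_energy(freqs: FrequencySet) -> float:
    """ZPE = Σ ν_i / 2, converted to kcal/mol."""
    freqs.require_minimum()
    return 0.5 * sum(freqs.wavenumbers) * CM1_TO_KCAL


@dataclass(frozen=True)
class ThermoState:
    """H/S/G decomposition of one conformer at one temperature.

    ``H_total`` includes the ZPE; ``G_total = H_total − T·S_total/1000``
    holds exactly by construction.
    """

    temperature: float
    H_trans: float
    H_rot: float
    H_vib: float
    ZPE: float
    S_trans: float
    S_rot: float
    S_vib: float

    @property
    def H_total(self) -> float:
        return self.H_trans + self.H_rot + self.H_vib + self.ZPE

    @property
    def S_total(self) -> float:
        return self.S_trans + self.S_rot + self.S_vib

    @property
    def G_total(self) -> float:
        return self.H_total - self.temperature * self.S_total / 1000.0


def sackur_tetrode_entropy(mass_u: float, T: float, p: float = P_STANDARD) -> float:
    """Translational entropy of an ideal gas, cal mol⁻¹ K⁻¹."""
    m = mass_u * ATOMIC_MASS_U
    lam_term = (2.0 * np.pi * m * BOLTZMANN_K * T / PLANCK_H**2) ** 1.5
    q_trans = lam_term * BOLTZMANN_K * T / p
    return R_CAL * (np.log(q_trans) + 2.5)


def rotational_entropy(rot: RotationalConstants, T: float) -> float:
    """Classical asymmetric-top rotational entropy, σ = 1, cal mol⁻¹ K⁻¹."""
    # rotational temperatures Θ = h c B / k
    theta = [
        PLANCK_H * SPEED_OF_LIGHT * 100.0 * b / BOLTZMANN_K
        for b in (rot.A, rot.B, rot.C)
    ]
    if rot.linear:
        q = T / theta[1]
        return R_CAL * (np.log(q) + 1.0)
    q = np.sqrt(np.pi) * np.sqrt(T**3 / (theta[0] * theta[1] * theta[2]))
    return R_CAL * (np.log(q) + 1.5)


def _vib_theta(freqs: FrequencySet) -> np.ndarray:
    w = np.asarray(freqs.wavenumbers)
    return PLANCK_H * SPEED_OF_LIGHT * 100.0 * w / BOLTZMANN_K  # K


def vibrational_thermal_energy(freqs: FrequencySet, T: float) -> float:
    """Thermal (beyond-ZPE) vibrational energy, kcal/mol."""
    theta = _vib_theta(freqs)
    x = theta / T
    with np.errstate(over="ignore"):
        return float(np.sum(R_KCAL * theta / np.expm1(x)))


def vibrational_entropy(freqs: FrequencySet, T: float) -> float:
    """Harmonic-oscillator vibrational entropy, cal mol⁻¹ K⁻¹."""
    theta = _vib_theta(freqs)
    x = theta / T
    with np.errstate(over="ignore"):
        s = x / np.expm1(x) - np.log1p(-np.exp(-x))
    return float(R_CAL * np.sum(s))


def rrho_state(
    freqs: FrequencySet,
    rot: RotationalConstants,
    mass_u: float,
    T: float,
    p: float = P_STANDARD,
) -> ThermoState:
    """Full RRHO state of one conformer.

    ``H_trans = (5/2)RT`` (ideal gas, pV included), ``H_rot = (3/2)RT``
    for a nonlinear top; vibrational terms from the harmonic partition
    function over every mode.  At T → 0 all thermal contributions and
    entropies vanish and only the ZPE survives.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    freqs.require_minimum()
    h_rot = (1.0 if rot.linear else 1.5) * R_KCAL * T
    return ThermoState(
        temperature=T,
        H_trans=2.5 * R_KCAL * T,
        H_rot=h_rot,
        H_vib=vibrational_thermal_energy(freqs, T),
        ZPE=zero_point_energy(freqs),
        S_trans=sackur_tetrode_entropy(mass_u, T, p),
        S_rot=rotational_entropy(rot, T),
        S_vib=vibrational_entropy(freqs, T),
    )


PROTON_MASS_U = 1.007276466621  # bare proton, u


@dataclass(frozen=True)
class ProtonThermo:
    """Ideal-gas thermodynamics of the free proton at one temperature."""

    temperature: float
    H: float  # kcal/mol
    S: float  # cal mol^-1 K^-1

    @property
    def G(self) -> float:
        return self.H - self.temperature * self.S / 1000.0


def proton_thermo(T: float, p: float = P_STANDARD) -> ProtonThermo:
    """H⁺(g): H = (5/2)RT (1.48 kcal/mol at 298.15 K), Sackur–Tetrode S.

    The proton has no internal structure, so translation is the whole
    story; the entropy is fixed by physics, not fitted.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    return ProtonThermo(
        temperature=T,
        H=2.5 * R_KCAL * T,
        S=sackur_tetrode_entropy(PROTON_MASS_U, T, p),
    )


def pa_gb_pair(
    neutral: ThermoState, protonated: ThermoState, proton: ProtonThermo
) -> tuple[float, float]:
    """Proton affinity and gas-phase basicity of one conformer pair.

    For the gas-phase deprotonation BH⁺ → B + H⁺:
    PA = H(B) + H(H⁺) − H(BH⁺) and GB = G(B) + G(H⁺) − G(BH⁺); the
    identity PA − GB = T·ΔS/1000 holds exactly.
    """
    temps = {neutral.temperature, protonated.temperature, proton.temperature}
    if max(temps) - min(temps) > 1e-9:
        raise ValueError("all states must share one temperature")
    pa = neutral.H_total + proton.H - protonated.H_total
    gb = neutral.G_total + proton.G - protonated.G_total
    return pa, gb
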