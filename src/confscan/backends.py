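"""Synthetic stand-ins for the electronic-structure layer.

Two generators live here:

* an analytic torsional potential (:class:`ToyTorsionalPES`) with an
  optimizer and central-difference frequencies, exposed through the
  same backend contract a real quantum-chemistry driver would fill —
  it exists to exercise the grid-search workflow, not to model any
  real molecule, and its "frequencies" are nominal numbers from a
  torsion-space Hessian, explicitly non-physical;
* a correction-ledger generator (:func:`generate_ledger`) that emulates
  the magnitude structure of benchmark focal-point tables: relative
  energies of a few kcal/mol, additive corrections of order
  0.01–0.1 kcal/mol, and zero-point corrections whose sign depends on
  the protonation site.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
from scipy.optimize import minimize

from .geometry import (
    MolecularGeometry,
    TorsionSpec,
    measure_dihedral,
    set_dihedral,
)

TWO_PI = 2.0 * np.pi


class EnergyBackend(Protocol):
    """Contract every optimization driver fulfils."""

    def energy(self, geometry: MolecularGeometry) -> float: ...

    def optimize(
        self, geometry: MolecularGeometry
    ) -> tuple[MolecularGeometry, float, bool]: ...

    def frequencies(self, geometry: MolecularGeometry) -> np.ndarray: ...


@dataclass(frozen=True)
class ToyTorsionalPES:
    """Smooth 2π-periodic potential over torsion angles (radians inside).

    V(φ) = Σ_j Σ_k a_{jk} (1 − cos(k φ_j − δ_{jk}))
         + Σ_{j<j'} c_{jj'} (1 − cos(φ_j − φ_{j'}))

    ``amplitudes[j]`` is a list of (k, a_jk, delta_jk) triples; couplings
    map index pairs to amplitudes.  All energies in kcal/mol, angles at
    the API surface in degrees.
    """

    amplitudes: tuple[tuple[tuple[int, float, float], ...], ...]
    couplings: tuple[tuple[int, int, float], ...] = ()

    @property
    def n_torsions(self) -> int:
        return len(self.amplitudes)

    def _check(self, phi_deg: Sequence[float]) -> np.ndarray:
        phi = np.radians(np.asarray(phi_deg, dtype=float))
        if phi.shape != (self.n_torsions,):
            raise ValueError(
                f"expected {self.n_torsions} torsion angles, got {phi.shape}"
            )
        return phi

    def energy(self, phi_deg: Sequence[float]) -> float:
        """Exact analytic potential value at an angle tuple (degrees)."""
        phi = self._check(phi_deg)
        v = 0.0
        for j, terms in enumerate(self.amplitudes):
            for k, a, delta in terms:
                v += a * (1.0 - np.cos(k * phi[j] - delta))
        for i, j, c in self.couplings:
            v += c * (1.0 - np.cos(phi[i] - phi[j]))
        return float(v)

    def gradient(self, phi_deg: Sequence[float]) -> np.ndarray:
        """Analytic gradient in kcal/mol per radian."""
        phi = self._check(phi_deg)
        g = np.zeros_like(phi)
        for j, terms in enumerate(self.amplitudes):
            for k, a, delta in terms:
                g[j] += a * k * np.sin(k * phi[j] - delta)
        for i, j, c in self.couplings:
            s = c * np.sin(phi[i] - phi[j])
            g[i] += s
            g[j] -= s
        return g

    def hessian(self, phi_deg: Sequence[float], step_deg: float = 0.5) -> np.ndarray:
        """Central-difference Hessian in torsion space (per radian²)."""
        phi = np.asarray(phi_deg, dtype=float)
        h = np.radians(step_deg)
        n = self.n_torsions
        H = np.zeros((n, n))
        step = np.degrees(h)

        def e(p):
            return self.energy(p)

        e0 = e(phi)
        for i in range(n):
            for j in range(i, n):
                if i == j:
                    pp = phi.copy()
                    pp[i] += step
                    pm = phi.copy()
                    pm[i] -= step
                    H[i, i] = (e(pp) - 2 * e0 + e(pm)) / h**2
                else:
                    vals = []
                    for si, sj in itertools.product((1, -1), repeat=2):
                        p = phi.copy()
                        p[i] += si * step
                        p[j] += sj * step
                        vals.append(si * sj * e(p))
                    H[i, j] = H[j, i] = sum(vals) / (4 * h**2)
        return H


def dense_scan_minima(
    pes: ToyTorsionalPES, resolution_deg: float = 1.0
) -> list[tuple[tuple[float, ...], float]]:
    """Exhaustively locate local minima on a dense periodic grid.

    A grid point is a minimum when its value is below all 3^n − 1
    periodic neighbours.  Serves as the independent oracle for the
    optimizer-driven search.
    """
    n = pes.n_torsions
    m = int(round(360.0 / resolution_deg))
    axes = [np.arange(m) * resolution_deg for _ in range(n)]
    grid = np.empty([m] * n)
    for idx in itertools.product(range(m), repeat=n):
        grid[idx] = pes.energy([axes[d][i] for d, i in enumerate(idx)])
    minima = []
    offsets = [o for o in itertools.product((-1, 0, 1), repeat=n) if any(o)]
    for idx in itertools.product(range(m), repeat=n):
        v = grid[idx]
        if all(
            v < grid[tuple((i + o) % m for i, o in zip(idx, off))]
            for off in offsets
        ):
            point = tuple(float(axes[d][i]) for d, i in enumerate(idx))
            minima.append((point, float(v)))
    return minima


def optimize_torsions(
    pes: ToyTorsionalPES,
    start_deg: Sequence[float],
    tol: float = 1e-8,
) -> tuple[np.ndarray, float, bool]:
    """Minimize the toy potential in torsion space from *start_deg*.

    Gradient-based quasi-Newton in radians with the analytic gradient;
    convergence tolerance 1e-8 kcal/mol.  Returns angles in degrees
    wrapped to [0, 360).
    """
    phi0 = np.radians(np.asarray(start_deg, dtype=float))

    def fun(phi):
        return pes.energy(np.degrees(phi))

    def jac(phi):
        return pes.gradient(np.degrees(phi))

    res = minimize(fun, phi0, jac=jac, method="BFGS", options={"gtol": 1e-10})
    ok = bool(res.success) or float(np.linalg.norm(jac(res.x))) < 1e-6
    angles = np.degrees(res.x) % 360.0
    return angles, float(res.fun), ok


#: fixed, admittedly arbitrary mapping from torsion-space Hessian
#: eigenvalues (kcal/mol/rad²) to nominal wavenumbers — keeps the
#: minimum/saddle bookkeeping meaningful without claiming physics.
_NOMINAL_FREQ_SCALE = 100.0


def torsional_frequencies(
    pes: ToyTorsionalPES, phi_deg: Sequence[float], step_deg: float = 0.5
) -> np.ndarray:
    """Nominal wavenumbers from the torsion-space Hessian.

    Negative entries encode imaginary modes (negative Hessian
    eigenvalues), so a saddle of index 1 reports exactly one negative
    value.  Not physical frequencies.
    """
    eigvals = np.linalg.eigvalsh(pes.hessian(phi_deg, step_deg=step_deg))
    return np.sign(eigvals) * _NOMINAL_FREQ_SCALE * np.sqrt(np.abs(eigvals))


@dataclass
class ToyTorsionalBackend:
    """EnergyBackend over geometries, delegating to a torsional toy PES.

    The backend measures the dihedrals named by ``torsions`` on the
    incoming geometry, optimizes them on the analytic surface, and
    writes the optimized angles back onto the geometry, so the whole
    grid-search pipeline runs unchanged with no electronic-structure
    code behind it.
    """

    pes: ToyTorsionalPES
    torsions: tuple[TorsionSpec, ...]

    def _angles(self, geometry: MolecularGeometry) -> list[float]:
        return [measure_dihedral(geometry, t.dihedral_atoms) for t in self.torsions]

    def energy(self, geometry: MolecularGeometry) -> float:
        return self.pes.energy(self._angles(geometry))

    def optimize(self, geometry: MolecularGeometry):
        angles, energy, ok = optimize_torsions(self.pes, self._angles(geometry))
        geom = geometry
        for t, a in zip(self.torsions, angles):
            geom = set_dihedral(geom, t, a)
        return geom, energy, ok

    def frequencies(self, geometry: MolecularGeometry) -> np.ndarray:
        return torsional_frequencies(self.pes, self._angles(geometry))

    def n_imaginary(self, geometry: MolecularGeometry) -> int:
        return int(np.sum(self.frequencies(geometry) < 0))


def toy_chain_geometry(n_torsions: int, element: str = "C") -> tuple[
    MolecularGeometry, tuple[TorsionSpec, ...]
]:
    """A zig-zag heavy-atom chain with ``n_torsions`` rotatable bonds.

    The chain has n_torsions + 3 atoms; consecutive atom quadruples
    define the torsions, each driving the tail of the chain.  Useful as
    a minimal geometry whose dihedrals the toy backend can exercise.
    """
    if n_torsions < 1:
        raise ValueError("need at least one torsion")
    n_atoms = n_torsions + 3
    bond, angle = 1.54, np.radians(109.5)
    coords = [np.zeros(3), np.array([bond, 0.0, 0.0])]
    # place successive atoms with alternating in-plane zig-zag, then
    # perturb nothing: dihedrals start at 180°.
    direction_flip = 1.0
    for _ in range(2, n_atoms):
        prev, prev2 = coords[-1], coords[-2]
        back = (prev - prev2) / np.linalg.norm(prev - prev2)
        perp = np.array([-back[1], back[0], 0.0])
        if np.linalg.norm(perp) < 1e-8:
            perp = np.array([0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        newdir = np.cos(np.pi - angle) * back + np.sin(np.pi - angle) * perp * direction_flip
        coords.append(prev + bond * newdir)
        direction_flip *= -1.0
    geom = MolecularGeometry(
        elements=tuple(element for _ in range(n_atoms)),
        coords=np.array(coords),
        charge=0,
        label=f"toy-chain-{n_torsions}",
    )
    torsions = tuple(
        TorsionSpec(
            axis=(i + 1, i + 2),
            dihedral_atoms=(i, i + 1, i + 2, i + 3),
            moving_set=frozenset(range(i + 3, n_atoms)),
            step_deg=60.0,
        )
        for i in range(n_torsions)
    )
    return geom, torsions


def random_pes(
    n_torsions: int,
    seed: int = 0,
    barrier_range: tuple[float, float] = (1.0, 5.0),
    coupling_scale: float = 0.3,
) -> ToyTorsionalPES:
    """A seeded multi-well torsional potential.

    Each coordinate gets cosine terms of order 1–3 with barriers drawn
    from *barrier_range* (kcal/mol) and random phase offsets, plus weak
    pairwise couplings, so a handful of wells funnel many grid starts —
    the qualitative behaviour a conformer search has to cope with.
    """
    rng = np.random.default_rng(seed)
    amplitudes = []
    for _ in range(n_torsions):
        terms = []
        for k in (1, 2, 3):
            a = rng.uniform(*barrier_range) / k
            delta = rng.uniform(0.0, TWO_PI)
            terms.append((k, float(a), float(delta)))
        amplitudes.append(tuple(terms))
    couplings = tuple(
        (i, j, float(rng.uniform(0.0, coupling_scale)))
        for i in range(n_torsions)
        for j in range(i + 1, n_torsions)
    )
    return ToyTorsionalPES(amplitudes=tuple(amplitudes), couplings=couplings)


# ---------------------------------------------------------------------------
# synthetic correction ledgers


@dataclass(frozen=True)
class LedgerSpec:
    """Shape of a synthetic focal-point correction ledger.

    ``site`` controls the zero-point-correction sign convention the
    generator emulates: amino-protonated species mix signs, carbonyl
    ones are negative, thiol ones positive (mean magnitude
    ``zpe_mean``).  Correction noise scales are standard deviations in
    kcal/mol.
    """

    n_conformers: int = 10
    rel_energy_range: tuple[float, float] = (0.0, 8.0)
    core_scale: float = 0.03
    rel_scale: float = 0.01
    delta_t_scale: float = 0.02
    delta_q_scale: float = 0.03
    zpe_mean: float = 0.4
    zpe_scale: float = 0.15
    site: str = "neutral"  # neutral | amino | carbonyl | thiol
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_conformers < 1:
            raise ValueError("need at least one conformer")
        lo, hi = self.rel_energy_range
        if lo < 0 or hi < lo:
            raise ValueError("relative-energy range must be ordered and nonnegative")
        for s in (self.core_scale, self.rel_scale, self.delta_t_scale,
                  self.delta_q_scale, self.zpe_scale):
            if s < 0:
                raise ValueError("noise scales must be nonnegative")
        if self.site not in ("neutral", "amino", "carbonyl", "thiol"):
            raise ValueError(f"unknown site {self.site!r}")


_ZPE_SIGN = {"neutral": 0.0, "amino": 0.0, "carbonyl": -1.0, "thiol": 1.0}


def generate_ledger(spec: LedgerSpec):
    """Generate a reproducible synthetic energy ledger.

    Returns an :class:`~confscan.composite.EnergyLedger` whose raw
    column pairs are internally consistent, i.e. the focal-point
    assembly recovers exactly the corrections drawn here.  Conformer I
    has every relative column equal to zero.
    """
    from .composite import EnergyLedger  # local import: avoid cycle

    rng = np.random.default_rng(spec.seed)
    n = spec.n_conformers
    lo, hi = spec.rel_energy_range
    base = np.sort(rng.uniform(lo, hi, size=n))
    base[0] = 0.0

    def noise(scale):
        v = rng.normal(0.0, scale, size=n) if scale > 0 else np.zeros(n)
        v[0] = 0.0
        return v

    d_core = noise(spec.core_scale)
    d_rel = noise(spec.rel_scale)
    d_t = noise(spec.delta_t_scale)
    d_q = noise(spec.delta_q_scale)
    sign = _ZPE_SIGN[spec.site]
    if spec.zpe_scale > 0 or spec.zpe_mean > 0:
        mag = rng.normal(spec.zpe_mean, spec.zpe_scale, size=n)
        if sign == 0.0:
            zpe = mag * rng.choice([-1.0, 1.0], size=n) * 0.3
        else:
            zpe = sign * np.abs(mag)
        zpe[0] = 0.0
    else:
        zpe = np.zeros(n)

    import pandas as pd

    geom_shift = noise(0.02)
    df = pd.DataFrame(
        {
            "name": [_roman(i + 1) for i in range(n)],
            "E_mp2_avdz": base + noise(0.1),
            "E_cc_dz_mp2geom": base + geom_shift,
            "E_cc_dz": base,
            "E_cc_tz": base + noise(0.02),
            "E_cc_qz_f12a": base + noise(0.01),
            "E_cc_qz_f12b": base,
            "E_fc_cvtz": base,
            "E_ae_cvtz": base + d_core,
            "E_nodk": base,
            "E_dk": base + d_rel,
            "E_ccsd_t_631g": base,
            "E_ccsdt_631g": base + d_t,
            "E_ccsdt_q_631g": base + d_t + d_q,
            "zpe": zpe,
        }
    )
    return EnergyLedger(df, relative=True)


_ROMAN = [
    (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"), (90, "XC"),
    (50, "L"), (40, "XL"), (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I"),
]


def _roman(n: int) -> str:
    out = []
    for val, sym in _ROMAN:
        while n >= val:
            out.append(sym)
            n -= val
    return "".join(out)
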