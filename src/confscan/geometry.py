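"""Cartesian molecular geometries and the operations the conformer
search needs: dihedral measurement and rotation, rotational constants,
covalent-radius connectivity perception, protonation-variant
construction, and topology-based byproduct classification.

Conventions: coordinates in Å, angles in degrees at the API surface
(IUPAC dihedral sign: looking from b to c, clockwise positive; values
reported in (−180°, 180°]), rotational constants in cm⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .constants import (
    ANGSTROM,
    ATOMIC_MASS_U,
    PLANCK_H,
    SPEED_OF_LIGHT,
    covalent_radius,
    mass_of,
)


class InvalidTorsionError(ValueError):
    """Torsion definition inconsistent with the geometry."""


class DegenerateGeometryError(ValueError):
    """Geometry unusable for the requested operation (e.g. zero-length axis)."""


class MissingSiteError(ValueError):
    """Requested protonation site not present in the molecule."""


class IncomparableSpeciesError(ValueError):
    """Byproduct classification attempted across different stoichiometries."""


@dataclass(frozen=True)
class MolecularGeometry:
    """An ordered set of atoms with Cartesian coordinates.

    Parameters
    ----------
    elements:
        Element symbols, one per atom.
    coords:
        (N, 3) array of positions in Å.
    charge:
        Total charge in elementary charges (0 or +1 for this study's
        species, but not enforced beyond integrality).
    masses:
        Atomic masses in u; looked up from the standard-weight table
        when omitted.
    label:
        Free-text identifier carried through the pipeline.
    """

    elements: tuple[str, ...]
    coords: np.ndarray
    charge: int = 0
    masses: tuple[float, ...] = ()
    label: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] == 0:
            raise ValueError("coords must be a non-empty (N, 3) array")
        if len(self.elements) != coords.shape[0]:
            raise ValueError("elements and coords disagree on atom count")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "elements", tuple(self.elements))
        masses = self.masses or tuple(mass_of(e) for e in self.elements)
        if len(masses) != len(self.elements):
            raise ValueError("masses and elements disagree on atom count")
        if any(m <= 0 for m in masses):
            raise ValueError("masses must be positive")
        object.__setattr__(self, "masses", tuple(float(m) for m in masses))

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def total_mass(self) -> float:
        return float(sum(self.masses))

    def with_coords(self, coords: np.ndarray) -> "MolecularGeometry":
        return replace(self, coords=np.asarray(coords, dtype=float))

    def distance(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.coords[i] - self.coords[j]))


@dataclass(frozen=True)
class TorsionSpec:
    """A rotatable bond with its measured dihedral and grid metadata.

    ``axis`` is the bonded pair (b, c); rotating moves every atom in
    ``moving_set`` about that axis.  ``dihedral_atoms`` (a, b, c, d)
    defines the angle that is reported and driven.
    ``symmetry_period_deg`` is the local rotor periodicity (360 for an
    asymmetric group, 120 for a C3v ammonium top); ``mirror_equivalent``
    marks a torsion whose grid is halved once by a local mirror plane
    (the C2v doubly-hydroxylated carbon of a protonated carboxyl).
    """

    axis: tuple[int, int]
    dihedral_atoms: tuple[int, int, int, int]
    moving_set: frozenset[int]
    step_deg: float = 60.0
    symmetry_period_deg: float = 360.0
    mirror_equivalent: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "axis", tuple(int(i) for i in self.axis))
        object.__setattr__(
            self, "dihedral_atoms", tuple(int(i) for i in self.dihedral_atoms)
        )
        object.__setattr__(self, "moving_set", frozenset(int(i) for i in self.moving_set))
        b, c = self.axis
        if b == c:
            raise InvalidTorsionError("axis atoms must differ")
        if b in self.moving_set or c in self.moving_set:
            raise InvalidTorsionError("axis atoms may not be in the moving set")
        if self.step_deg <= 0 or self.symmetry_period_deg <= 0:
            raise InvalidTorsionError("step and period must be positive")
        if round(360.0 / self.step_deg, 9) % 1:
            raise InvalidTorsionError("step must divide 360°")
        if round(360.0 / self.symmetry_period_deg, 9) % 1:
            raise InvalidTorsionError("symmetry period must divide 360°")

    @property
    def n_grid_points(self) -> int:
        """Grid points this torsion contributes before any mirror halving."""
        n = self.symmetry_period_deg / self.step_deg
        if round(n, 9) % 1:
            raise InvalidTorsionError(
                f"step {self.step_deg}° does not divide period {self.symmetry_period_deg}°"
            )
        return int(round(n))


def wrap_angle(angle_deg: float) -> float:
    """Map an angle to the reporting interval (−180°, 180°]."""
    a = float(angle_deg) % 360.0
    if a > 180.0:
        a -= 360.0
    return a


def measure_dihedral(geometry: MolecularGeometry, atoms) -> float:
    """Signed dihedral angle a–b–c–d in degrees, IUPAC convention."""
    a, b, c, d = (geometry.coords[i] for i in atoms)
    b1, b2, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm2 = np.linalg.norm(b2)
    if norm2 == 0 or not n1.any() or not n2.any():
        raise DegenerateGeometryError("collinear atoms define no dihedral")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / norm2)
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def _rotation_matrix(axis_vec: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation about a unit axis."""
    k = axis_vec / np.linalg.norm(axis_vec)
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * kx + (1 - np.cos(angle_rad)) * (kx @ kx)


def rotate_torsion(
    geometry: MolecularGeometry, torsion: TorsionSpec, angle_deg: float
) -> MolecularGeometry:
    """Rotate ``torsion.moving_set`` about the torsion axis by *angle_deg*.

    The measured dihedral changes by exactly +angle_deg (mod 360°);
    every atom outside the moving set is untouched and all distances
    inside the moving set are preserved (rigid rotation).
    """
    n = geometry.n_atoms
    for i in (*torsion.axis, *torsion.dihedral_atoms, *torsion.moving_set):
        if not 0 <= i < n:
            raise InvalidTorsionError(f"atom index {i} outside geometry of {n} atoms")
    b, c = torsion.axis
    axis_vec = geometry.coords[c] - geometry.coords[b]
    if np.linalg.norm(axis_vec) < 1e-12:
        raise DegenerateGeometryError("zero-length torsion axis")
    # rotating the d-side set by +angle about b->c (right-handed) adds
    # +angle to the IUPAC dihedral
    rot = _rotation_matrix(axis_vec, np.radians(angle_deg))
    origin = geometry.coords[b]
    coords = geometry.coords.copy()
    idx = sorted(torsion.moving_set)
    coords[idx] = (coords[idx] - origin) @ rot.T + origin
    return geometry.with_coords(coords)


def set_dihedral(
    geometry: MolecularGeometry, torsion: TorsionSpec, target_deg: float
) -> MolecularGeometry:
    """Drive the torsion so its measured dihedral equals *target_deg*."""
    current = measure_dihedral(geometry, torsion.dihedral_atoms)
    return rotate_torsion(geometry, torsion, target_deg - current)


# ---------------------------------------------------------------------------
# rotational constants


@dataclass(frozen=True)
class RotationalConstants:
    """Principal rotational constants in cm⁻¹, sorted A ≥ B ≥ C.

    For a linear geometry ``linear`` is set, A is undefined (NaN) and
    B = C is the single constant.
    """

    A: float
    B: float
    C: float
    linear: bool = False

    def __post_init__(self) -> None:
        if not self.linear:
            if not (self.A >= self.B >= self.C > 0):
                raise ValueError("expected A ≥ B ≥ C > 0 for a nonlinear top")


def _inertia_tensor(geometry: MolecularGeometry) -> np.ndarray:
    m = np.asarray(geometry.masses)
    r = geometry.coords - np.average(geometry.coords, axis=0, weights=m)
    x, y, z = r[:, 0], r[:, 1], r[:, 2]
    ixx = np.sum(m * (y**2 + z**2))
    iyy = np.sum(m * (x**2 + z**2))
    izz = np.sum(m * (x**2 + y**2))
    ixy = -np.sum(m * x * y)
    ixz = -np.sum(m * x * z)
    iyz = -np.sum(m * y * z)
    return np.array([[ixx, ixy, ixz], [ixy, iyy, iyz], [ixz, iyz, izz]])


_LINEAR_TOL = 1e-10  # relative moment threshold below which a top is linear


def rotational_constants(geometry: MolecularGeometry) -> RotationalConstants:
    """Rotational constants from principal moments of inertia.

    B_i = h / (8 π² c I_i), with I about the center of mass.  Invariant
    under rigid translation/rotation of the input and under permutation
    of identical atoms.
    """
    if geometry.n_atoms < 2:
        raise DegenerateGeometryError("rotational constants need at least two atoms")
    moments = np.linalg.eigvalsh(_inertia_tensor(geometry))  # ascending, u Å²
    moments_si = moments * ATOMIC_MASS_U * ANGSTROM**2
    scale = PLANCK_H / (8 * np.pi**2 * SPEED_OF_LIGHT)  # -> 1/m
    with np.errstate(divide="ignore"):
        consts = scale / moments_si / 100.0  # cm⁻¹, descending where defined
    if moments[0] <= _LINEAR_TOL * max(moments[-1], 1e-30):
        b = float(consts[1])
        return RotationalConstants(A=float("nan"), B=b, C=b, linear=True)
    return RotationalConstants(
        A=float(consts[0]), B=float(consts[1]), C=float(consts[2])
    )


# ---------------------------------------------------------------------------
# connectivity


@dataclass
class ConnectivityGraph:
    """Bond graph from a covalent-radius distance criterion.

    Two atoms bond when their distance is ≤ scale × (r_cov(i) + r_cov(j)).
    Used as a cheap structural fingerprint: fragment count, small rings,
    and the map of which heavy atom each hydrogen sits on.
    """

    graph: nx.Graph
    elements: tuple[str, ...]
    scale: float

    @property
    def n_fragments(self) -> int:
        return nx.number_connected_components(self.graph)

    @property
    def rings(self) -> list[frozenset[int]]:
        return [frozenset(c) for c in nx.cycle_basis(self.graph)]

    @property
    def hydrogen_attachment(self) -> dict[int, frozenset[int]]:
        """Heavy-atom index -> set of attached hydrogen indices."""
        out: dict[int, set[int]] = {
            i: set() for i, e in enumerate(self.elements) if e not in ("H", "D")
        }
        for i, e in enumerate(self.elements):
            if e in ("H", "D"):
                for j in self.graph.neighbors(i):
                    if self.elements[j] not in ("H", "D"):
                        out[j].add(i)
        return {k: frozenset(v) for k, v in out.items()}

    def degree_profile(self) -> tuple[tuple[str, int], ...]:
        """Sorted (element, degree) multiset — a permutation-invariant key."""
        return tuple(
            sorted((self.elements[i], d) for i, d in self.graph.degree())
        )


def perceive_connectivity(
    geometry: MolecularGeometry, scale: float = 1.2
) -> ConnectivityGraph:
    """Perceive bonds from interatomic distances and covalent radii."""
    if not 0.8 < scale < 1.6:
        raise ValueError("scale must lie in (0.8, 1.6)")
    g = nx.Graph()
    g.add_nodes_from(range(geometry.n_atoms))
    radii = np.array([covalent_radius(e) for e in geometry.elements])
    diff = geometry.coords[:, None, :] - geometry.coords[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    cutoff = scale * (radii[:, None] + radii[None, :])
    ii, jj = np.nonzero(np.triu(dist <= cutoff, k=1))
    g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    return ConnectivityGraph(graph=g, elements=geometry.elements, scale=scale)


def classify_byproduct(
    candidate: ConnectivityGraph, reference: ConnectivityGraph
) -> str:
    """Classify an optimized structure against the target topology.

    Returns one of ``target``, ``broken``, ``cyclized``, ``rearranged``:
    more fragments than the reference means a detached leaving group
    (broken); a connected structure with a ring the reference lacks is
    cyclized; connected and acyclic but with a different atom-attachment
    pattern is rearranged; otherwise the candidate is the target.
    Decided purely from topology — relative energy is deliberately not
    consulted because the energy gap between target and byproduct
    structures is not reliable.
    """
    if len(candidate.elements) != len(reference.elements) or sorted(
        candidate.elements
    ) != sorted(reference.elements):
        raise IncomparableSpeciesError(
            "candidate and reference must share atom count and element multiset"
        )
    if candidate.n_fragments > reference.n_fragments:
        return "broken"
    ref_ring_count = len(reference.rings)
    if len(candidate.rings) > ref_ring_count:
        return "cyclized"
    if _attachment_signature(candidate) != _attachment_signature(reference):
        return "rearranged"
    return "target"


def _attachment_signature(cg: ConnectivityGraph):
    """Permutation-invariant summary of hydrogen counts and heavy-atom bonds."""
    h_counts = sorted(
        (cg.elements[k], len(v)) for k, v in cg.hydrogen_attachment.items()
    )
    heavy_edges = sorted(
        tuple(sorted((cg.elements[u], cg.elements[v])))
        for u, v in cg.graph.edges()
        if cg.elements[u] not in ("H", "D") and cg.elements[v] not in ("H", "D")
    )
    return (h_counts, heavy_edges, cg.degree_profile())


# ---------------------------------------------------------------------------
# protonation-variant construction

#: trial bond length (Å) of the added proton by site — a starting guess
#: for downstream optimization, not a converged bond length.
PROTON_TRIAL_BOND = {"amino": 1.02, "carbonyl": 0.98, "hydroxyl": 0.98, "thiol": 1.35}


def _find_site(cg: ConnectivityGraph, site: str) -> tuple[int, list[int]]:
    """Locate the site atom (the atom that receives the proton) and its
    bonded neighbours.  Raises MissingSiteError when absent."""
    els = cg.elements
    hmap = cg.hydrogen_attachment
    for i, e in enumerate(els):
        nbrs = list(cg.graph.neighbors(i))
        heavy = [j for j in nbrs if els[j] not in ("H", "D")]
        nh = len(hmap.get(i, ()))
        if site == "amino" and e == "N" and nh >= 2:
            return i, nbrs
        if site == "thiol" and e == "S" and nh == 1:
            return i, nbrs
        if site == "hydroxyl" and e == "O" and nh == 1 and len(heavy) == 1:
            return i, nbrs
        if site == "carbonyl" and e == "O" and nh == 0 and len(heavy) == 1:
            # carbonyl O: bonded to a carbon that also carries another O
            c = heavy[0]
            if els[c] == "C" and any(
                els[k] == "O" and k != i for k in cg.graph.neighbors(c)
            ):
                return i, nbrs
    raise MissingSiteError(f"no {site} site found")


def attach_proton(
    geometry: MolecularGeometry,
    site: str,
    variant: int = 1,
    scale: float = 1.2,
) -> MolecularGeometry:
    """Build a trial protonated structure at a named functional group.

    Two variants are generated per site, differing as follows: for the
    hydroxyl and thiol groups the two H–O–H / H–S–H planes are
    perpendicular; for the amino group the added N–H is rotated by 60°
    about the C–N axis; for the carbonyl the new O–H is placed cis
    versus trans with respect to the C–O single bond.

    The proton is appended as the last atom at the site's trial bond
    length along a lone-pair direction; the total charge is incremented.
    """
    if site not in PROTON_TRIAL_BOND:
        raise ValueError(f"unknown protonation site {site!r}")
    if variant not in (1, 2):
        raise ValueError("variant must be 1 or 2")
    cg = perceive_connectivity(geometry, scale=scale)
    i, nbrs = _find_site(cg, site)
    pos = geometry.coords[i]
    bond = PROTON_TRIAL_BOND[site]
    nbr_vecs = [geometry.coords[j] - pos for j in nbrs]

    if site == "amino":
        # lone pair points opposite the mean of the three N bonds
        lone = -np.sum([v / np.linalg.norm(v) for v in nbr_vecs], axis=0)
        lone /= np.linalg.norm(lone)
        heavy = [j for j in nbrs if geometry.elements[j] not in ("H", "D")]
        axis = pos - geometry.coords[heavy[0]] if heavy else np.array([0.0, 0.0, 1.0])
        if variant == 2:
            lone = _rotation_matrix(axis, np.radians(60.0)) @ lone
        direction = lone
    elif site == "carbonyl":
        c = [j for j in nbrs if geometry.elements[j] not in ("H", "D")][0]
        co = pos - geometry.coords[c]
        co /= np.linalg.norm(co)
        # the other oxygen on the carbonyl carbon fixes the cis reference
        other_o = [
            k
            for k in cg.graph.neighbors(c)
            if geometry.elements[k] == "O" and k != i
        ][0]
        ref = geometry.coords[other_o] - geometry.coords[c]
        in_plane = ref - np.dot(ref, co) * co
        in_plane /= np.linalg.norm(in_plane)
        ang = np.radians(60.0)  # ~120° O=C–H angle from the C–O axis
        direction = np.cos(ang) * co + np.sin(ang) * (
            in_plane if variant == 1 else -in_plane
        )
    else:  # hydroxyl, thiol: existing bonds are one heavy atom and one H
        els = geometry.elements
        h_j = [j for j in nbrs if els[j] in ("H", "D")][0]
        c_j = [j for j in nbrs if els[j] not in ("H", "D")][0]
        u = geometry.coords[h_j] - pos
        u /= np.linalg.norm(u)
        vc = geometry.coords[c_j] - pos
        vc /= np.linalg.norm(vc)
        w1 = vc - np.dot(vc, u) * u  # in the C–X–H plane
        w1 /= np.linalg.norm(w1)
        w2 = np.cross(u, w1)
        # both variants make the same H–X–H angle with the existing H;
        # their H–X–H planes (each spanned by u and one frame vector)
        # are exactly perpendicular.
        ang = np.radians(95.0)
        w = -w1 if variant == 1 else w2
        direction = np.cos(ang) * u + np.sin(ang) * w
    direction = direction / np.linalg.norm(direction)
    new_coords = np.vstack([geometry.coords, pos + bond * direction])
    return MolecularGeometry(
        elements=(*geometry.elements, "H"),
        coords=new_coords,
        charge=geometry.charge + 1,
        masses=(*geometry.masses, mass_of("H")),
        label=f"{geometry.label}+H({site},v{variant})" if geometry.label else f"+H({site},v{variant})",
    )
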