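"""Symmetry-reduced torsional grid enumeration, optimization sweeps,
stationary-point filtering, and conformer deduplication.

The grid over k torsions has Π_j (period_j / step_j) points, halved
once when any torsion carries a local mirror plane.  Two optimized
structures count as the *same* conformer only when both their relative
energies agree within ``e_tol`` (default 0.01 kcal/mol) and their A
rotational constants agree within ``a_tol`` (default 3×10⁻⁴ cm⁻¹);
merging is the transitive closure of that relation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

from .geometry import (
    MolecularGeometry,
    RotationalConstants,
    TorsionSpec,
    rotational_constants,
    set_dihedral,
)

DEFAULT_E_TOL = 0.01  # kcal/mol
DEFAULT_A_TOL = 3e-4  # cm^-1


class InvalidGridError(ValueError):
    pass


class UnevaluatedEntryError(ValueError):
    """Frequency data required but absent."""


@dataclass(frozen=True)
class TorsionGrid:
    """Lazily enumerable direct product of torsion angle grids."""

    torsions: tuple[TorsionSpec, ...]

    @property
    def n_points(self) -> int:
        """Π over torsions of (period/step), halved once for a mirror.

        The halving acts on the first mirror-equivalent torsion's own
        axis (its grid cannot shrink below one point).
        """
        n = 1
        mirror_done = False
        for t in self.torsions:
            k = t.n_grid_points
            if t.mirror_equivalent and not mirror_done:
                k = max(1, k // 2)
                mirror_done = True
            n *= k
        return n

    def points(self) -> Iterator[tuple[float, ...]]:
        """Angle tuples in lexicographic order.

        The mirror reduction halves the range of the first
        mirror-flagged torsion: angles ≥ period/2 on that coordinate are
        mirror images of retained points.
        """
        axes: list[list[float]] = []
        mirror_done = False
        for t in self.torsions:
            n = t.n_grid_points
            vals = [i * t.step_deg for i in range(n)]
            if t.mirror_equivalent and not mirror_done:
                vals = vals[: max(1, n // 2)]
                mirror_done = True
            axes.append(vals)
        yield from itertools.product(*axes)


def enumerate_grid(torsions: Sequence[TorsionSpec]) -> TorsionGrid:
    """Build the symmetry-reduced torsional start grid.

    Five 60°/360° torsions give 6⁵ = 7776 starts; replacing one rotor by
    a C3v top (period 120°) gives 6⁴·2 = 2592; six rotors with one
    mirror-equivalent torsion give 6⁶/2 = 23 328.
    """
    grid = TorsionGrid(torsions=tuple(torsions))
    for t in grid.torsions:
        t.n_grid_points  # raises InvalidTorsionError if step/period mismatch
    return grid


@dataclass
class SearchRecord:
    """Outcome of optimizing one grid start."""

    start_point: tuple[float, ...]
    converged: bool
    final_energy: float = float("nan")
    final_geometry: MolecularGeometry | None = None
    assigned_conformer: int | None = None

    def __post_init__(self) -> None:
        if not self.converged and self.assigned_conformer is not None:
            raise ValueError("only converged records may carry a conformer id")


@dataclass
class ConformerEntry:
    """A distinct conformer with its dedup fingerprint and bookkeeping."""

    id: int
    geometry: MolecularGeometry | None
    relative_energy: float  # kcal/mol vs current set minimum
    A_constant: float  # cm^-1
    n_imaginary: int | None = None
    occurrences: dict[str, int] = field(default_factory=dict)

    @property
    def total_occurrences(self) -> int:
        return sum(self.occurrences.values())


def run_search(
    seed: MolecularGeometry,
    grid: TorsionGrid,
    backend,
    source: str = "grid",
) -> list[SearchRecord]:
    """Optimize every grid start with *backend* and record the outcomes.

    Backend failures and non-convergence are recorded (``converged=False``)
    and never abort the sweep; occurrence statistics later count only
    converged records.
    """
    records: list[SearchRecord] = []
    for point in grid.points():
        geom = seed
        try:
            for t, ang in zip(grid.torsions, point):
                geom = set_dihedral(geom, t, ang)
            opt_geom, energy, converged = backend.optimize(geom)
        except Exception:
            records.append(SearchRecord(start_point=point, converged=False))
            continue
        records.append(
            SearchRecord(
                start_point=point,
                converged=bool(converged),
                final_energy=float(energy),
                final_geometry=opt_geom if converged else None,
            )
        )
    return records


def collect_conformers(
    records: Iterable[SearchRecord],
    e_tol: float = DEFAULT_E_TOL,
    a_tol: float = DEFAULT_A_TOL,
    source: str = "grid",
) -> tuple[list[ConformerEntry], list[SearchRecord]]:
    """Cluster converged search records into conformers.

    Assigns each converged record a conformer id (mutating the records)
    and returns the deduplicated entries sorted by relative energy.
    """
    records = list(records)
    conv = [r for r in records if r.converged]
    if not conv:
        return [], records
    e_min = min(r.final_energy for r in conv)
    raw: list[ConformerEntry] = []
    for r in conv:
        A = rotational_constants(r.final_geometry).A
        raw.append(
            ConformerEntry(
                id=len(raw),
                geometry=r.final_geometry,
                relative_energy=r.final_energy - e_min,
                A_constant=A,
                occurrences={source: 1},
            )
        )
    clustered = deduplicate(raw, e_tol=e_tol, a_tol=a_tol)
    # map each record to its cluster via the same similarity rule
    for r in conv:
        rel = r.final_energy - e_min
        A = rotational_constants(r.final_geometry).A
        best = min(
            clustered,
            key=lambda c: (abs(c.relative_energy - rel), abs(c.A_constant - A)),
        )
        r.assigned_conformer = best.id
    for c in clustered:
        c.occurrences = {source: 0}
    for r in conv:
        by_id = {c.id: c for c in clustered}
        by_id[r.assigned_conformer].occurrences[source] += 1
    return clustered, records


def _same_conformer(a: ConformerEntry, b: ConformerEntry, e_tol: float, a_tol: float) -> bool:
    # "different if ΔE differs by ≥ e_tol and/or A deviates by > a_tol"
    # ⇔ same iff both fingerprints agree within tolerance.
    return (
        abs(a.relative_energy - b.relative_energy) < e_tol
        and abs(a.A_constant - b.A_constant) <= a_tol
    )


def deduplicate(
    entries: Sequence[ConformerEntry],
    e_tol: float = DEFAULT_E_TOL,
    a_tol: float = DEFAULT_A_TOL,
) -> list[ConformerEntry]:
    """Merge near-identical conformers by energy and A-constant fingerprint.

    Entries merge when their relative energies differ by less than
    ``e_tol`` AND their A constants by at most ``a_tol``; clusters are
    the transitive closure of this relation (union-find).  The cluster
    representative is the lowest-energy member; relative energies are
    re-zeroed on the surviving minimum and the merge repeats until a
    fixed point, so the result is idempotent.
    """
    if e_tol <= 0 or a_tol <= 0:
        raise ValueError("tolerances must be positive")
    current = [replace(e) for e in entries]
    while True:
        merged = _merge_pass(current, e_tol, a_tol)
        if len(merged) == len(current):
            break
        current = merged
    # renumber by energy order
    current.sort(key=lambda e: e.relative_energy)
    for new_id, e in enumerate(current):
        e.id = new_id
    return current


def _merge_pass(entries, e_tol, a_tol):
    n = len(entries)
    if n == 0:
        return []
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    e_min = min(e.relative_energy for e in entries)
    rel = [e.relative_energy - e_min for e in entries]
    for i in range(n):
        for j in range(i + 1, n):
            if (
                abs(rel[i] - rel[j]) < e_tol
                and abs(entries[i].A_constant - entries[j].A_constant) <= a_tol
            ):
                union(i, j)
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    out: list[ConformerEntry] = []
    for members in clusters.values():
        rep_idx = min(members, key=lambda i: entries[i].relative_energy)
        rep = replace(entries[rep_idx])
        occ: dict[str, int] = {}
        for i in members:
            for k, v in entries[i].occurrences.items():
                occ[k] = occ.get(k, 0) + v
        rep.occurrences = occ
        rep.relative_energy = rel[rep_idx]
        out.append(rep)
    return out


def filter_minima(entries: Sequence[ConformerEntry]) -> list[ConformerEntry]:
    """Keep true minima (no imaginary harmonic modes).

    Entries lacking frequency data raise rather than pass silently:
    minima and transition states cannot be told apart without a Hessian.
    """
    for e in entries:
        if e.n_imaginary is None:
            raise UnevaluatedEntryError(
                f"conformer {e.id} has no frequency data; cannot separate "
                "minima from transition states"
            )
    return [e for e in entries if e.n_imaginary == 0]
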