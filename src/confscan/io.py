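"""File formats and the pipeline driver.

Geometries travel as standard XYZ (two header lines, element symbols,
Å); torsion definitions as YAML; energy ledgers and reports as CSV
with a units row under the header.  ``run_pipeline`` chains the stages
(enumerate → search → dedup → frequencies → thermo report) on a named
backend and writes a manifest so a run is reproducible from its config
and seed alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .composite import EnergyLedger
from .constants import mass_of
from .geometry import MolecularGeometry, TorsionSpec
from .search import DEFAULT_A_TOL, DEFAULT_E_TOL


class XYZFormatError(ValueError):
    pass


def read_xyz(path) -> MolecularGeometry:
    """Read one geometry from an XYZ file (coordinates in Å)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise XYZFormatError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise XYZFormatError(f"{path}: first line must be the atom count") from None
    if len(lines) < n + 2:
        raise XYZFormatError(f"{path}: expected {n} atom lines, file too short")
    comment = lines[1].strip()
    elements, coords = [], []
    for ln in lines[2 : 2 + n]:
        parts = ln.split()
        if len(parts) < 4:
            raise XYZFormatError(f"{path}: malformed atom line {ln!r}")
        el = parts[0].capitalize()
        mass_of(el)  # raises on unknown element
        elements.append(el)
        coords.append([float(x) for x in parts[1:4]])
    return MolecularGeometry(
        elements=tuple(elements), coords=np.array(coords), label=comment
    )


def write_xyz(geometry: MolecularGeometry, path) -> None:
    lines = [str(geometry.n_atoms), geometry.label or ""]
    for el, xyz in zip(geometry.elements, geometry.coords):
        lines.append(f"{el:2s} {xyz[0]:15.8f} {xyz[1]:15.8f} {xyz[2]:15.8f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_torsions(path) -> list[TorsionSpec]:
    """Load torsion definitions from a YAML file."""
    data = yaml.safe_load(Path(path).read_text())
    specs = []
    for entry in data["torsions"]:
        specs.append(
            TorsionSpec(
                axis=tuple(entry["axis"]),
                dihedral_atoms=tuple(entry["dihedral_atoms"]),
                moving_set=frozenset(entry["moving_set"]),
                step_deg=float(entry.get("step_deg", 60.0)),
                symmetry_period_deg=float(entry.get("symmetry_period_deg", 360.0)),
                mirror_equivalent=bool(entry.get("mirror_equivalent", False)),
            )
        )
    return specs


# ---------------------------------------------------------------------------
# ledger / report CSV (header + units row + data)


def read_table(path) -> pd.DataFrame:
    """Read a CSV whose second row lists units; units land in ``df.attrs``."""
    df = pd.read_csv(path, dtype=str)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    units = df.iloc[0]
    if not any("/" in str(u) for u in units if isinstance(u, str)):
        # no units row — plain CSV
        units = None
        body = df
    else:
        body = df.iloc[1:].reset_index(drop=True)
    if body.empty:
        raise ValueError(f"{path}: no data rows below the units row")
    out = pd.DataFrame()
    for col in body.columns:
        try:
            out[col] = pd.to_numeric(body[col])
        except (ValueError, TypeError):
            out[col] = body[col]
    if units is not None:
        out.attrs["units"] = {c: units[c] for c in df.columns}
    return out


def write_table(df: pd.DataFrame, path, units: dict[str, str] | None = None) -> None:
    """Write a CSV with an optional units row under the header."""
    path = Path(path)
    if units:
        header = ",".join(df.columns)
        unit_row = ",".join(str(units.get(c, "")) for c in df.columns)
        body = df.to_csv(index=False, header=False)
        path.write_text(header + "\n" + unit_row + "\n" + body)
    else:
        df.to_csv(path, index=False)


def read_ledger(path, relative: bool = True) -> EnergyLedger:
    """Read an energy-ledger CSV into an :class:`EnergyLedger`."""
    df = read_table(path)
    if "name" not in df.columns:
        raise KeyError(f"{path}: ledger must have a 'name' column")
    return EnergyLedger(df, relative=relative)


# ---------------------------------------------------------------------------
# packaged fixtures

_FIXTURES = {
    "neutral": "table2_neutral.csv",
    "N": "table3_n_protonated.csv",
    "O": "table4_o_protonated.csv",
    "S": "table5_s_protonated.csv",
    "pa_gb": "table6_pa_gb.csv",
}


def fixture_path(key: str) -> Path:
    """Path of a packaged fixture table ('neutral', 'N', 'O', 'S', 'pa_gb')."""
    try:
        name = _FIXTURES[key]
    except KeyError:
        raise KeyError(f"unknown fixture {key!r}; choose from {sorted(_FIXTURES)}")
    return Path(resources.files("confscan.data") / name)


def load_benchmark_table(key: str) -> pd.DataFrame:
    """Load a packaged benchmark table as a DataFrame."""
    return read_table(fixture_path(key))


def load_benchmark_ledger(key: str) -> EnergyLedger:
    """Load a packaged benchmark table as a relative EnergyLedger."""
    return read_ledger(fixture_path(key), relative=True)


def load_seed_geometry() -> MolecularGeometry:
    """The packaged synthetic cysteine seed geometry (14 atoms)."""
    return read_xyz(Path(resources.files("confscan.data") / "cysteine_seed_synthetic.xyz"))


def load_seed_torsions() -> list[TorsionSpec]:
    """Torsion definitions matching the packaged seed geometry."""
    return read_torsions(Path(resources.files("confscan.data") / "cysteine_torsions.yaml"))


# ---------------------------------------------------------------------------
# pipeline driver


@dataclass
class RunConfig:
    """End-to-end run parameters; serialized verbatim into the manifest."""

    temperature: float = 298.15  # K
    pressure: float = 1.0e5  # Pa
    e_tol: float = DEFAULT_E_TOL  # kcal/mol
    a_tol: float = DEFAULT_A_TOL  # cm^-1
    grid_step: float = 60.0  # degrees
    backend: str = "toy"
    seed: int = 0
    n_torsions: int = 2
    outdir: str = "confscan_run"

    def __post_init__(self) -> None:
        for name in ("temperature", "pressure", "e_tol", "a_tol", "grid_step"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run enumerate → search → dedup → frequency filter → thermo report
    on the toy backend and return the manifest.

    The toy run uses a synthetic chain geometry with ``n_torsions``
    rotatable bonds and a seeded random multi-well torsional potential,
    so identical config + seed gives byte-identical outputs.
    """
    from .backends import ToyTorsionalBackend, random_pes, toy_chain_geometry
    from .search import collect_conformers, enumerate_grid, filter_minima, run_search

    if config.backend != "toy":
        raise ValueError(f"unknown backend {config.backend!r}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []

    geom, torsions = toy_chain_geometry(config.n_torsions)
    torsions = tuple(
        TorsionSpec(
            axis=t.axis,
            dihedral_atoms=t.dihedral_atoms,
            moving_set=t.moving_set,
            step_deg=config.grid_step,
        )
        for t in torsions
    )
    grid = enumerate_grid(torsions)
    stages.append(f"enumerate: {grid.n_points} starts")

    pes = random_pes(config.n_torsions, seed=config.seed)
    backend = ToyTorsionalBackend(pes=pes, torsions=torsions)
    records = run_search(geom, grid, backend)
    n_conv = sum(r.converged for r in records)
    stages.append(f"search: {n_conv}/{len(records)} converged")
    rec_df = pd.DataFrame(
        {
            "start_point": [";".join(f"{a:g}" for a in r.start_point) for r in records],
            "converged": [r.converged for r in records],
            "final_energy": [r.final_energy for r in records],
        }
    )
    write_table(rec_df, outdir / "search_records.csv",
                units={"final_energy": "kcal/mol"})

    conformers, records = collect_conformers(
        records, e_tol=config.e_tol, a_tol=config.a_tol
    )
    stages.append(f"dedup: {len(conformers)} conformers")
    for c in conformers:
        c.n_imaginary = backend.n_imaginary(c.geometry)
    minima = filter_minima(conformers)
    stages.append(f"minima: {len(minima)} of {len(conformers)}")
    conf_df = pd.DataFrame(
        {
            "id": [c.id for c in conformers],
            "relative_energy": [c.relative_energy for c in conformers],
            "A_constant": [c.A_constant for c in conformers],
            "n_imaginary": [c.n_imaginary for c in conformers],
            "occurrences": [c.total_occurrences for c in conformers],
        }
    )
    write_table(conf_df, outdir / "conformers.csv",
                units={"relative_energy": "kcal/mol", "A_constant": "cm-1"})

    manifest = {
        "version": __version__,
        "config": asdict(config),
        "config_hash": config.digest(),
        "stages": stages,
        "n_starts": grid.n_points,
        "n_converged": n_conv,
        "n_conformers": len(conformers),
        "n_minima": len(minima),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
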