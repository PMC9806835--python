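"""Focal-point assembly of benchmark energies.

A benchmark (composite) electronic energy is built as a large-basis
explicitly-correlated coupled-cluster value plus additive small-basis
corrections:

    E_e  = E[CCSD(T)-F12b/QZ] + Δ_core + Δ_rel + δT + δ(Q)
    H_0  = E_e + ΔZPE

with δT = CCSDT − CCSD(T), δ(Q) = CCSDT(Q) − CCSDT (small basis),
Δ_core = all-electron − frozen-core, and Δ_rel the second-order
Douglas–Kroll relativistic shift (DK − non-DK).  The ledger carries
the per-conformer single-point energies these differences are taken
from; printed tables that only list the corrections are accepted too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import HARTREE_TO_KCAL


class MissingColumnError(KeyError):
    pass


class LedgerConventionError(ValueError):
    """Absolute/relative flags mixed or inconsistent with the data."""


#: raw single-point columns (kcal/mol relative, or hartree absolute)
RAW_COLUMNS = (
    "E_mp2_avdz",
    "E_cc_dz_mp2geom",
    "E_cc_dz",
    "E_cc_tz",
    "E_cc_qz_f12a",
    "E_cc_qz_f12b",
    "E_ae_cvtz",
    "E_fc_cvtz",
    "E_dk",
    "E_nodk",
    "E_ccsd_t_631g",
    "E_ccsdt_631g",
    "E_ccsdt_q_631g",
)

#: pre-computed correction columns, the form benchmark tables print
DIRECT_COLUMNS = ("d_core", "d_rel", "d_T", "d_Q")

ENERGY_COLUMNS = RAW_COLUMNS + DIRECT_COLUMNS + ("zpe",)


@dataclass
class EnergyLedger:
    """Per-conformer single-point energies and corrections.

    ``relative=True`` means every energy column is already relative to
    the first conformer (which must then be zero in each energy column
    present); ``relative=False`` means absolute energies in hartree,
    converted to kcal/mol on ingest.  Columns the schema does not know
    are preserved untouched.
    """

    table: pd.DataFrame
    relative: bool = True

    def __post_init__(self) -> None:
        df = self.table.copy()
        if "name" not in df.columns:
            df.insert(0, "name", [f"conf{i+1}" for i in range(len(df))])
        if df.empty:
            raise LedgerConventionError("empty ledger")
        if not self.relative:
            for col in df.columns:
                if col in RAW_COLUMNS:
                    df[col] = df[col] * HARTREE_TO_KCAL
            self.relative = False
        else:
            first = df.iloc[0]
            for col in df.columns:
                if col in RAW_COLUMNS and abs(float(first[col])) > 1e-9:
                    raise LedgerConventionError(
                        f"relative ledger must have the first conformer at 0 "
                        f"in column {col!r} (found {first[col]})"
                    )
        self.table = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def names(self) -> list[str]:
        return list(self.table["name"])

    def _col(self, name: str) -> np.ndarray:
        if name not in self.table.columns:
            raise MissingColumnError(
                f"ledger is missing required column {name!r}"
            )
        return self.table[name].to_numpy(dtype=float)

    def has(self, *names: str) -> bool:
        return all(n in self.table.columns for n in names)


def _difference(ledger: EnergyLedger, hi: str, lo: str, direct: str) -> np.ndarray:
    """hi − lo from raw columns, falling back to a printed correction column."""
    if ledger.has(hi, lo):
        return ledger._col(hi) - ledger._col(lo)
    if ledger.has(direct):
        return ledger._col(direct)
    raise MissingColumnError(
        f"ledger has neither raw columns ({hi!r}, {lo!r}) nor the "
        f"direct correction column {direct!r}"
    )


def post_T_corrections(ledger: EnergyLedger) -> tuple[np.ndarray, np.ndarray]:
    """Beyond-perturbative-triples corrections, small basis.

    δT = CCSDT − CCSD(T);  δ(Q) = CCSDT(Q) − CCSDT.
    """
    delta_T = _difference(ledger, "E_ccsdt_631g", "E_ccsd_t_631g", "d_T")
    delta_Q = _difference(ledger, "E_ccsdt_q_631g", "E_ccsdt_631g", "d_Q")
    return delta_T, delta_Q


def core_correction(ledger: EnergyLedger) -> np.ndarray:
    """Core-correlation correction: all-electron − frozen-core."""
    return _difference(ledger, "E_ae_cvtz", "E_fc_cvtz", "d_core")


def relativistic_correction(ledger: EnergyLedger) -> np.ndarray:
    """Scalar relativistic correction: Douglas–Kroll − non-relativistic."""
    return _difference(ledger, "E_dk", "E_nodk", "d_rel")


def geometry_effect(ledger: EnergyLedger) -> np.ndarray:
    """Energy cost of the cheaper reference geometry.

    Difference of the coupled-cluster DZ energy evaluated at the MP2
    geometry versus at the coupled-cluster geometry.
    """
    if not ledger.has("E_cc_dz_mp2geom", "E_cc_dz"):
        raise MissingColumnError(
            "geometry effect needs columns 'E_cc_dz_mp2geom' and 'E_cc_dz'"
        )
    return ledger._col("E_cc_dz_mp2geom") - ledger._col("E_cc_dz")


@dataclass
class CompositeResult:
    """Assembled benchmark energies, one row per conformer.

    Columns: name, E_qz, delta_core, delta_rel, delta_T, delta_Q, E_e,
    zpe, H_0 — all kcal/mol, relative values re-zeroed on the lowest
    E_e conformer when the source ledger was relative.
    """

    table: pd.DataFrame
    relative: bool

    def __post_init__(self) -> None:
        t = self.table
        if not np.allclose(
            t["E_e"],
            t["E_qz"] + t["delta_core"] + t["delta_rel"] + t["delta_T"] + t["delta_Q"],
            atol=1e-12, rtol=0,
        ):
            raise ValueError("composite invariant violated: E_e != QZ + corrections")
        if not np.allclose(t["H_0"], t["E_e"] + t["zpe"], atol=1e-12, rtol=0):
            raise ValueError("composite invariant violated: H_0 != E_e + ZPE")


def assemble_benchmark(ledger: EnergyLedger) -> CompositeResult:
    """Assemble benchmark electronic and adiabatic (0 K) energies.

    Sums the QZ single-point column with the four additive corrections,
    adds the zero-point correction for H_0, and (for relative ledgers)
    re-zeroes both on the conformer with the lowest E_e.  Re-zeroing
    shifts every conformer equally, so energy differences are exact.
    """
    e_qz = ledger._col("E_cc_qz_f12b")
    d_core = core_correction(ledger)
    d_rel = relativistic_correction(ledger)
    d_T, d_Q = post_T_corrections(ledger)
    zpe = ledger._col("zpe")
    e_e = e_qz + d_core + d_rel + d_T + d_Q
    h_0 = e_e + zpe
    if ledger.relative:
        shift = e_e.min()
        e_qz = e_qz - shift
        e_e = e_e - shift
        h_0 = h_0 - shift
    df = pd.DataFrame(
        {
            "name": ledger.names,
            "E_qz": e_qz,
            "delta_core": d_core,
            "delta_rel": d_rel,
            "delta_T": d_T,
            "delta_Q": d_Q,
            "E_e": e_e,
            "zpe": zpe,
            "H_0": h_0,
        }
    )
    return CompositeResult(table=df, relative=ledger.relative)
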