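"""Boltzmann conformer populations and mixture-averaged proton
affinities / gas-phase basicities.

Populations follow x_i = exp(−ΔG°_rel,i / RT) / Σ_j exp(−ΔG°_rel,j / RT)
with ΔG°_rel relative to the most stable conformer.  Mixture
enthalpies are population-weighted means; the mixture free energy is
the ensemble form −RT ln Σ_i exp(−G_i/RT), which equals the weighted
mean plus the configurational mixing term RT Σ x_i ln x_i.  The
ensemble form (not the bare weighted mean) is what reproduces
benchmark mixture basicities, and the package treats it as the
definition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import R_KCAL


@dataclass(frozen=True)
class PopulationSet:
    """Boltzmann populations of a conformer ensemble at one temperature."""

    names: tuple[str, ...]
    fractions: np.ndarray
    temperature: float
    dG_rel: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.fractions, dtype=float)
        if abs(x.sum() - 1.0) > 1e-12:
            raise ValueError("populations must sum to 1")
        if np.any(x <= 0) or np.any(x > 1):
            raise ValueError("populations must lie in (0, 1]")
        object.__setattr__(self, "fractions", x)
        object.__setattr__(self, "dG_rel", np.asarray(self.dG_rel, dtype=float))


def boltzmann_populations(
    dG_rel: Sequence[float], T: float, names: Sequence[str] | None = None
) -> PopulationSet:
    """Relative populations from relative standard Gibbs free energies.

    Gauge-invariant: adding a constant to every ΔG leaves the fractions
    unchanged (the common shift cancels in the normalization).
    """
    g = np.asarray(dG_rel, dtype=float)
    if g.size == 0:
        raise ValueError("empty conformer set")
    if not np.all(np.isfinite(g)) or T <= 0:
        raise ValueError("finite free energies and positive T required")
    w = np.exp(-(g - g.min()) / (R_KCAL * T))
    x = w / w.sum()
    if names is None:
        names = tuple(f"conf{i+1}" for i in range(g.size))
    return PopulationSet(
        names=tuple(names), fractions=x, temperature=T, dG_rel=g
    )


def mixture_enthalpy(pops: PopulationSet, H_rel: Sequence[float]) -> float:
    """Population-weighted mean relative enthalpy, kcal/mol."""
    h = np.asarray(H_rel, dtype=float)
    if h.shape != pops.fractions.shape:
        raise ValueError("enthalpy column does not align with populations")
    return float(pops.fractions @ h)


def mixture_free_energy(
    pops: PopulationSet, G_rel: Sequence[float], T: float | None = None
) -> float:
    """Ensemble mixture free energy −RT ln Σ exp(−G_i/RT), kcal/mol.

    Includes the configurational (mixing) contribution, so it never
    exceeds the population-weighted mean free energy; for n degenerate
    conformers at G = 0 it equals −RT ln n.
    """
    g = np.asarray(G_rel, dtype=float)
    if g.shape != pops.fractions.shape:
        raise ValueError("free-energy column does not align with populations")
    T = pops.temperature if T is None else T
    if abs(T - pops.temperature) > 1e-9:
        raise ValueError("temperature disagrees with the population set")
    rt = R_KCAL * T
    gmin = g.min()
    return float(gmin - rt * np.log(np.sum(np.exp(-(g - gmin) / rt))))


@dataclass(frozen=True)
class MixtureResult:
    """Site-resolved proton affinity / gas-phase basicity summary."""

    site: str
    flavor: str  # "lowest-conformer" | "mixture"
    PA_0K: float
    PA_298K: float
    GB_298K: float


def site_pa_gb(
    neutral: pd.DataFrame,
    protonated: pd.DataFrame,
    anchor: dict[str, float],
    T: float = 298.15,
    site: str = "",
) -> MixtureResult:
    """Boltzmann-mixture PA/GB for one protonation site.

    *neutral* and *protonated* are per-conformer tables with relative
    columns ``h0``, ``h298`` and ``g298`` (kcal/mol, most stable
    conformer at zero).  *anchor* holds the lowest-conformer pair
    values ``{"pa0": …, "pa298": …, "gb298": …}``.

    One population set per species is formed from its ΔG°_rel column at
    *T*; that set weights both the 0 K and 298.15 K enthalpy columns.
    The mixture then shifts the anchor by the neutral-minus-protonated
    average (enthalpies) or by the ensemble free-energy difference
    (basicity):

        PA_mix  = PA_anchor + ⟨ΔH⟩_B − ⟨ΔH⟩_BH⁺
        GB_mix  = GB_anchor + G_mix(B) − G_mix(BH⁺)
    """
    for df, who in ((neutral, "neutral"), (protonated, "protonated")):
        for col in ("h0", "h298", "g298"):
            if col not in df.columns:
                raise KeyError(f"{who} table is missing column {col!r}")
    for key in ("pa0", "pa298", "gb298"):
        if key not in anchor:
            raise KeyError(f"anchor is missing {key!r}")
    pop_n = boltzmann_populations(neutral["g298"].to_numpy(), T)
    pop_p = boltzmann_populations(protonated["g298"].to_numpy(), T)
    pa0 = anchor["pa0"] + (
        mixture_enthalpy(pop_n, neutral["h0"]) - mixture_enthalpy(pop_p, protonated["h0"])
    )
    pa298 = anchor["pa298"] + (
        mixture_enthalpy(pop_n, neutral["h298"])
        - mixture_enthalpy(pop_p, protonated["h298"])
    )
    gb298 = anchor["gb298"] + (
        mixture_free_energy(pop_n, neutral["g298"])
        - mixture_free_energy(pop_p, protonated["g298"])
    )
    return MixtureResult(
        site=site, flavor="mixture", PA_0K=pa0, PA_298K=pa298, GB_298K=gb298
    )


def pa_gb_report(
    neutral: pd.DataFrame,
    site_tables: dict[str, pd.DataFrame],
    anchors: dict[str, dict[str, float]],
    T: float = 298.15,
) -> pd.DataFrame:
    """Per-site PA/GB report with lowest-conformer and mixture rows.

    *site_tables* maps site labels ("N", "O", "S") to their conformer
    tables; *anchors* maps the same labels to lowest-conformer
    ``{"pa0", "pa298", "gb298"}`` values, which are passed through as
    the lowest-conformer rows.
    """
    rows = []
    for site, prot in site_tables.items():
        a = anchors[site]
        rows.append(
            {
                "pair": f"lowest-{site}",
                "flavor": "lowest-conformer",
                "PA_0K": a["pa0"],
                "PA_298K": a["pa298"],
                "GB_298K": a["gb298"],
            }
        )
        mix = site_pa_gb(neutral, prot, a, T=T, site=site)
        rows.append(
            {
                "pair": f"average-{site}",
                "flavor": "mixture",
                "PA_0K": mix.PA_0K,
                "PA_298K": mix.PA_298K,
                "GB_298K": mix.GB_298K,
            }
        )
    return pd.DataFrame(rows)
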