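# confscan

Tools for mapping amino-acid conformers by systematic torsional
rotation and for turning per-conformer benchmark electronic-structure
energies into proton affinities (PA) and gas-phase basicities (GB) of
conformer mixtures.

The package targets the workflow used in benchmark thermochemistry
studies of gas-phase amino acids such as cysteine:

1. **Conformer mapping.** Starting from a seed geometry, the main
   internal rotations (amino, carboxyl, hydroxyl and thiol groups, and
   the side chain) are rotated on a grid — 60° steps give 6⁵ = 7776
   starts for five rotors. Local symmetry prunes the grid: a protonated
   amino group is a C₃ᵥ top (period 120°, 6⁴ × 2 = 2592 starts) and the
   C₂ᵥ {C(OH)₂} group of a carbonyl-protonated acid halves a six-rotor
   grid to 23 328. Optimized structures are deduplicated by two
   fingerprints: relative energy (0.01 kcal/mol) and the largest
   rotational constant A (3 × 10⁻⁴ cm⁻¹); harmonic frequencies then
   separate minima from transition states, and connectivity graphs
   classify "byproduct" structures (broken / rearranged / cyclized).
2. **Focal-point composite energies.** Benchmark electronic energies
   are assembled as
   `E_e = E[CCSD(T)-F12b/QZ] + Δcore + Δrel + δT + δ(Q)` with
   `δT = CCSDT − CCSD(T)`, `δ(Q) = CCSDT(Q) − CCSDT` (small basis),
   `Δcore = AE − FC`, and the Douglas–Kroll relativistic shift;
   `ΔH₀ = ΔE_e + ΔZPE`.
3. **RRHO thermochemistry and Boltzmann mixtures.** Rigid-rotor /
   harmonic-oscillator state functions give H, S and G per conformer;
   populations follow `x_i = exp(−ΔG°ᵢ/RT)/Σⱼ exp(−ΔG°ⱼ/RT)`. For the
   deprotonation BH⁺ → B + H⁺, `PA = ΔH` and `GB = ΔG`, with the free
   proton contributing H = (5/2)RT (1.48 kcal/mol at 298.15 K) and its
   Sackur–Tetrode entropy. Mixture enthalpies are population-weighted
   means; the mixture free energy is the ensemble form
   `−RT ln Σᵢ exp(−Gᵢ/RT)`, which includes the configurational mixing
   term.

The electronic-structure numbers themselves are *inputs*: the package
reads per-conformer "energy ledgers" (CSV) and ships transcriptions of
the published cysteine benchmark tables as fixtures. A synthetic
backend (analytic multi-well torsional potential + ledger generator)
exercises the full search pipeline without any quantum-chemistry code.

## Worked example

Mixture-averaged PA/GB for N-protonation of cysteine from the packaged
benchmark tables, anchored at the lowest-conformer pair:

```python
from confscan.io import load_benchmark_table
from confscan.mixtures import site_pa_gb

neutral = load_benchmark_table("neutral")     # 10 cysteine conformers
n_prot = load_benchmark_table("N")            # 10 N-protonated conformers
anchor = {"pa0": 214.49, "pa298": 215.79, "gb298": 208.44}

mix = site_pa_gb(neutral, n_prot, anchor, T=298.15, site="N")
print(f"PA(0 K)  = {mix.PA_0K:.2f} kcal/mol")
print(f"PA(298 K) = {mix.PA_298K:.2f} kcal/mol")
print(f"GB(298 K) = {mix.GB_298K:.2f} kcal/mol")
```

```
PA(0 K)  = 215.00 kcal/mol
PA(298 K) = 216.39 kcal/mol
GB(298 K) = 208.18 kcal/mol
```

Conformers above the global minimum raise the neutral ensemble's mean
enthalpy more than the protonated one's, so the mixture PA sits ~0.5
kcal/mol above the lowest-conformer value (215.79 → 216.39 at 298.15
K); the entropy term then lowers GB by PA − GB ≈ 8.2 kcal/mol.

The same machinery is scriptable from the shell:

```sh
confscan enumerate src/confscan/data/cysteine_torsions.yaml
# -> 7776 grid starts from 5 torsions
confscan run --n-torsions 2 --seed 1 --outdir scratch/demo
# -> enumerate/search/dedup/minima stage log + manifest.json
```

## Layout

- `confscan.geometry` — Cartesian geometries, torsion rotation,
  rotational constants, connectivity, protonation variants, byproduct
  classification
- `confscan.search` — grid enumeration, optimization sweeps,
  deduplication, minima filtering
- `confscan.backends` — synthetic torsional potential + ledger
  generator (the stand-in for electronic-structure drivers)
- `confscan.composite` — focal-point energy assembly
- `confscan.thermo` — RRHO state functions, proton thermodynamics,
  single-pair PA/GB
- `confscan.mixtures` — Boltzmann populations and mixture averages
- `confscan.io` / `confscan.cli` — XYZ/CSV/YAML formats, fixtures,
  pipeline driver, `confscan` command

See `docs/methods.md` for the model assumptions and numerical choices.
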