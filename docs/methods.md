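# Methods

## Scope and model

`confscan` implements the data-analysis side of a benchmark
conformer/thermochemistry study of a protonatable amino acid
(cysteine is the packaged example): systematic torsional mapping of
the conformational space, deduplication of optimized structures,
focal-point assembly of composite electronic energies from tabulated
single-point results, rigid-rotor/harmonic-oscillator (RRHO)
statistical thermodynamics, and Boltzmann-mixture proton affinities
(PA) and gas-phase basicities (GB). All quantum-chemistry numbers are
consumed as inputs (CSV ledgers); the package never computes wave
functions.

## Torsional mapping

A torsion is a bond axis (b, c), a measured dihedral (a, b, c, d)
(IUPAC sign convention, reported in (−180°, 180°]) and the set of
atoms rotated rigidly about the axis. The start grid is the direct
product of each torsion's angles, `period/step` points per torsion.
Defaults follow the study conditions: 60° steps and 360° periods
(6⁵ = 7776 starts for the five cysteine rotors), a 120° period for the
C₃ᵥ protonated amino top (6⁴ × 2 = 2592), and a mirror flag that
halves the grid once for the C₂ᵥ {C(OH)₂} group (6⁶/2 = 23 328). The
mirror halving truncates the flagged torsion's own axis to its first
half; for odd point counts it keeps ⌈1⌉…`n//2` points (never fewer
than one), which reduces to the plain "product divided by two" for the
even counts that occur in practice.

Each start is driven to its grid angles and handed to a backend's
optimizer. Non-convergence and backend failures are recorded as data
(`converged=False`), never raised, because occurrence statistics count
only converged starts.

### Deduplication

Two optimized structures are the *same* conformer only if their
relative energies differ by less than 0.01 kcal/mol **and** their A
rotational constants by at most 3 × 10⁻⁴ cm⁻¹ (the published
thresholds; the published phrasing "different if … and/or …" is the
contrapositive of this rule, and same-iff-both-below is the only
reading under which "different" is well defined). Clusters are the
transitive closure of the pairwise relation (union-find); the
representative is the lowest-energy member; relative energies are
re-zeroed on the surviving minimum and merging repeats to a fixed
point, which makes the operation idempotent. Chains of near-duplicates
therefore merge even when their endpoints differ by more than one
tolerance — a deliberate choice, documented rather than hidden,
because no published rule resolves such chains.

Minima are separated from transition states strictly by the count of
imaginary harmonic modes; entries without frequency data raise instead
of passing silently.

### Byproduct classification

Optimized structures that are not the target molecule are classified
purely from bond topology (distance ≤ 1.2 × sum of covalent radii,
Cordero consensus values): more fragments than the reference is
**broken** (a detached SH₂/OH₂/NH₃-type leaving group); a connected
structure with a ring the reference lacks is **cyclized** (the 3- and
4-membered rings seen in practice); connected and acyclic but with a
different hydrogen/heavy-atom attachment pattern is **rearranged**.
Energy is deliberately not consulted: the energy gap between target
conformers and byproducts is known to close for protonated species.

## Focal-point composite energies

The ledger schema carries the raw single-point columns; corrections
are differences of column pairs:

- δT = E[CCSDT/6-31G] − E[CCSD(T)/6-31G]
- δ(Q) = E[CCSDT(Q)/6-31G] − E[CCSDT/6-31G]
- Δcore = E[AE-CCSD(T)-F12a/cc-pCVTZ-F12] − E[FC-…]
- Δrel = E[DK-AE-CCSD(T)/aug-cc-pwCVTZ-DK] − E[non-DK …]

and the benchmark energies are

    E_e = E[CCSD(T)-F12b/cc-pVQZ-F12] + Δcore + Δrel + δT + δ(Q)
    H_0 = E_e + ΔZPE

Printed tables that list only the corrections are accepted through
equivalent direct columns (`d_T`, `d_Q`, `d_core`, `d_rel`). Ledgers
are either all-relative (first conformer pinned to zero in every raw
energy column) or all-absolute (hartree, converted with
627.509474 kcal/mol on ingest); a flag disambiguates. Relative outputs
are re-zeroed on the lowest-E_e conformer; the shift is common to all
conformers, so differences are exact. The packaged table fixtures
reproduce their printed E_e column within 0.025 kcal/mol, the worst
case for a sum of five columns each rounded to 0.01.

The geometry effect — the cost of using the cheaper MP2 reference
geometry — is the difference between the coupled-cluster DZ energy at
the MP2 geometry and at the coupled-cluster geometry; on the packaged
thiol-protonated table its mean magnitude is ≈0.5 kcal/mol,
an order of magnitude larger than for the other sites.

## RRHO thermochemistry

Ideal gas, one conformer at a time: H_trans = (5/2)RT with
Sackur–Tetrode entropy at 1 bar; H_rot = (3/2)RT with the classical
asymmetric-top entropy at symmetry number 1 (all species are C₁);
harmonic-oscillator vibrational energy and entropy over all modes,
with ZPE = Σνᵢ/2 reported separately so that H(0 K) is the adiabatic
energy. No frequency scaling, no anharmonicity, no hindered-rotor or
quasi-RRHO damping — plain RRHO, with the usual caveat that
low-frequency torsional modes make the 298 K thermal terms the least
certain numbers in the chain. Electronic degeneracy is 1 (closed
shells).

The free proton has H = (5/2)RT — 1.48 kcal/mol at 298.15 K — and
Sackur–Tetrode entropy (26.04 cal mol⁻¹ K⁻¹ at 298.15 K, 1 bar),
fixed by physics rather than fitted. The standard state is 1 bar
throughout; the proton enthalpy is pressure-independent, and 1 bar
reproduces the standard proton entropy.

For BH⁺ → B + H⁺: PA = H(B) + H(H⁺) − H(BH⁺),
GB = G(B) + G(H⁺) − G(BH⁺), and PA − GB = T·ΔS/1000 exactly.

Constants are CODATA-2018, shared through one module:
R = 1.98720425864 × 10⁻³ kcal mol⁻¹ K⁻¹ and
1 cm⁻¹ = 2.85914 × 10⁻³ kcal/mol, so implementation and test oracles
cannot drift apart. Atomic masses are IUPAC standard weights for both
rotational constants and thermochemistry.

## Boltzmann mixtures

Populations: x_i = exp(−ΔG°ᵢ/RT)/Σⱼ exp(−ΔG°ⱼ/RT) over each species'
relative Gibbs energies at 298.15 K; one population set per species is
used for all averaged quantities, including the 0 K enthalpy column
(populations at 0 K would collapse to the global minimum and simply
reproduce the anchor). Mixture enthalpies are population-weighted
means. The mixture free energy is the **ensemble** form

    G_mix = −RT ln Σᵢ exp(−Gᵢ/RT) = ⟨G⟩ + RT Σᵢ xᵢ ln xᵢ,

i.e. the weighted mean plus the (nonpositive) configurational mixing
term. This convention is load-bearing: on the packaged cysteine
tables the ensemble form reproduces the benchmark N-site mixture
basicity within input rounding while the bare weighted mean is ≈0.44
kcal/mol too high; the discriminating computation is kept as a
regression test. Mixture PA/GB are expressed as shifts of the
lowest-conformer anchor pair:

    PA_mix = PA_anchor + ⟨ΔH⟩_B − ⟨ΔH⟩_BH⁺
    GB_mix = GB_anchor + G_mix(B) − G_mix(BH⁺)

Comparisons against the printed tables use 0.05 kcal/mol: the inputs
are printed to two decimals, and the published averages were formed
from unrounded machine values, so closeness, not bit-equality, is the
correct assertion.

## Synthetic backend

The toy potential V(φ) = Σⱼ Σₖ aⱼₖ(1 − cos(kφⱼ − δⱼₖ)) plus weak
pairwise cosine couplings is smooth, 2π-periodic, and has minima
enumerable by dense scan — the properties the search pipeline needs.
Optimization runs in torsion space (BFGS with the analytic gradient,
tolerance 1e-8 kcal/mol), since the purpose is workflow validation,
not molecular mechanics. "Frequencies" are eigenvalues of a
central-difference torsional Hessian (0.5° step) mapped to nominal
wavenumbers by a fixed scale; they preserve the minimum/saddle
distinction (sign) and nothing else — they are explicitly
non-physical. The seeded default surface (three cosine orders per
coordinate, barriers 1–5 kcal/mol) funnels a 36-point, 2-torsion grid
into ~4 wells, mirroring how thousands of real starts collapse into
tens of conformers.

The ledger generator emulates the magnitude structure of benchmark
correction tables: relative energies 0–8 kcal/mol, corrections of
order 0.01–0.1 kcal/mol, and site-dependent ZPE-correction signs
(mixed for amino-protonated species, negative for carbonyl, positive
for thiol, mean magnitude 0.4 kcal/mol). Its raw column pairs are
internally consistent, so the focal-point assembly recovers exactly
the drawn corrections. What the synthetic layer does **not** emulate:
basis-set-specific behaviour, real occurrence statistics, Cartesian
relaxation, or any coupling between torsions and the correction
columns — passing tests demonstrate the pipeline's bookkeeping and
numerics, not chemical accuracy on real surfaces.

## Packaged data

Five CSV fixtures transcribe the published 10-conformer benchmark
tables (neutral and N-/O-/S-protonated cysteine, plus the per-site
PA/GB summary with its lowest-conformer and mixture rows). The seed
geometry `cysteine_seed_synthetic.xyz` is a synthetic stand-in
(RDKit ETKDG + MMFF94) for the literature global-minimum structure;
only formula- and connectivity-level facts about it are asserted. The
torsion file is a best-effort reconstruction of the five driven
rotations — the defining atom quadruples are this package's choice,
as no published list exists.

## Problem sizes and determinism

Unit and acceptance tests run 2-torsion searches (36–144 starts) and
1–2° exhaustive scans, sizes at which the independent oracles
(dense scan, all-pairs transitive closure, closed forms) are exact and
fast; the grid-combinatorics checks cover the full 7776/2592/23 328
counts exactly, since enumeration is lazy. Every stochastic element
(surface generation, ledger noise, optimizer starts) takes an explicit
seed recorded in the run manifest, and identical config + seed yields
byte-identical output CSVs.

## Known limitations

- Dedup uses energy + one rotational constant as the fingerprint;
  genuinely distinct conformers that collide in both (within
  tolerance) would merge. The published thresholds were chosen to make
  this unlikely, not impossible.
- Trial proton placement is a starting guess (fixed bond lengths,
  idealized lone-pair directions), adequate only as optimizer input.
- The RRHO model inherits all its usual failure modes for
  low-frequency torsions; no uncertainty propagation is attempted
  beyond carrying the published ±0.40 (PA) / ±1.20 (GB) kcal/mol as
  context.
- Per-conformer 298.15 K thermal corrections in the packaged tables
  cannot be recomputed from first principles here because the
  underlying harmonic frequencies are not published; the tables are
  used directly.
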