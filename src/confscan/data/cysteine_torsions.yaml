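# Torsion definitions for the packaged synthetic cysteine seed
# (cysteine_seed_synthetic.xyz; atom indices are 0-based into that file:
# 0 N, 1 Ca, 2 Cb, 3 S, 4 C(carboxyl), 5 O(carbonyl), 6 O(hydroxyl),
# 7-8 H(N), 9 H(Ca), 10-11 H(Cb), 12 H(S), 13 H(O)).
#
# Best-effort reconstruction: the five driven internal rotations are the
# amino, carboxyl, hydroxyl and thiol groups and the side chain; the
# exact defining quadruples are a choice of this package.
torsions:
  - name: amino
    axis: [1, 0]
    dihedral_atoms: [4, 1, 0, 7]
    moving_set: [7, 8]
    step_deg: 60.0
    symmetry_period_deg: 360.0
    mirror_equivalent: false
  - name: carboxyl
    axis: [1, 4]
    dihedral_atoms: [0, 1, 4, 5]
    moving_set: [5, 6, 13]
    step_deg: 60.0
    symmetry_period_deg: 360.0
    mirror_equivalent: false
  - name: hydroxyl
    axis: [4, 6]
    dihedral_atoms: [5, 4, 6, 13]
    moving_set: [13]
    step_deg: 60.0
    symmetry_period_deg: 360.0
    mirror_equivalent: false
  - name: sidechain
    axis: [1, 2]
    dihedral_atoms: [0, 1, 2, 3]
    moving_set: [3, 10, 11, 12]
    step_deg: 60.0
    symmetry_period_deg: 360.0
    mirror_equivalent: false
  - name: thiol
    axis: [2, 3]
    dihedral_atoms: [1, 2, 3, 12]
    moving_set: [12]
    step_deg: 60.0
    symmetry_period_deg: 360.0
    mirror_equivalent: false
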