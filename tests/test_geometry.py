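"""Geometry layer: torsion rotation, rotational constants, connectivity,
protonation variants, and byproduct classification."""

import numpy as np
import pytest

from confscan.geometry import (
    DegenerateGeometryError,
    IncomparableSpeciesError,
    InvalidTorsionError,
    MissingSiteError,
    MolecularGeometry,
    TorsionSpec,
    attach_proton,
    classify_byproduct,
    measure_dihedral,
    perceive_connectivity,
    rotate_torsion,
    rotational_constants,
    set_dihedral,
)


def reference_dihedral(p0, p1, p2, p3):
    """Independent dihedral formula (Praxeolitic projection form)."""
    b0, b1, b2 = p0 - p1, p3 - p2, p2 - p1  # note orientation
    b2n = b2 / np.linalg.norm(b2)
    v = b0 - np.dot(b0, b2n) * b2n
    w = b1 - np.dot(b1, b2n) * b2n
    x = np.dot(v, w)
    y = np.dot(np.cross(b2n, v), w)
    return np.degrees(np.arctan2(y, x))


@pytest.fixture
def ethane_like():
    """Staggered X2C-CX2-style 6-atom toy with one torsion."""
    coords = np.array(
        [
            [0.0, 0.0, 0.0],      # C
            [1.54, 0.0, 0.0],     # C
            [-0.5, 1.0, 0.0],     # X on atom 0
            [-0.5, -0.5, 0.9],    # X on atom 0
            [2.04, 1.0, 0.0],     # X on atom 1
            [2.04, -0.5, -0.9],   # X on atom 1
        ]
    )
    geom = MolecularGeometry(elements=("C", "C", "H", "H", "H", "H"), coords=coords)
    torsion = TorsionSpec(
        axis=(0, 1), dihedral_atoms=(2, 0, 1, 4), moving_set=frozenset({4, 5})
    )
    return geom, torsion


class TestRotateTorsion:
    def test_zero_angle_is_identity(self, ethane_like):
        geom, torsion = ethane_like
        out = rotate_torsion(geom, torsion, 0.0)
        np.testing.assert_array_equal(out.coords, geom.coords)

    def test_full_turn_is_identity(self, ethane_like):
        geom, torsion = ethane_like
        out = rotate_torsion(geom, torsion, 360.0)
        np.testing.assert_allclose(out.coords, geom.coords, atol=1e-9)

    @pytest.mark.parametrize("angle", [60.0, -60.0, 17.3, 145.0])
    def test_dihedral_changes_by_requested_angle(self, ethane_like, angle):
        geom, torsion = ethane_like
        before = reference_dihedral(*(geom.coords[i] for i in torsion.dihedral_atoms))
        out = rotate_torsion(geom, torsion, angle)
        after = reference_dihedral(*(out.coords[i] for i in torsion.dihedral_atoms))
        delta = (after - before - angle + 180.0) % 360.0 - 180.0
        assert abs(delta) < 1e-9

    def test_nonmoving_atoms_fixed_and_bonds_rigid(self, ethane_like):
        geom, torsion = ethane_like
        out = rotate_torsion(geom, torsion, 73.0)
        fixed = [i for i in range(geom.n_atoms) if i not in torsion.moving_set]
        np.testing.assert_array_equal(out.coords[fixed], geom.coords[fixed])
        for i in torsion.moving_set:
            for j in torsion.moving_set:
                assert abs(out.distance(i, j) - geom.distance(i, j)) < 1e-10

    def test_composed_full_cycle_returns_start(self, ethane_like):
        geom, torsion = ethane_like
        out = geom
        for _ in range(6):
            out = rotate_torsion(out, torsion, 60.0)
        np.testing.assert_allclose(out.coords, geom.coords, atol=1e-9)

    def test_set_dihedral_hits_target(self, ethane_like):
        geom, torsion = ethane_like
        out = set_dihedral(geom, torsion, 42.0)
        assert abs(measure_dihedral(out, torsion.dihedral_atoms) - 42.0) < 1e-9

    def test_axis_atom_in_moving_set_rejected(self):
        with pytest.raises(InvalidTorsionError):
            TorsionSpec(axis=(0, 1), dihedral_atoms=(2, 0, 1, 4), moving_set=frozenset({1, 4}))

    def test_zero_length_axis_rejected(self, ethane_like):
        geom, torsion = ethane_like
        bad = geom.with_coords(
            np.vstack([geom.coords[0], geom.coords[0], geom.coords[2:]])
        )
        with pytest.raises(DegenerateGeometryError):
            rotate_torsion(bad, torsion, 10.0)


class TestRotationalConstants:
    def test_rigid_transform_invariance(self, cysteine_seed):
        rc = rotational_constants(cysteine_seed)
        theta = 0.7
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0.0],
                [np.sin(theta), np.cos(theta), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        moved = cysteine_seed.with_coords(cysteine_seed.coords @ rot.T + [3.0, -1.0, 2.0])
        rc2 = rotational_constants(moved)
        for a, b in zip((rc.A, rc.B, rc.C), (rc2.A, rc2.B, rc2.C)):
            assert abs(a - b) < 1e-9

    def test_identical_atom_permutation_invariance(self, cysteine_seed):
        rc = rotational_constants(cysteine_seed)
        # swap the two amino hydrogens (indices 7, 8)
        coords = cysteine_seed.coords.copy()
        coords[[7, 8]] = coords[[8, 7]]
        rc2 = rotational_constants(cysteine_seed.with_coords(coords))
        assert abs(rc.A - rc2.A) < 1e-12

    def test_spherical_top_tetrahedron(self):
        verts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float)
        geom = MolecularGeometry(elements=("C",) * 4, coords=verts)
        rc = rotational_constants(geom)
        assert rc.A == pytest.approx(rc.B, abs=1e-10)
        assert rc.B == pytest.approx(rc.C, abs=1e-10)

    def test_diatomic_closed_form(self):
        # B = h / (8 pi^2 c mu r^2) with the same constant set
        r = 0.74  # Å
        geom = MolecularGeometry(
            elements=("H", "H"), coords=np.array([[0.0, 0.0, 0.0], [0.0, 0.0, r]])
        )
        rc = rotational_constants(geom)
        assert rc.linear
        h, c = 6.62607015e-34, 2.99792458e8
        mu = (1.008 / 2) * 1.66053906660e-27
        b_expected = h / (8 * np.pi**2 * c * mu * (r * 1e-10) ** 2) / 100.0
        assert rc.B == pytest.approx(b_expected, rel=1e-12)


class TestConnectivity:
    def test_far_atoms_disconnect(self):
        geom = MolecularGeometry(
            elements=("C", "C"), coords=np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]])
        )
        assert perceive_connectivity(geom).n_fragments == 2

    def test_cysteine_seed_bond_list(self, cysteine_seed):
        """The packaged seed must match its manually enumerated bond list."""
        cg = perceive_connectivity(cysteine_seed)
        expected = {
            (0, 1), (1, 2), (2, 3), (1, 4), (4, 5), (4, 6),
            (0, 7), (0, 8), (1, 9), (2, 10), (2, 11), (3, 12), (6, 13),
        }
        assert {tuple(sorted(e)) for e in cg.graph.edges()} == expected
        assert cg.n_fragments == 1
        assert cg.rings == []

    @pytest.mark.parametrize("s_small,s_large", [(0.9, 1.1), (1.0, 1.3), (1.1, 1.5)])
    def test_edge_set_monotone_in_scale(self, cysteine_seed, s_small, s_large):
        small = set(perceive_connectivity(cysteine_seed, s_small).graph.edges())
        large = set(perceive_connectivity(cysteine_seed, s_large).graph.edges())
        assert small <= large

    def test_scale_bounds_enforced(self, cysteine_seed):
        with pytest.raises(ValueError):
            perceive_connectivity(cysteine_seed, 2.0)


class TestClassifyByproduct:
    def test_self_is_target(self, cysteine_seed):
        cg = perceive_connectivity(cysteine_seed)
        assert classify_byproduct(cg, cg) == "target"

    def test_detached_sh2_is_broken(self, cysteine_seed):
        """SH2 split off 4 Å away: an S–C and an H–C bond break."""
        coords = cysteine_seed.coords.copy()
        # move S, its H, and one beta-H far from the backbone as an SH2 unit
        s = coords[3]
        shift = np.array([4.0, 4.0, 0.0])
        coords[3] = s + shift
        coords[12] = coords[12] + shift
        coords[10] = coords[3] + np.array([0.9, -0.9, 0.0])
        cand = perceive_connectivity(cysteine_seed.with_coords(coords))
        ref = perceive_connectivity(cysteine_seed)
        assert classify_byproduct(cand, ref) == "broken"

    def test_three_membered_ring_is_cyclized(self):
        """A C–C–N triangle plus a distant reference chain."""
        tri = MolecularGeometry(
            elements=("C", "C", "N"),
            coords=np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0], [0.75, 1.3, 0.0]]),
        )
        chain = MolecularGeometry(
            elements=("C", "C", "N"),
            coords=np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0], [3.0, 0.0, 0.0]]),
        )
        assert classify_byproduct(
            perceive_connectivity(tri), perceive_connectivity(chain)
        ) == "cyclized"

    def test_hydrogen_migration_is_rearranged(self, cysteine_seed):
        coords = cysteine_seed.coords.copy()
        # move a beta-carbon hydrogen (10) onto the sulfur: S gets 2 H, C keeps 1
        s_dir = coords[3] - coords[2]
        coords[10] = coords[3] + 1.30 * np.array([0.0, 0.0, 1.0])
        cand = perceive_connectivity(cysteine_seed.with_coords(coords))
        ref = perceive_connectivity(cysteine_seed)
        assert classify_byproduct(cand, ref) == "rearranged"

    def test_atom_count_mismatch_raises(self, cysteine_seed):
        small = MolecularGeometry(
            elements=("C",), coords=np.array([[0.0, 0.0, 0.0]])
        )
        with pytest.raises(IncomparableSpeciesError):
            classify_byproduct(
                perceive_connectivity(small), perceive_connectivity(cysteine_seed)
            )


class TestAttachProton:
    def test_bookkeeping(self, cysteine_seed):
        out = attach_proton(cysteine_seed, "amino", 1)
        assert out.charge == cysteine_seed.charge + 1
        assert out.n_atoms == cysteine_seed.n_atoms + 1
        assert out.elements[-1] == "H"

    def test_four_sites_two_variants_all_distinct(self, cysteine_seed):
        geoms = [
            attach_proton(cysteine_seed, site, v)
            for site in ("amino", "carbonyl", "hydroxyl", "thiol")
            for v in (1, 2)
        ]
        assert len(geoms) == 8
        positions = [tuple(np.round(g.coords[-1], 6)) for g in geoms]
        assert len(set(positions)) == 8

    def test_amino_variants_differ_by_60_degrees(self, cysteine_seed):
        v1 = attach_proton(cysteine_seed, "amino", 1)
        v2 = attach_proton(cysteine_seed, "amino", 2)
        # dihedral of the added H about the C-N axis (Ca=1, N=0)
        d1 = measure_dihedral(v1, (4, 1, 0, v1.n_atoms - 1))
        d2 = measure_dihedral(v2, (4, 1, 0, v2.n_atoms - 1))
        diff = abs((d1 - d2 + 180.0) % 360.0 - 180.0)
        assert diff == pytest.approx(60.0, abs=1e-6)

    def test_thiol_variant_planes_perpendicular(self, cysteine_seed):
        v1 = attach_proton(cysteine_seed, "thiol", 1)
        v2 = attach_proton(cysteine_seed, "thiol", 2)
        s, h_old = cysteine_seed.coords[3], cysteine_seed.coords[12]

        def plane_normal(g):
            h_new = g.coords[-1]
            return np.cross(h_old - s, h_new - s)

        n1, n2 = plane_normal(v1), plane_normal(v2)
        cosang = abs(np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2)))
        assert cosang == pytest.approx(0.0, abs=1e-6)

    def test_missing_site_raises(self):
        methane_ish = MolecularGeometry(
            elements=("C", "H", "H", "H", "H"),
            coords=np.array(
                [[0, 0, 0], [1.09, 0, 0], [-0.36, 1.03, 0], [-0.36, -0.51, 0.89],
                 [-0.36, -0.51, -0.89]], dtype=float
            ),
        )
        with pytest.raises(MissingSiteError):
            attach_proton(methane_ish, "thiol", 1)
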