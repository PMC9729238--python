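"""Structure I/O, superposition, symmetry expansion and GROMOS clustering."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from tfx.structio import (Structure, Trajectory, Transform, c5_expand,
                          gromos_cluster, pairwise_rmsd_matrix, read_structure,
                          superpose, write_structure)

from conftest import simple_structure

PDB_3ATOM = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.513   7.280  -4.870  1.00  0.00           C
END
"""

GRO_2ATOM = """\
toy system
 2
    1ALA      N    1   1.110   0.613  -0.650
    1ALA     CA    2   1.164   0.607  -0.515
   2.50000   3.00000   3.50000
"""


class TestReadWrite:
    def test_pdb_fields_preserved(self, tmp_path):
        p = tmp_path / "three.pdb"
        p.write_text(PDB_3ATOM)
        s = read_structure(p)
        assert len(s) == 3
        assert [a.name for a in s.atoms] == ["N", "CA", "C"]
        assert np.allclose(s.atoms[0].xyz, [11.104, 6.134, -6.504])
        assert all(a.vdw_radius > 0 and a.mhp_const is not None for a in s.atoms)

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("")
        with pytest.raises(ValueError, match="zero"):
            read_structure(p)

    def test_gro_box_converted_nm_to_angstrom(self, tmp_path):
        p = tmp_path / "two.gro"
        p.write_text(GRO_2ATOM)
        s = read_structure(p)
        # hand-conversion oracle: the three box numbers x 10
        assert np.allclose(s.box, [25.0, 30.0, 35.0])
        assert np.allclose(s.atoms[0].xyz, [11.10, 6.13, -6.50])

    def test_pdb_roundtrip_preserves_coordinates(self, tmp_path):
        s = simple_structure([("N", "N", "ALA", 1, "A", (1.234, -2.345, 3.456)),
                              ("CA", "C", "ALA", 1, "A", (0.001, 0.0, -9.999)),
                              ("OG", "O", "SER", 2, "A", (5.5, 4.4, 3.3))])
        path = tmp_path / "rt.pdb"
        write_structure(s, path)
        back = read_structure(path)
        assert np.allclose(back.coords, s.coords, atol=1e-3)
        assert [a.name for a in back.atoms] == [a.name for a in s.atoms]

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            read_structure(tmp_path / "x.xyz", format="xyz")


class TestSuperpose:
    def test_identical_sets_rmsd_zero(self):
        P = np.random.default_rng(0).normal(size=(6, 3))
        _, rmsd = superpose(P, P)
        assert rmsd < 1e-10

    def test_rigid_copy_recovered(self):
        rng = np.random.default_rng(1)
        P = rng.normal(size=(8, 3))
        R = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        Q = P @ R.T + np.array([1.0, 2.0, 3.0])
        tr, rmsd = superpose(P, Q)
        assert rmsd < 1e-10
        assert np.allclose(tr.apply(P), Q, atol=1e-9)

    def test_lifted_square_matches_numeric_minimisation(self):
        """Unit square vs square with one corner lifted 1 A in z."""
        P = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
        Q = P.copy()
        Q[2, 2] = 1.0
        _, rmsd = superpose(P, Q)

        # independent oracle: direct minimisation over rotations+translation
        def cost(theta):
            R = Rotation.from_rotvec(theta[:3]).as_matrix()
            moved = P @ R.T + theta[3:]
            return np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1)))

        best = np.inf
        for seed_rot in ([0, 0, 0], [0.3, 0, 0], [0, 0.3, 0], [0.2, 0.2, 0.2]):
            res = minimize(cost, x0=list(seed_rot) + [0, 0, 0], method="Nelder-Mead",
                           options=dict(xatol=1e-10, fatol=1e-12, maxiter=20000))
            best = min(best, res.fun)
        assert rmsd == pytest.approx(best, abs=1e-5)

    def test_mismatched_and_degenerate_inputs(self):
        with pytest.raises(ValueError):
            superpose(np.zeros((3, 3)), np.zeros((4, 3)))
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
        with pytest.raises(ValueError, match="collinear"):
            superpose(line, line + 1.0)

    @pytest.mark.parametrize("angle,axis", [(25, [0, 0, 1]), (120, [1, 1, 0]),
                                            (310, [0.3, -1, 2])])
    def test_invariant_to_rigid_transform_of_mobile(self, angle, axis):
        rng = np.random.default_rng(5)
        P = rng.normal(size=(10, 3))
        Q = rng.normal(size=(10, 3))
        _, rmsd0 = superpose(P, Q)
        tr = Transform.about_axis(np.array([1.0, 2.0, 3.0]), np.array(axis, dtype=float),
                                  angle)
        _, rmsd1 = superpose(tr.apply(P), Q)
        assert rmsd1 == pytest.approx(rmsd0, abs=1e-6)


class TestC5Expand:
    def _ligand(self, xyz):
        return simple_structure([("CA", "C", "GLY", i + 1, "L",
                                  np.asarray(xyz) + [0, 0, i]) for i in range(3)])

    def test_copies_on_circle_every_72_degrees(self):
        s = self._ligand([30.0, 0.0, 5.0])
        out = c5_expand(s, np.zeros(3), np.array([0, 0, 1.0]))
        assert len(out) == 15
        cents = [out.coords[3 * k:3 * k + 3].mean(axis=0) for k in range(5)]
        radii = [np.hypot(c[0], c[1]) for c in cents]
        assert np.allclose(radii, radii[0])
        angles = np.unwrap([np.arctan2(c[1], c[0]) for c in cents])
        assert np.allclose(np.diff(angles), np.deg2rad(72), atol=1e-6)
        # pentamer centroid lies on the axis
        assert np.allclose(out.centroid()[:2], 0.0, atol=1e-6)

    def test_ligand_on_axis_warns_of_clashes(self):
        s = self._ligand([0.0, 0.0, 5.0])
        with pytest.warns(UserWarning, match="clash|closer"):
            out = c5_expand(s, np.zeros(3), np.array([0, 0, 1.0]))
        cents = np.array([out.coords[3 * k:3 * k + 3].mean(axis=0) for k in range(5)])
        assert np.allclose(cents, cents[0], atol=1e-9)

    def test_first_copy_is_identity(self):
        s = self._ligand([30.0, 0.0, 5.0])
        out = c5_expand(s, np.zeros(3), np.array([0, 0, 1.0]))
        assert np.allclose(out.coords[:3], s.coords, atol=1e-6)
        assert len(set(a.chain for a in out.atoms)) == 5


class TestGromosCluster:
    def _traj(self, frames):
        n_atoms = frames.shape[1]
        top = simple_structure([("CA", "C", "GLY", i + 1, "A", frames[0, i])
                                for i in range(n_atoms)])
        return Trajectory(top, frames)

    def test_two_bundles_recovered(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(5, 3)) * 5
        far = base + np.array([0, 0, 9.0]) + rng.normal(size=(5, 3))  # different shape
        frames = np.array([base + rng.normal(scale=0.05, size=base.shape) for _ in range(4)]
                          + [far + rng.normal(scale=0.05, size=base.shape) for _ in range(3)])
        traj = self._traj(frames)
        res = gromos_cluster(traj, cutoff=0.1, selection=range(5))  # 1 A
        assert len(res.cluster_members) == 2
        assert res.cluster_members[0] == frozenset({0, 1, 2, 3})
        assert res.cluster_members[1] == frozenset({4, 5, 6})

    def test_huge_cutoff_single_cluster(self):
        rng = np.random.default_rng(3)
        frames = rng.normal(size=(6, 4, 3))
        res = gromos_cluster(self._traj(frames), cutoff=100.0, selection=range(4))
        assert len(res.cluster_members) == 1
        assert res.cluster_members[0] == frozenset(range(6))

    def test_matches_bruteforce_neighbour_count_oracle(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(6, 3)) * 4
        frames = np.array([base + rng.normal(scale=0.8, size=base.shape)
                           for _ in range(20)])
        traj = self._traj(frames)
        cutoff_nm = 0.12
        res = gromos_cluster(traj, cutoff_nm, selection=range(6))

        # independent O(n^2) re-implementation of the neighbour-count rule
        mat = pairwise_rmsd_matrix(traj, range(6))
        adj = mat <= cutoff_nm * 10.0
        remaining = set(range(20))
        expected = []
        while remaining:
            rem = sorted(remaining)
            counts = {i: sum(1 for j in rem if adj[i, j]) for i in rem}
            best = max(rem, key=lambda i: (counts[i], -i))
            cluster = frozenset(j for j in rem if adj[best, j])
            expected.append(cluster)
            remaining -= cluster
        expected.sort(key=len, reverse=True)
        assert res.cluster_members == expected

    def test_membership_conserved_and_sizes_sorted(self, toy):
        rng = np.random.default_rng(6)
        frames = rng.normal(size=(12, 5, 3)) * 2
        res = gromos_cluster(self._traj(frames), cutoff=0.4, selection=range(5))
        sizes = [len(m) for m in res.cluster_members]
        assert sizes == sorted(sizes, reverse=True)
        union = frozenset().union(*res.cluster_members)
        assert union == frozenset(range(12))
        assert sum(sizes) == 12  # disjoint
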