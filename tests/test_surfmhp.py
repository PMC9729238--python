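"""SASA, buried area and MHP complementarity."""

import numpy as np
import pytest

from tfx.structio import Transform
from tfx.surfmhp import (buried_area, fibonacci_sphere, mhp_complementarity,
                         sasa)

from conftest import make_atom, simple_structure


def carbon(serial, xyz, res_id=None, chain="A", mhp=0.36):
    return make_atom(serial, "CB", "C", "ALA", res_id or serial, chain,
                     xyz, vdw_radius=1.9 if serial == 0 else None, mhp_const=mhp)


class TestSasa:
    def test_single_sphere_matches_closed_form(self):
        from tfx.structio import Structure

        s = Structure([make_atom(1, "CB", "C", "ALA", 1, "A", (0, 0, 0),
                                 vdw_radius=1.9)])
        res = sasa(s, probe=1.4, n_points=960)
        exact = 4 * np.pi * 3.3 ** 2  # 136.85 A^2
        assert res.total == pytest.approx(exact, rel=0.02)

    def test_two_distant_atoms_additive(self):
        s = simple_structure([("CB", "C", "ALA", 1, "A", (0, 0, 0)),
                              ("CB", "C", "ALA", 2, "A", (100, 0, 0))])
        res = sasa(s)
        single = sasa(s.subset([0]))
        assert res.total == pytest.approx(2 * single.total, rel=1e-9)

    def test_caged_atom_has_zero_area(self):
        entries = [("CB", "C", "ALA", 1, "A", (0.0, 0.0, 0.0))]
        # cage of overlapping spheres on a shell of radius 2.2 A
        shell = 2.2 * fibonacci_sphere(40)
        entries += [("CB", "C", "ALA", 2 + i, "A", tuple(p))
                    for i, p in enumerate(shell)]
        res = sasa(simple_structure(entries))
        assert res.per_atom[0] == 0.0

    def test_total_equals_sum_and_converges(self):
        rng = np.random.default_rng(0)
        s = simple_structure([("CB", "C", "ALA", i + 1, "A", tuple(xyz))
                              for i, xyz in enumerate(rng.normal(scale=3, size=(20, 3)))])
        res = sasa(s, n_points=480)
        assert res.total == pytest.approx(res.per_atom.sum(), abs=1e-6)
        res2 = sasa(s, n_points=960)
        assert abs(res2.total - res.total) / res2.total < 0.01

    def test_agrees_with_independent_reference_implementation(self):
        """Cross-check against biotite's Shrake-Rupley on the same radii."""
        import biotite.structure as struc

        rng = np.random.default_rng(3)
        coords = rng.normal(scale=3, size=(15, 3))
        s = simple_structure([("CB", "C", "ALA", i + 1, "A", tuple(x))
                              for i, x in enumerate(coords)])
        ours = sasa(s, probe=1.4, n_points=960)
        arr = struc.AtomArray(15)
        arr.coord = coords
        arr.element[:] = "C"
        arr.res_name[:] = "ALA"
        arr.atom_name[:] = "CB"
        arr.res_id[:] = np.arange(1, 16)
        arr.chain_id[:] = "A"
        ref = struc.sasa(arr, probe_radius=1.4, point_number=960,
                         vdw_radii="Single").sum()
        assert ours.total == pytest.approx(ref, rel=0.03)


class TestBuriedArea:
    def test_far_ligand_buries_nothing(self):
        s = simple_structure([("CB", "C", "ALA", 1, "L", (0, 0, 0)),
                              ("CB", "C", "ALA", 2, "R", (50, 0, 0))])
        assert buried_area(s, [0], [1]) == pytest.approx(0.0, abs=1e-9)

    def test_matches_point_count_oracle(self):
        """Brute-force occlusion count with the same sphere points."""
        s = simple_structure([("CB", "C", "ALA", 1, "L", (0, 0, 0)),
                              ("CB", "C", "ALA", 2, "L", (2.5, 0, 0)),
                              ("CB", "C", "ALA", 3, "R", (0, 3.4, 0)),
                              ("CB", "C", "ALA", 4, "R", (2.5, 3.4, 0))])
        n_pts = 960
        got = buried_area(s, [0, 1], [2, 3], n_points=n_pts)

        unit = fibonacci_sphere(n_pts)
        coords = s.coords
        expanded = np.array([a.vdw_radius for a in s.atoms]) + 1.4

        def exposed_area(i, context):
            pts = coords[i] + expanded[i] * unit
            keep = np.ones(n_pts, dtype=bool)
            for j in context:
                if j == i:
                    continue
                keep &= np.sum((pts - coords[j]) ** 2, axis=1) > expanded[j] ** 2
            return keep.sum() / n_pts * 4 * np.pi * expanded[i] ** 2

        free = sum(exposed_area(i, [0, 1]) for i in (0, 1))
        bound = sum(exposed_area(i, [0, 1, 2, 3]) for i in (0, 1))
        assert got == pytest.approx(free - bound, abs=1e-9)
        assert got > 0

    def test_funnel_threshold_is_350(self):
        from tfx.funnel import FunnelConfig

        cfg = FunnelConfig()
        assert not 349.0 >= cfg.buried_min
        assert 351.0 >= cfg.buried_min


def slab(chain, z, mhp, res0=1):
    """4x4 grid of atoms in a z-plane with uniform hydrophobicity sign."""
    entries = []
    rid = res0
    for x in range(4):
        for y in range(4):
            name, el = ("CB", "C") if mhp > 0 else ("OE1", "O")
            entries.append(make_atom(0, name, el, "XXX", rid, chain,
                                     (2.0 * x, 2.0 * y, z), vdw_radius=1.7,
                                     mhp_const=mhp))
            rid += 1
    return entries


class TestMhpComplementarity:
    def _two_slabs(self, mhp_top, mhp_bottom):
        from tfx.structio import Structure

        atoms = slab("L", 3.4, mhp_top) + slab("R", 0.0, mhp_bottom, res0=100)
        for i, a in enumerate(atoms):
            a.serial = i + 1
        s = Structure(atoms)
        lig = [i for i, a in enumerate(s.atoms) if a.chain == "L"]
        rec = [i for i, a in enumerate(s.atoms) if a.chain == "R"]
        return s, lig, rec

    def test_matching_hydrophobic_slabs_score_near_one(self):
        s, lig, rec = self._two_slabs(0.36, 0.36)
        assert mhp_complementarity(s, lig, rec) > 0.9

    def test_hydrophobic_facing_polar_scores_near_minus_one(self):
        s, lig, rec = self._two_slabs(0.36, -0.6)
        assert mhp_complementarity(s, lig, rec) < -0.9

    def test_no_interface_raises(self):
        s = simple_structure([("CB", "C", "ALA", 1, "L", (0, 0, 0)),
                              ("CB", "C", "ALA", 2, "R", (50, 0, 0))])
        with pytest.raises(ValueError, match="interface"):
            mhp_complementarity(s, [0], [1])

    def test_invariant_under_rigid_transform(self, toy):
        from tfx.funnel import Pose, _site_structure

        ligand = toy.ligand.apply(toy.true_pose)
        site, rec_sel, lig_sel = _site_structure(Pose(0, 0, 0, toy.true_pose),
                                                 toy.ensembles(), ligand)
        base = mhp_complementarity(site, lig_sel, rec_sel, n_points=480)
        tr = Transform.about_axis(np.array([5.0, -3.0, 1.0]),
                                  np.array([1.0, 2.0, 0.5]), 37.0)
        moved = site.apply(tr)
        moved_score = mhp_complementarity(moved, lig_sel, rec_sel, n_points=480)
        assert moved_score == pytest.approx(base, abs=1e-3)

    def test_funnel_threshold_is_055(self):
        from tfx.funnel import FunnelConfig

        cfg = FunnelConfig()
        assert 0.56 >= cfg.mhp_min
        assert not 0.54 >= cfg.mhp_min
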