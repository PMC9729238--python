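"""Solvent-accessible surface area, interface burial, and MHP complementarity.

SASA uses Shrake-Rupley sampling on a Fibonacci sphere lattice.  The
molecular hydrophobicity potential (MHP) at a surface point is the sum of
atomic hydrophobicity constants decayed exponentially with distance,
MHP(p) = sum_i f_i exp(-d_i / alpha).  Interface complementarity compares
the MHP sign on the ligand's buried surface with the receptor's MHP at the
nearest receptor surface point:

    score = (matching-sign buried area - mismatching-sign area) / total,

which lies in [-1, 1]; +1 means perfectly matched hydrophobic/hydrophilic
patterns across the interface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structio import Structure

DEFAULT_PROBE = 1.4  # water probe radius, A
DEFAULT_N_POINTS = 960
DEFAULT_ALPHA = 2.0  # MHP distance decay length, A


@dataclass
class SasaResult:
    per_atom: np.ndarray  # A^2
    total: float          # A^2
    probe_radius: float
    n_points: int


def fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points on the Fibonacci (golden-angle) lattice."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi),
                            np.cos(phi)])


def _radii(s: Structure) -> np.ndarray:
    r = np.empty(len(s))
    for i, a in enumerate(s.atoms):
        if a.vdw_radius is None:
            raise ValueError(f"atom {a.serial} has no vdW radius assigned")
        r[i] = a.vdw_radius
    return r


def _exposed_point_mask(coords: np.ndarray, radii: np.ndarray, probe: float,
                        unit_points: np.ndarray) -> list[np.ndarray]:
    """Per atom, boolean mask of sphere points not inside any other expanded sphere."""
    n = len(coords)
    expanded = radii + probe
    tree = cKDTree(coords)
    max_r = expanded.max()
    masks = []
    for i in range(n):
        pts = coords[i] + expanded[i] * unit_points
        neigh = [j for j in tree.query_ball_point(coords[i], expanded[i] + max_r)
                 if j != i]
        exposed = np.ones(len(unit_points), dtype=bool)
        for j in neigh:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            exposed &= d2 > expanded[j] ** 2
        masks.append(exposed)
    return masks


def sasa(s: Structure, probe: float = DEFAULT_PROBE,
         n_points: int = DEFAULT_N_POINTS) -> SasaResult:
    """Shrake-Rupley solvent-accessible surface area (A^2)."""
    if n_points < 92:
        raise ValueError("n_points must be >= 92")
    coords = s.coords
    radii = _radii(s)
    unit = fibonacci_sphere(n_points)
    masks = _exposed_point_mask(coords, radii, probe, unit)
    expanded = radii + probe
    per_atom = np.array([m.sum() / n_points * 4.0 * np.pi * er ** 2
                         for m, er in zip(masks, expanded)])
    return SasaResult(per_atom, float(per_atom.sum()), probe, n_points)


def buried_area(complex_structure: Structure, ligand_sel: Sequence[int],
                receptor_sel: Sequence[int], probe: float = DEFAULT_PROBE,
                n_points: int = DEFAULT_N_POINTS) -> float:
    """Ligand surface area buried at the interface (A^2).

    Ligand-side convention: SASA of the free ligand minus the ligand's SASA
    within the two-body complex.
    """
    ligand_sel = list(ligand_sel)
    receptor_sel = list(receptor_sel)
    if not ligand_sel or not receptor_sel:
        raise ValueError("selections must be non-empty")
    free = sasa(complex_structure.subset(ligand_sel), probe, n_points)
    both = complex_structure.subset(ligand_sel + receptor_sel)
    bound = sasa(both, probe, n_points)
    return float(free.total - bound.per_atom[: len(ligand_sel)].sum())


def _canonical_frame(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic body frame (principal axes, skewness-fixed signs).

    Computing surface-point lattices in this frame makes point-sampled
    quantities exactly invariant under proper rigid transforms of the input.
    """
    centre = coords.mean(axis=0)
    X = coords - centre
    w, V = np.linalg.eigh(X.T @ X)
    V = V[:, ::-1]  # descending variance
    for j in range(3):
        skew = float(np.sum((X @ V[:, j]) ** 3))
        if skew < 0:
            V[:, j] = -V[:, j]
    if np.linalg.det(V) < 0:
        V[:, 2] = -V[:, 2]
    return centre, V


def _mhp_at_points(points: np.ndarray, atom_coords: np.ndarray,
                   consts: np.ndarray, alpha: float) -> np.ndarray:
    d = np.linalg.norm(points[:, None, :] - atom_coords[None, :, :], axis=-1)
    return (consts[None, :] * np.exp(-d / alpha)).sum(axis=1)


def mhp_complementarity(complex_structure: Structure, ligand_sel: Sequence[int],
                        receptor_sel: Sequence[int], probe: float = DEFAULT_PROBE,
                        n_points: int = DEFAULT_N_POINTS,
                        alpha: float = DEFAULT_ALPHA) -> float:
    """Hydrophobicity-pattern complementarity of the interface, in [-1, 1].

    Computed over the ligand surface points that are solvent-accessible on
    the free ligand but occluded by the receptor in the complex.
    """
    ligand_sel = list(ligand_sel)
    receptor_sel = list(receptor_sel)
    lig = complex_structure.subset(ligand_sel)
    rec = complex_structure.subset(receptor_sel)
    lc, rc = lig.coords, rec.coords
    # body frame of the whole interface: makes the score rigid-invariant
    centre, frame = _canonical_frame(np.vstack([lc, rc]))
    lc = (lc - centre) @ frame
    rc = (rc - centre) @ frame
    lr, rr = _radii(lig), _radii(rec)
    consts_l = np.array([a.mhp_const if a.mhp_const is not None else 0.0 for a in lig.atoms])
    consts_r = np.array([a.mhp_const if a.mhp_const is not None else 0.0 for a in rec.atoms])
    if np.all(consts_l == 0) and np.all(consts_r == 0):
        raise ValueError("no hydrophobicity constants assigned")
    unit = fibonacci_sphere(n_points)

    free_masks = _exposed_point_mask(lc, lr, probe, unit)
    rec_tree = cKDTree(rc)
    rec_expanded = rr + probe
    max_rr = rec_expanded.max()

    buried_pts, buried_w = [], []
    for i in range(len(lc)):
        er = lr[i] + probe
        pts = lc[i] + er * unit[free_masks[i]]
        if len(pts) == 0:
            continue
        # occluded by any receptor sphere?
        occluded = np.zeros(len(pts), dtype=bool)
        neigh = rec_tree.query_ball_point(lc[i], er + max_rr)
        for j in neigh:
            occluded |= np.sum((pts - rc[j]) ** 2, axis=1) <= rec_expanded[j] ** 2
        if occluded.any():
            area_per_pt = 4.0 * np.pi * er ** 2 / len(unit)
            buried_pts.append(pts[occluded])
            buried_w.append(np.full(int(occluded.sum()), area_per_pt))
    if not buried_pts:
        raise ValueError("no interface: zero buried area")
    P = np.vstack(buried_pts)
    W = np.concatenate(buried_w)

    mhp_lig = _mhp_at_points(P, lc, consts_l, alpha)

    # receptor surface points (free receptor) and their MHP values
    rec_masks = _exposed_point_mask(rc, rr, probe, unit)
    rec_surface = []
    for j in range(len(rc)):
        pts = rc[j] + (rr[j] + probe) * unit[rec_masks[j]]
        if len(pts):
            rec_surface.append(pts)
    if not rec_surface:
        raise ValueError("receptor has no accessible surface")
    RS = np.vstack(rec_surface)
    mhp_rec_all = _mhp_at_points(RS, rc, consts_r, alpha)
    _, nearest = cKDTree(RS).query(P)
    mhp_rec = mhp_rec_all[nearest]

    match = np.sign(mhp_lig) * np.sign(mhp_rec) >= 0
    score = (W[match].sum() - W[~match].sum()) / W.sum()
    return float(score)
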