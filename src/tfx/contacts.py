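"""Geometric detection and typing of intermolecular contacts.

Six contact kinds are distinguished on heavy-atom geometry alone (deposited
models frequently lack hydrogens): hydrogen bonds, ionic bridges, ion-dipole
interactions, hydrophobic carbon-carbon contacts, aromatic stacking, and
cation-pi interactions.  Hydrogen bonds, ionic bridges, stacking and
cation-pi count as "specific" contacts; hydrophobic and ion-dipole do not.

Thresholds live in :class:`ContactCriteria`; the defaults are artifact
choices (the original analysis software does not publish its cutoffs) and
every one of them is configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import _chem
from .structio import Structure, Trajectory

SPECIFIC_KINDS = frozenset({"hbond", "ionic", "stacking", "cation_pi"})
ALL_KINDS = ("hbond", "ionic", "ion_dipole", "hydrophobic", "stacking", "cation_pi")


@dataclass
class ContactCriteria:
    """Distance/angle thresholds for each contact kind (A, degrees)."""

    hbond_max_dist: float = 3.5
    hbond_min_angle: float = 120.0
    ionic_max_dist: float = 4.0
    ion_dipole_max_dist: float = 4.0
    hydrophobic_max_dist: float = 4.5
    stack_max_centroid_dist: float = 5.5
    stack_parallel_max_angle: float = 30.0
    stack_tshape_range: tuple[float, float] = (60.0, 90.0)
    cation_pi_max_dist: float = 6.0
    cation_pi_max_cone: float = 45.0

    def __post_init__(self) -> None:
        for name in ("hbond_max_dist", "ionic_max_dist", "ion_dipole_max_dist",
                     "hydrophobic_max_dist", "stack_max_centroid_dist", "cation_pi_max_dist"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for ang in (self.hbond_min_angle, self.stack_parallel_max_angle,
                    self.cation_pi_max_cone, *self.stack_tshape_range):
            if not 0.0 <= ang <= 180.0:
                raise ValueError("angles must lie in [0, 180] degrees")


@dataclass(frozen=True)
class ContactRecord:
    kind: str
    partner_a: tuple  # (chain, res_id, atom-or-group label)
    partner_b: tuple
    distance: float
    frame: int = 0

    def residue_pair(self) -> tuple:
        a = self.partner_a[:2]
        b = self.partner_b[:2]
        return (a, b) if a <= b else (b, a)


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

def _features(s: Structure, sel: Sequence[int]) -> dict:
    """Role-tagged atom features for one selection."""
    donors, acceptors, cations, anions, polar, apolar = [], [], [], [], [], []
    by_residue: dict[tuple, list[int]] = {}
    for i in sel:
        a = s.atoms[i]
        key = (a.chain, a.res_id)
        by_residue.setdefault(key, []).append(i)
        if _chem.is_hbond_donor(a.res_name, a.name):
            donors.append(i)
        if _chem.is_hbond_acceptor(a.res_name, a.name):
            acceptors.append(i)
        if _chem.is_cation(a.res_name, a.name):
            cations.append(i)
        if _chem.is_anion(a.res_name, a.name):
            anions.append(i)
        if _chem.is_polar_uncharged(a.res_name, a.name, a.element):
            polar.append(i)
        if _chem.is_apolar_carbon(a.res_name, a.name, a.element):
            apolar.append(i)
    rings = []
    for (chain, res_id), idxs in by_residue.items():
        res_name = s.atoms[idxs[0]].res_name
        ring_defs = _chem.AROMATIC_RINGS.get(res_name)
        if not ring_defs:
            continue
        names = {s.atoms[i].name: i for i in idxs}
        for ring_names in ring_defs:
            if all(n in names for n in ring_names):
                rings.append(((chain, res_id), [names[n] for n in ring_names]))
            else:
                warnings.warn(f"residue {chain}/{res_id} {res_name}: missing ring atoms, "
                              "aromatic contacts skipped")
    return dict(donors=donors, acceptors=acceptors, cations=cations, anions=anions,
                polar=polar, apolar=apolar, rings=rings, by_residue=by_residue)


def _ring_geometry(coords: np.ndarray, idxs: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    pts = coords[list(idxs)]
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, _, vt = np.linalg.svd(centered)
    normal = vt[2]
    return centroid, normal / np.linalg.norm(normal)


def _antecedent(s: Structure, coords: np.ndarray, donor_idx: int) -> int | None:
    """Heavy covalent neighbour of a donor within the same residue (<= 1.9 A)."""
    a = s.atoms[donor_idx]
    best, best_d = None, 1.9
    for j, b in enumerate(s.atoms):
        if j == donor_idx or b.chain != a.chain or b.res_id != a.res_id:
            continue
        d = float(np.linalg.norm(coords[j] - coords[donor_idx]))
        if d < best_d:
            best, best_d = j, d
    return best


def _angle_deg(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    v1, v2 = p1 - p2, p3 - p2
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_contacts(s: Structure, sel_a: Sequence[int], sel_b: Sequence[int],
                      criteria: ContactCriteria | None = None,
                      frame: int = 0,
                      coords: np.ndarray | None = None) -> list[ContactRecord]:
    """Detect and type all intermolecular contacts between two selections.

    Records are returned in a deterministic order (kind, residue ids, atom
    labels).  One residue pair may carry several kinds.
    """
    c = criteria or ContactCriteria()
    sel_a = list(sel_a)
    sel_b = list(sel_b)
    if not sel_a or not sel_b:
        raise ValueError("selections must be non-empty")
    if set(sel_a) & set(sel_b):
        raise ValueError("selections must be disjoint")
    X = s.coords if coords is None else np.asarray(coords, dtype=float)
    fa = _features(s, sel_a)
    fb = _features(s, sel_b)

    def label(i: int) -> tuple:
        a = s.atoms[i]
        return (a.chain, a.res_id, a.name)

    records: set[ContactRecord] = set()

    def add(kind: str, i: int, j: int, dist: float,
            a_group: tuple | None = None, b_group: tuple | None = None) -> None:
        pa = a_group if a_group is not None else label(i)
        pb = b_group if b_group is not None else label(j)
        records.add(ContactRecord(kind, pa, pb, round(float(dist), 6), frame))

    def pair_dists(idx1: list[int], idx2: list[int]):
        if not idx1 or not idx2:
            return None
        d = np.linalg.norm(X[np.asarray(idx1)][:, None, :] - X[np.asarray(idx2)][None, :, :],
                           axis=-1)
        return d

    # --- hydrogen bonds (both directions) -------------------------------
    for donors, acceptors, swap in ((fa["donors"], fb["acceptors"], False),
                                    (fb["donors"], fa["acceptors"], True)):
        d = pair_dists(donors, acceptors)
        if d is None:
            continue
        for ii, jj in zip(*np.nonzero(d <= c.hbond_max_dist)):
            di, aj = donors[ii], acceptors[jj]
            ante = _antecedent(s, X, di)
            if ante is not None:
                if _angle_deg(X[ante], X[di], X[aj]) < c.hbond_min_angle:
                    continue
            if swap:
                add("hbond", aj, di, d[ii, jj])
            else:
                add("hbond", di, aj, d[ii, jj])

    # --- ionic bridges --------------------------------------------------
    for cat, ani, swap in ((fa["cations"], fb["anions"], False),
                           (fb["cations"], fa["anions"], True)):
        d = pair_dists(cat, ani)
        if d is None:
            continue
        for ii, jj in zip(*np.nonzero(d <= c.ionic_max_dist)):
            i, j = cat[ii], ani[jj]
            add("ionic", (j if swap else i), (i if swap else j), d[ii, jj])

    # --- ion-dipole -----------------------------------------------------
    charged_a = fa["cations"] + fa["anions"]
    charged_b = fb["cations"] + fb["anions"]
    for chg, pol, swap in ((charged_a, fb["polar"], False),
                           (charged_b, fa["polar"], True)):
        d = pair_dists(chg, pol)
        if d is None:
            continue
        for ii, jj in zip(*np.nonzero(d <= c.ion_dipole_max_dist)):
            i, j = chg[ii], pol[jj]
            add("ion_dipole", (j if swap else i), (i if swap else j), d[ii, jj])

    # --- hydrophobic ----------------------------------------------------
    d = pair_dists(fa["apolar"], fb["apolar"])
    if d is not None:
        for ii, jj in zip(*np.nonzero(d <= c.hydrophobic_max_dist)):
            add("hydrophobic", fa["apolar"][ii], fb["apolar"][jj], d[ii, jj])

    # --- stacking -------------------------------------------------------
    for (res_a, ring_a) in fa["rings"]:
        ca, na = _ring_geometry(X, ring_a)
        for (res_b, ring_b) in fb["rings"]:
            cb, nb = _ring_geometry(X, ring_b)
            dist = float(np.linalg.norm(ca - cb))
            if dist > c.stack_max_centroid_dist:
                continue
            ang = float(np.rad2deg(np.arccos(np.clip(abs(np.dot(na, nb)), 0.0, 1.0))))
            lo, hi = c.stack_tshape_range
            if ang <= c.stack_parallel_max_angle or lo <= ang <= hi:
                records.add(ContactRecord("stacking", (*res_a, "ring"), (*res_b, "ring"),
                                          round(dist, 6), frame))

    # --- cation-pi ------------------------------------------------------
    for cats, rings, swap in ((fa["cations"], fb["rings"], False),
                              (fb["cations"], fa["rings"], True)):
        for i in cats:
            for (res_r, ring) in rings:
                cr, nr = _ring_geometry(X, ring)
                v = X[i] - cr
                dist = float(np.linalg.norm(v))
                if dist > c.cation_pi_max_dist or dist == 0.0:
                    continue
                cone = float(np.rad2deg(np.arccos(np.clip(abs(np.dot(v / dist, nr)), 0.0, 1.0))))
                if cone <= c.cation_pi_max_cone:
                    pa, pb = label(i), (*res_r, "ring")
                    if swap:
                        pa, pb = pb, pa
                    records.add(ContactRecord("cation_pi", pa, pb, round(dist, 6), frame))

    return sorted(records, key=lambda r: (r.kind, r.partner_a, r.partner_b, r.distance))


def residue_has_specific_contact(records: Iterable[ContactRecord],
                                 residue: tuple) -> bool:
    """True iff (chain, res_id) participates in a specific-kind contact.

    Specific kinds are hydrogen bonds, ionic bridges, stacking and cation-pi;
    hydrophobic and ion-dipole contacts do not qualify.
    """
    for r in records:
        if r.kind not in SPECIFIC_KINDS:
            continue
        if r.partner_a[:2] == tuple(residue) or r.partner_b[:2] == tuple(residue):
            return True
    return False


def count_good_contacts(records: Iterable[ContactRecord]) -> int:
    """Number of unique (residue pair, kind) specific contacts."""
    return len({(r.residue_pair(), r.kind) for r in records if r.kind in SPECIFIC_KINDS})


# ---------------------------------------------------------------------------
# lifetimes
# ---------------------------------------------------------------------------

def contact_lifetimes(traj: Trajectory, sel_a: Sequence[int], sel_b: Sequence[int],
                      criteria: ContactCriteria | None = None) -> pd.DataFrame:
    """Occupancy and mean continuous lifetime per (kind, residue pair).

    Occupancy is the fraction of frames in which the contact is present;
    mean lifetime is the average maximal run length in ps (frame spacing
    taken from the trajectory times).
    """
    if traj.n_frames < 2:
        raise ValueError("need at least two frames")
    dt = float(traj.times[1] - traj.times[0])
    presence: dict[tuple, np.ndarray] = {}
    for f in range(traj.n_frames):
        recs = classify_contacts(traj.topology, sel_a, sel_b, criteria,
                                 frame=f, coords=traj.frames[f])
        seen = {(r.kind, r.residue_pair()) for r in recs}
        for key in seen:
            if key not in presence:
                presence[key] = np.zeros(traj.n_frames, dtype=bool)
            presence[key][f] = True
    rows = []
    for (kind, pair), mask in sorted(presence.items()):
        runs = []
        run = 0
        for present in mask:
            if present:
                run += 1
            elif run:
                runs.append(run)
                run = 0
        if run:
            runs.append(run)
        (chain_a, res_a), (chain_b, res_b) = pair
        rows.append(dict(kind=kind, chain_a=chain_a, res_a=res_a,
                         chain_b=chain_b, res_b=res_b,
                         occupancy=mask.sum() / traj.n_frames,
                         mean_lifetime_ps=float(np.mean(runs)) * dt))
    return pd.DataFrame(rows, columns=["kind", "chain_a", "res_a", "chain_b", "res_b",
                                       "occupancy", "mean_lifetime_ps"])
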