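"""Structure and trajectory I/O, geometry primitives, and conformer clustering.

Atomic structures are held in a lightweight :class:`Structure` container
(ordered :class:`Atom` records plus cached coordinate arrays).  PDB and GRO
dialects are read and written through biotite; all internal lengths are
Angstrom (GRO nm are converted on read), energies kcal/mol unless stated.

Also provides Kabsch superposition, C5 symmetry expansion about an axis, and
GROMOS-style iterative neighbour-count clustering of trajectory frames.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from . import _chem

NM_TO_ANG = 10.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    """One atom: identity, coordinates (A) and derived physical constants."""

    serial: int
    name: str
    element: str
    res_name: str
    res_id: int
    chain: str
    xyz: np.ndarray
    vdw_radius: float | None = None
    partial_charge: float | None = None
    mhp_const: float | None = None
    icode: str = ""

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.serial}: xyz must be a finite 3-vector")
        if self.vdw_radius is not None and self.vdw_radius <= 0:
            raise ValueError(f"atom {self.serial}: vdw_radius must be > 0")

    def key(self) -> tuple:
        return (self.chain, self.res_id, self.icode, self.name)


class Structure:
    """Ordered collection of atoms with optional box (A)."""

    def __init__(self, atoms: Iterable[Atom], title: str = "", box: np.ndarray | None = None):
        self.atoms: list[Atom] = list(atoms)
        if not self.atoms:
            raise ValueError("zero atoms: a Structure must be non-empty")
        self.title = title
        self.box = None if box is None else np.asarray(box, dtype=float)
        keys = [a.key() for a in self.atoms]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chain, res_id, name) atom keys in Structure")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray, title: str | None = None) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [replace(a, xyz=coords[i].copy()) for i, a in enumerate(self.atoms)]
        return Structure(atoms, title=self.title if title is None else title, box=self.box)

    def subset(self, indices: Sequence[int], title: str | None = None) -> "Structure":
        atoms = [replace(self.atoms[i], xyz=self.atoms[i].xyz.copy()) for i in indices]
        return Structure(atoms, title=self.title if title is None else title, box=self.box)

    def chain_indices(self, chain: str) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if a.chain == chain], dtype=int)

    def residue_indices(self, chain: str, res_id: int) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms)
                         if a.chain == chain and a.res_id == res_id], dtype=int)

    def chains(self) -> list[str]:
        seen: list[str] = []
        for a in self.atoms:
            if a.chain not in seen:
                seen.append(a.chain)
        return seen

    def apply(self, transform: "Transform") -> "Structure":
        return self.with_coords(transform.apply(self.coords))

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)


@dataclass
class Trajectory:
    """Topology plus per-frame coordinates (n_frames, n_atoms, 3) in A."""

    topology: Structure
    frames: np.ndarray
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != len(self.topology):
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.times is None:
            self.times = np.arange(self.frames.shape[0], dtype=float)
        else:
            self.times = np.asarray(self.times, dtype=float)
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_structure(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames[i])


@dataclass
class Transform:
    """Proper rigid transform x -> R @ x + t (A)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3, translation a 3-vector")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation determinant must be +1")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthonormal")

    @classmethod
    def identity(cls) -> "Transform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def about_axis(cls, point: np.ndarray, direction: np.ndarray, angle_deg: float) -> "Transform":
        """Rotation by angle_deg about the line through `point` along `direction`."""
        from scipy.spatial.transform import Rotation

        point = np.asarray(point, dtype=float)
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        R = Rotation.from_rotvec(np.deg2rad(angle_deg) * d).as_matrix()
        t = point - R @ point
        return cls(R, t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "Transform") -> "Transform":
        """Transform equivalent to applying `other` first, then self."""
        return Transform(self.rotation @ other.rotation,
                         self.rotation @ other.translation + self.translation)

    def inverse(self) -> "Transform":
        Rt = self.rotation.T
        return Transform(Rt, -Rt @ self.translation)

    def rotation_angle_deg(self) -> float:
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass
class ClusterResult:
    """GROMOS clustering output: member frame-index sets per cluster."""

    cluster_members: list[frozenset]
    centroids: list[int]
    cutoff: float  # nm

    def __post_init__(self) -> None:
        sizes = [len(m) for m in self.cluster_members]
        if sizes != sorted(sizes, reverse=True):
            raise ValueError("clusters must be ordered by decreasing size")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _assign_constants(atom: Atom) -> Atom:
    if atom.vdw_radius is None:
        atom.vdw_radius = _chem.vdw_radius(atom.element)
    if atom.mhp_const is None:
        atom.mhp_const = _chem.mhp_constant(atom.res_name, atom.name, atom.element)
    return atom


def _from_atom_array(array, title: str = "") -> Structure:
    import biotite.structure as struc

    n = array.array_length()
    if n == 0:
        raise ValueError("zero atoms in file")
    elements = array.element if "element" in array.get_annotation_categories() else None
    icodes = array.ins_code if "ins_code" in array.get_annotation_categories() else None
    atoms = []
    for i in range(n):
        el = str(elements[i]).strip() if elements is not None else ""
        name = str(array.atom_name[i]).strip()
        if not el:
            el = _chem.guess_element(name)
        atoms.append(_assign_constants(Atom(
            serial=i + 1,
            name=name,
            element=el.capitalize(),
            res_name=str(array.res_name[i]).strip(),
            res_id=int(array.res_id[i]),
            chain=str(array.chain_id[i]).strip() or "A",
            xyz=np.asarray(array.coord[i], dtype=float),
            icode=str(icodes[i]).strip() if icodes is not None else "",
        )))
    box = None
    if array.box is not None:
        box = np.asarray(np.diagonal(array.box), dtype=float)
    return Structure(atoms, title=title, box=box)


def read_structure(path, format: str | None = None) -> Structure:
    """Read a PDB or GRO file into a Structure.

    Bondi radii and hydrophobicity constants are assigned from the packaged
    tables.  Altlocs resolve to the highest occupancy (ties: first).
    """
    path = str(path)
    if format is None:
        format = "gro" if path.lower().endswith(".gro") else "pdb"
    format = format.lower()
    if format == "pdb":
        from biotite.structure.io.pdb import PDBFile

        pdb = PDBFile.read(path)
        if pdb.get_model_count() == 0:
            raise ValueError(f"zero atoms in {path}")
        array = pdb.get_structure(model=1, altloc="occupancy")
        return _from_atom_array(array, title="")
    if format == "gro":
        from biotite.structure.io.gro import GROFile

        gro = GROFile.read(path)
        if gro.get_model_count() == 0:
            raise ValueError(f"zero atoms in {path}")
        array = gro.get_structure(model=1)
        return _from_atom_array(array, title="")
    raise ValueError(f"unknown format {format!r} (expected 'pdb' or 'gro')")


def _to_atom_array(s: Structure):
    import biotite.structure as struc

    n = len(s)
    array = struc.AtomArray(n)
    array.coord = s.coords
    # PDB chain ids are single characters: map long internal ids deterministically
    chains = s.chains()
    alphabet = string.ascii_uppercase + string.ascii_lowercase + string.digits
    mapping = {}
    for c in chains:
        mapping[c] = c if len(c) == 1 else alphabet[len(mapping) % len(alphabet)]
    used = set(mapping.values())
    # resolve collisions deterministically
    for c in chains:
        if len(c) != 1:
            cand = mapping[c]
            while list(mapping.values()).count(cand) > 1:
                cand = alphabet[(alphabet.index(cand) + 1) % len(alphabet)]
                mapping[c] = cand
    for i, a in enumerate(s.atoms):
        array.chain_id[i] = mapping[a.chain]
        array.res_id[i] = a.res_id
        array.res_name[i] = a.res_name
        array.atom_name[i] = a.name
        array.element[i] = a.element.upper()
        array.hetero[i] = False
    if s.box is not None:
        array.box = np.diag(s.box)
    return array


def write_structure(s: Structure, path, format: str | None = None) -> None:
    """Write a Structure as PDB or GRO (mirror of read_structure)."""
    path = str(path)
    if format is None:
        format = "gro" if path.lower().endswith(".gro") else "pdb"
    format = format.lower()
    array = _to_atom_array(s)
    if format == "pdb":
        from biotite.structure.io.pdb import PDBFile

        pdb = PDBFile()
        pdb.set_structure(array)
        pdb.write(path)
    elif format == "gro":
        from biotite.structure.io.gro import GROFile

        gro = GROFile()
        gro.set_structure(array)
        gro.write(path)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'pdb' or 'gro')")


def read_trajectory(path, format: str = "pdb") -> Trajectory:
    """Read a multi-model PDB file as a Trajectory (frame time = model index)."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    if n_models == 0:
        raise ValueError(f"zero models in {path}")
    first = _from_atom_array(pdb.get_structure(model=1, altloc="occupancy"))
    frames = np.empty((n_models, len(first), 3))
    for m in range(n_models):
        frames[m] = pdb.get_structure(model=m + 1, altloc="occupancy").coord
    return Trajectory(first, frames)


def shift_residue_numbering(s: Structure, offset: int,
                            chains: Sequence[str] | None = None) -> Structure:
    """Return a copy with res_id shifted by `offset` (optionally per chain).

    Deposited toxin structures are numbered from 0 in some conventions and
    from 1 in others; selections in this package always follow the file, so
    renumber explicitly instead of guessing.
    """
    atoms = [replace(a, res_id=a.res_id + offset, xyz=a.xyz.copy())
             if chains is None or a.chain in chains
             else replace(a, xyz=a.xyz.copy())
             for a in s.atoms]
    return Structure(atoms, title=s.title, box=s.box)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[Transform, float]:
    """Kabsch least-squares superposition of `mobile` onto `reference`.

    Returns the optimal proper rigid transform and the post-fit RMSD (A).
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    if P.shape[0] < 3:
        raise ValueError("need at least 3 points")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    if np.linalg.matrix_rank(P0, tol=1e-8) < 2:
        raise ValueError("degenerate geometry: points are collinear")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cq - R @ cp
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return Transform(R, t), rmsd


def c5_expand(site_complex: Structure, axis_point: np.ndarray, axis_direction: np.ndarray,
              clash_distance: float = 1.5, max_clash_pairs: int = 25) -> Structure:
    """Expand a structure into five C5 symmetry copies about an axis.

    Copies are generated at 0/72/144/216/288 degrees; chain identifiers get a
    per-copy suffix.  Overlapping copies (more than `max_clash_pairs` atom
    pairs closer than `clash_distance` A between different copies) trigger a
    warning, not an error.
    """
    from scipy.spatial import cKDTree

    copies = []
    for k in range(5):
        tr = Transform.about_axis(axis_point, axis_direction, 72.0 * k)
        moved = site_complex.apply(tr)
        atoms = []
        for a in moved.atoms:
            atoms.append(replace(a, chain=f"{a.chain}{k}" if k > 0 else a.chain,
                                 xyz=a.xyz.copy()))
        copies.append(atoms)
    n = len(site_complex)
    all_atoms = [a for c in copies for a in c]
    out = Structure(all_atoms, title=f"{site_complex.title} C5", box=site_complex.box)
    coords = out.coords
    tree = cKDTree(coords)
    pairs = tree.query_pairs(clash_distance)
    clashes = sum(1 for i, j in pairs if i // n != j // n)
    if clashes > max_clash_pairs:
        warnings.warn(f"C5 expansion produced {clashes} inter-copy atom pairs "
                      f"closer than {clash_distance} A")
    return out


# ---------------------------------------------------------------------------
# GROMOS clustering
# ---------------------------------------------------------------------------

def pairwise_rmsd_matrix(traj: Trajectory, selection: Sequence[int]) -> np.ndarray:
    """All-vs-all RMSD (A) over `selection` after Kabsch superposition."""
    sel = np.asarray(selection, dtype=int)
    if sel.size == 0:
        raise ValueError("empty selection")
    n = traj.n_frames
    coords = traj.frames[:, sel, :]
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, r = superpose(coords[j], coords[i])
            mat[i, j] = mat[j, i] = r
    return mat


def gromos_cluster(traj: Trajectory, cutoff: float, selection: Sequence[int]) -> ClusterResult:
    """GROMOS iterative neighbour-count clustering.

    `cutoff` is in nm (GROMACS convention); RMSDs are computed in A after
    superposition on `selection`.  The frame with the most neighbours within
    the cutoff seeds a cluster (ties: lowest frame index); it and its
    neighbours are removed and the procedure repeats.
    """
    if traj.n_frames < 1:
        raise ValueError("need at least one frame")
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    mat = pairwise_rmsd_matrix(traj, selection)
    cutoff_ang = cutoff * NM_TO_ANG
    remaining = list(range(traj.n_frames))
    members: list[frozenset] = []
    centroids: list[int] = []
    while remaining:
        idx = np.array(remaining)
        sub = mat[np.ix_(idx, idx)]
        neigh_counts = (sub <= cutoff_ang).sum(axis=1)  # includes self
        best_pos = int(np.argmax(neigh_counts))  # argmax takes first max: lowest index
        center = int(idx[best_pos])
        cluster = frozenset(int(idx[p]) for p in np.nonzero(sub[best_pos] <= cutoff_ang)[0])
        members.append(cluster)
        centroids.append(center)
        remaining = [f for f in remaining if f not in cluster]
    order = sorted(range(len(members)), key=lambda i: (-len(members[i]), centroids[i]))
    return ClusterResult([members[i] for i in order], [centroids[i] for i in order], cutoff)
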