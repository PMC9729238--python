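"""Seeded synthetic benchmarks with known ground truth for every pipeline stage.

The toy complex is a C5-symmetric pseudo-receptor ring with an inter-subunit
pocket and a three-loop pseudo-toxin whose middle loop carries two arginines
that bridge the two pocket subunits - the same interaction chemistry (salt
bridges, hydrogen bonds, stacking, cation-pi) the real toxin/receptor
interface shows, built from pseudo-residues with standard names so the real
chemistry tables drive every metric.  The planted pose satisfies the default
funnel thresholds by construction; decoys are rigid perturbations of it.

None of the toys are physically realistic proteins: they exist to exercise
geometry, thresholds and estimators against known ground truth.

Every generator is a pure function of :class:`SynthSpec` (each draws from its
own seeded RNG stream, so adding one generator never perturbs another).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .densfit import DensityMap, simulate_map
from .energetics import KB_KJ, KJ_PER_KCAL, UmbrellaWindow
from .funnel import Ensembles, Pose
from .membrane_binding import CompetitionSeries, TitrationSeries
from .structio import Atom, Structure, Transform


@dataclass
class SynthSpec:
    """All knobs of the synthetic study conditions (defaults = the conditions
    the analysed experiments report, where they report them)."""

    seed: int = 7
    # toy complex geometry (A)
    wall_radius: float = 25.0
    wall_height: float = 40.0
    site_z: float = 13.0
    map_resolution: float = 8.0
    map_noise_frac: float = 0.02      # Gaussian noise SD as fraction of map max
    membrane_z: float = -5.0
    # decoy perturbations
    decoy_shift_range: tuple = (3.0, 25.0)   # A
    decoy_rot_range: tuple = (10.0, 180.0)   # degrees
    # vesicle titration (Langmuir)
    langmuir_k_app: float = 2.0       # mM
    langmuir_b: float = 0.9
    titration_noise_sd: float = 0.02
    lipid_composition: str = "POPC:POPG:CHOL = 7:1:2"
    # competition (Hill); the printed fit values of the emulated assays
    wtx_ic50: float = 26e-6           # M
    wtx_nh: float = 1.5
    bgtx_ic50: float = 3.2e-9         # M
    bgtx_nh: float = 2.1
    bgtx_a0: float = 50.0             # MFI baseline
    bgtx_a1: float = 1000.0           # MFI amplitude
    competition_noise_frac: float = 0.03
    n_replicates: int = 5
    # umbrella sampling
    temperature: float = 310.0        # K
    umbrella_k: float = 1000.0        # kJ mol^-1 nm^-2
    well_depth: float = 10.0          # kcal/mol
    well_width: float = 0.8           # nm
    umbrella_samples: int = 1000


def _rng(spec: SynthSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stream])


# ---------------------------------------------------------------------------
# toy complex
# ---------------------------------------------------------------------------

@dataclass
class ToyComplex:
    receptor: Structure            # full C5 pentamer, chains A-E
    ligand: Structure              # free frame (centroid at origin)
    true_pose: Transform
    membrane_point: np.ndarray
    membrane_normal: np.ndarray
    axis_point: np.ndarray
    axis_direction: np.ndarray
    site_chains: tuple             # (primary, complementary) of the reference site
    required_residues: tuple
    loop_i_range: tuple
    loop_ii_range: tuple
    loop_iii_range: tuple

    def ensembles(self) -> Ensembles:
        return Ensembles(receptors=[self.receptor], ligands=[self.ligand],
                         site_chains=self.site_chains,
                         axis_point=self.axis_point,
                         axis_direction=self.axis_direction)


def _iface_pt(theta_deg: float, wall_radius: float, z_centre: float,
              t: float, dr: float, dz: float) -> np.ndarray:
    """Point near an inter-subunit interface: tangential t, radial dr, axial dz."""
    th = math.radians(theta_deg)
    e_r = np.array([math.cos(th), math.sin(th), 0.0])
    e_t = np.array([-math.sin(th), math.cos(th), 0.0])
    base = wall_radius * e_r + np.array([0.0, 0.0, z_centre])
    return base + t * e_t + dr * e_r + dz * np.array([0.0, 0.0, 1.0])


def _hexagon(centre: np.ndarray, normal: np.ndarray, radius: float = 1.39) -> list[np.ndarray]:
    n = normal / np.linalg.norm(normal)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, n)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    u = np.cross(n, ref)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return [centre + radius * (math.cos(a) * u + math.sin(a) * v)
            for a in np.linspace(0, 2 * math.pi, 6, endpoint=False)]


_RING_NAMES = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")


def make_toy_complex(spec: SynthSpec | None = None) -> ToyComplex:
    """Build the C5 pseudo-receptor, pseudo-toxin, planted pose and membrane.

    The planted pose places the toxin's loop II into the pocket at the A/B
    interface (both required arginines bridging the two subunits) with loop I
    pointing at the membrane plane; it passes the default funnel config.
    """
    spec = spec or SynthSpec()
    R0 = spec.wall_radius
    zc = spec.site_z

    def P(theta, t, dr, dz):
        return _iface_pt(theta, R0, zc, t, dr, dz)

    serial = [0]

    def atom(name, element, res_name, res_id, chain, xyz):
        serial[0] += 1
        from . import _chem
        return Atom(serial[0], name, element, res_name, res_id, chain,
                    np.asarray(xyz, dtype=float),
                    vdw_radius=_chem.vdw_radius(element),
                    mhp_const=_chem.mhp_constant(res_name, name, element))

    # ---- base receptor subunit (chain A spans angles [0, 72)) -------------
    base_atoms: list[Atom] = []
    res_id = 0
    for iz in range(8):
        z = 2.5 + 5.0 * iz
        for ia in range(5):
            ang = 6.0 + 13.2 * ia
            res_id += 1
            th = math.radians(ang)
            e_r = np.array([math.cos(th), math.sin(th), 0.0])
            for name, r in (("N", R0 - 0.8), ("CA", R0), ("CB", R0 + 0.8)):
                el = "N" if name == "N" else "C"
                base_atoms.append(atom(name, el, "ALA", res_id, "A",
                                       r * e_r + np.array([0, 0, z])))

    # primary-edge pocket residues (relative to the interface at 72 deg)
    TH = 72.0
    # GLU 205: salt-bridge partner of ligand ARG 31
    for name, el, off in (("CD", "C", (-3.5, 2.0, 2.0)), ("OE1", "O", (-3.5, 3.2, 2.0)),
                          ("OE2", "O", (-4.4, 3.0, 2.0))):
        base_atoms.append(atom(name, el, "GLU", 205, "A", P(TH, *off)))
    # PHE 209 ring: cation-pi partner of ARG 31
    for name, xyz in zip(_RING_NAMES, _hexagon(P(TH, -6.0, 2.6, 0.0),
                                               P(TH, -6.0, 1.0, 0.0) - P(TH, -6.0, 0.0, 0.0))):
        base_atoms.append(atom(name, "C", "PHE", 209, "A", xyz))
    # TYR 210 ring: stacking partner of ligand PHE 36
    for name, xyz in zip(_RING_NAMES, _hexagon(P(TH, -1.2, 2.6, 3.0),
                                               P(TH, -1.2, 1.0, 3.0) - P(TH, -1.2, 0.0, 3.0))):
        base_atoms.append(atom(name, "C", "TYR", 210, "A", xyz))
    # LYS 167: cation-pi donor over the ligand PHE 36 ring
    base_atoms.append(atom("NZ", "N", "LYS", 167, "A", P(TH, -0.2, 9.6, 3.8)))
    base_atoms.append(atom("CE", "C", "LYS", 167, "A", P(TH, 0.4, 10.5, 4.4)))
    # GLU 211: salt-bridge partner of ligand LYS 27
    for name, el, off in (("CD", "C", (-3.5, 2.0, 5.5)), ("OE1", "O", (-3.5, 3.2, 5.5)),
                          ("OE2", "O", (-2.6, 3.0, 5.5))):
        base_atoms.append(atom(name, el, "GLU", 211, "A", P(TH, *off)))

    # complementary-edge pocket residues (relative to the interface at 0 deg;
    # after +72 deg rotation these serve the A/B site from the B side)
    for name, el, off in (("CG", "C", (4.0, 2.0, -3.0)), ("OD1", "O", (4.0, 3.2, -3.0)),
                          ("OD2", "O", (4.9, 3.0, -2.8))):
        base_atoms.append(atom(name, el, "ASP", 186, "A", P(0.0, *off)))
    for name, xyz in zip(_RING_NAMES, _hexagon(P(0.0, 6.3, 2.6, -1.0),
                                               P(0.0, 6.3, 1.0, -1.0) - P(0.0, 6.3, 0.0, -1.0))):
        base_atoms.append(atom(name, "C", "PHE", 77, "A", xyz))
    base_atoms.append(atom("OG", "O", "SER", 188, "A", P(0.0, 2.5, 3.2, 0.5)))
    base_atoms.append(atom("CB", "C", "SER", 188, "A", P(0.0, 2.5, 2.2, 0.5)))

    # pocket floor: apolar carbons lining the interface under the ligand
    # footprint (gives the concave packing surface that buries the toxin face)
    anchors = [(-3.5, 2.0), (-4.4, 2.0), (-6.0, 0.0), (-1.2, 3.0), (-3.5, 5.5),
               (4.0, -3.0), (4.9, -2.8), (6.3, -1.0), (2.5, 0.5)]
    rid_floor = 300
    for t in np.arange(-8.5, 8.51, 2.0):
        for dz in np.arange(-6.0, 7.01, 2.0):
            if any((t - at) ** 2 + (dz - az) ** 2 < 2.4 ** 2 for at, az in anchors):
                continue
            theta_edge = TH if t < 0 else 0.0
            rid_floor += 1
            base_atoms.append(atom("CB", "C", "ALA", rid_floor, "A",
                                   P(theta_edge, t, 3.5, dz)))

    # ---- expand to the C5 pentamer, chains A-E ---------------------------
    chains = "ABCDE"
    receptor_atoms: list[Atom] = []
    for k, ch in enumerate(chains):
        tr = Transform.about_axis(np.zeros(3), np.array([0.0, 0.0, 1.0]), 72.0 * k)
        for a in base_atoms:
            serial[0] += 1
            receptor_atoms.append(Atom(serial[0], a.name, a.element, a.res_name,
                                       a.res_id, ch, tr.apply(a.xyz[None, :])[0],
                                       vdw_radius=a.vdw_radius, mhp_const=a.mhp_const))
    receptor = Structure(receptor_atoms, title="toy pentamer receptor")

    # ---- ligand (docked position at the A/B interface, 72 deg) -----------
    lig: list[Atom] = []
    # loop II tip: ARG 31 (bridges to GLU 205 / PHE 209 of the primary subunit)
    for name, el, off in (("NH1", "N", (-3.5, 6.2, 2.0)), ("NH2", "N", (-4.4, 6.0, 2.0)),
                          ("CZ", "C", (-3.95, 7.3, 2.0)), ("NE", "N", (-3.0, 8.2, 2.0))):
        lig.append(atom(name, el, "ARG", 31, "L", P(TH, *off)))
    # ARG 32 (bridges to ASP 186 / PHE 77 of the complementary subunit)
    for name, el, off in (("NH1", "N", (4.0, 6.2, -3.0)), ("NH2", "N", (4.9, 6.0, -2.8)),
                          ("CZ", "C", (4.45, 7.3, -3.0)), ("NE", "N", (3.5, 8.2, -3.0))):
        lig.append(atom(name, el, "ARG", 32, "L", P(TH, *off)))
    # LYS 27 (salt bridge to GLU 211)
    lig.append(atom("NZ", "N", "LYS", 27, "L", P(TH, -3.5, 6.2, 5.5)))
    lig.append(atom("CE", "C", "LYS", 27, "L", P(TH, -3.5, 7.1, 6.3)))
    # PHE 36 ring (stacks on TYR 210, capped by LYS 167)
    for name, xyz in zip(_RING_NAMES, _hexagon(P(TH, -1.2, 6.4, 3.0),
                                               P(TH, -1.2, 1.0, 3.0) - P(TH, -1.2, 0.0, 3.0))):
        lig.append(atom(name, "C", "PHE", 36, "L", xyz))
    # SER 34 (hydrogen bond to SER 188)
    lig.append(atom("OG", "O", "SER", 34, "L", P(TH, 2.5, 6.2, 0.5)))
    lig.append(atom("CB", "C", "SER", 34, "L", P(TH, 2.5, 7.2, 0.5)))
    # apolar filler across the loop II face (burial + hydrophobic matching)
    for rid, (t, dz) in zip((25, 26, 28, 29, 30, 33, 35, 37, 38, 39, 40),
                            ((-6.5, -3.5), (-6.0, 3.5), (-1.5, -2.5), (0.5, 0.8),
                             (1.5, -4.0), (2.2, 3.8), (5.8, 0.5), (6.5, -4.0),
                             (-5.8, 0.0), (6.8, 3.0), (4.5, 4.8))):
        lig.append(atom("CB", "C", "ALA", rid, "L", P(TH, t, 6.2, dz)))
    # compact body behind the tip
    rid = 101
    for bt in (-4.5, -1.5, 1.5, 4.5):
        for bdz in (-3.0, 0.0, 3.0):
            for bdr in (9.8, 12.6):
                lig.append(atom("CA", "C", "GLY", rid, "L", P(TH, bt, bdr, bdz)))
                rid += 1
    # loop I: prong toward the membrane
    for i, dz in enumerate(np.arange(-4.0, -17.0, -2.0)):
        lig.append(atom("CA", "C", "GLY", 2 + i, "L", P(TH, (-1) ** i * 0.8, 11.0, dz)))
    # loop III: prong away from the membrane
    for i, dz in enumerate(np.arange(4.0, 15.0, 2.0)):
        lig.append(atom("CA", "C", "GLY", 45 + i, "L", P(TH, 1.0 + (-1) ** i * 0.8, 11.0, dz)))

    docked = Structure(lig, title="toy toxin (docked)")
    centroid = docked.centroid()
    ligand_free = docked.with_coords(docked.coords - centroid, title="toy toxin")
    true_pose = Transform(np.eye(3), centroid.copy())

    return ToyComplex(
        receptor=receptor, ligand=ligand_free, true_pose=true_pose,
        membrane_point=np.array([0.0, 0.0, spec.membrane_z]),
        membrane_normal=np.array([0.0, 0.0, 1.0]),
        axis_point=np.zeros(3), axis_direction=np.array([0.0, 0.0, 1.0]),
        site_chains=("A", "B"), required_residues=(("L", 31), ("L", 32)),
        loop_i_range=(1, 10), loop_ii_range=(25, 40), loop_iii_range=(45, 60))


def assemble_true_complex(toy: ToyComplex) -> Structure:
    """Receptor pentamer plus the five symmetry copies of the planted toxin."""
    from .structio import c5_expand

    placed = toy.ligand.apply(toy.true_pose)
    lig5 = c5_expand(placed, toy.axis_point, toy.axis_direction)
    return Structure(list(toy.receptor.atoms) + list(lig5.atoms), title="toy true complex")


def make_experimental_map(toy: ToyComplex, spec: SynthSpec | None = None) -> DensityMap:
    """Pseudo-experimental map: the true complex blurred to the stated
    resolution plus seeded Gaussian voxel noise."""
    spec = spec or SynthSpec()
    m = simulate_map(assemble_true_complex(toy), spec.map_resolution)
    rng = _rng(spec, 1)
    noisy = m.values + rng.normal(0.0, spec.map_noise_frac * m.values.max(),
                                  size=m.values.shape)
    return DensityMap(m.origin, m.spacing, noisy)


def make_pose_ensemble(true_pose: Transform, n_decoys: int,
                       spec: SynthSpec | None = None) -> tuple[list[Pose], int]:
    """One planted pose plus rigid-perturbation decoys.

    Decoy translations are 3-25 A (guaranteeing >= 3 A centroid shift) and
    rotations 10-180 deg about the placed ligand centroid.  Returns the pose
    list and the planted pose's id (its position is seeded-random).
    """
    spec = spec or SynthSpec()
    if n_decoys < 1:
        raise ValueError("need at least one decoy")
    rng = _rng(spec, 2)
    poses = []
    centre = true_pose.translation  # ligand centroid after placement
    for i in range(n_decoys):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = rng.uniform(*spec.decoy_rot_range)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        shift = rng.uniform(*spec.decoy_shift_range)
        rot = Transform.about_axis(centre, axis, angle)
        perturb = Transform(rot.rotation, rot.translation + shift * direction)
        poses.append(perturb.compose(true_pose))
    planted_at = int(rng.integers(0, n_decoys + 1))
    transforms = poses[:planted_at] + [true_pose] + poses[planted_at:]
    return ([Pose(pose_id=i, ligand_conformer=0, receptor_conformer=0, transform=t)
             for i, t in enumerate(transforms)], planted_at)


# ---------------------------------------------------------------------------
# binding data
# ---------------------------------------------------------------------------

@dataclass
class BindingData:
    titration: TitrationSeries
    competition_normalized: CompetitionSeries   # emulates the toxin competition assay
    competition_raw: CompetitionSeries          # emulates the high-affinity control assay
    truth: dict


def make_binding_data(spec: SynthSpec | None = None) -> BindingData:
    """Langmuir titration and Hill competition series with known parameters.

    Dose grids follow the emulated assays: lipid 0-16 mM, competitor
    0.3-50 uM (normalised %, mean of replicates) and 0.01-300 nM (raw MFI).
    """
    spec = spec or SynthSpec()
    rng = _rng(spec, 3)

    lipid = np.array([0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0])  # mM
    dilution = 1.0 + 0.02 * np.arange(len(lipid))
    p_true = 1.0 - spec.langmuir_b * lipid / (lipid + spec.langmuir_k_app)
    p_obs = p_true / dilution + rng.normal(0.0, spec.titration_noise_sd, len(lipid))
    titr = TitrationSeries(lipid, np.clip(p_obs, 0.0, 1.0), dilution,
                           lipid_composition=spec.lipid_composition)

    def replicate_mean(y_true, sd):
        reps = y_true[None, :] + rng.normal(0.0, sd, (spec.n_replicates, len(y_true)))
        return reps.mean(axis=0), reps.std(axis=0, ddof=1) / math.sqrt(spec.n_replicates)

    wtx_dose = np.geomspace(0.3e-6, 50e-6, 8)  # M
    y_wtx = 100.0 / (1.0 + (wtx_dose / spec.wtx_ic50) ** spec.wtx_nh)
    y, sem = replicate_mean(y_wtx, spec.competition_noise_frac * 100.0)
    comp_norm = CompetitionSeries(wtx_dose, y, sem, normalized=True)

    bgtx_dose = np.geomspace(0.01e-9, 300e-9, 9)  # M
    y_bgtx = spec.bgtx_a0 + spec.bgtx_a1 / (1.0 + (bgtx_dose / spec.bgtx_ic50) ** spec.bgtx_nh)
    y, sem = replicate_mean(y_bgtx, spec.competition_noise_frac * spec.bgtx_a1)
    comp_raw = CompetitionSeries(bgtx_dose, y, sem, normalized=False)

    truth = dict(K_app=spec.langmuir_k_app, B=spec.langmuir_b,
                 wtx_IC50=spec.wtx_ic50, wtx_nH=spec.wtx_nh,
                 bgtx_IC50=spec.bgtx_ic50, bgtx_nH=spec.bgtx_nh,
                 bgtx_A0=spec.bgtx_a0, bgtx_A1=spec.bgtx_a1)
    return BindingData(titr, comp_norm, comp_raw, truth)


# ---------------------------------------------------------------------------
# umbrella sampling
# ---------------------------------------------------------------------------

def binding_well_potential(spec: SynthSpec):
    """Smooth bound-state well: U(xi) = -D exp(-xi^2 / (2 w^2)), kcal/mol."""
    D, w = spec.well_depth, spec.well_width

    def U(xi):
        return -D * np.exp(-xi ** 2 / (2 * w ** 2))
    return U


def harmonic_potential(kappa_kcal: float = 10.0):
    """U(xi) = 1/2 kappa xi^2 with kappa in kcal mol^-1 nm^-2."""
    def U(xi):
        return 0.5 * kappa_kcal * xi ** 2
    return U


def _metropolis(U, xi0: float, k_kj: float, temperature: float, n_samples: int,
                rng: np.random.Generator, burn_in: int = 200, thin: int = 10) -> np.ndarray:
    """Seeded Metropolis sampling from exp(-(U + bias)/kT); U in kcal/mol."""
    kt_kj = KB_KJ * temperature

    def energy_kj(x):
        return U(x) * KJ_PER_KCAL + 0.5 * k_kj * (x - xi0) ** 2

    prop_sd = math.sqrt(kt_kj / k_kj) if k_kj > 0 else 0.1
    x = xi0
    e = energy_kj(x)
    out = np.empty(n_samples)
    n_acc = 0
    total = burn_in + n_samples * thin
    steps = rng.normal(0.0, prop_sd, total)
    unif = rng.random(total)
    j = 0
    for i in range(total):
        xn = x + steps[i]
        en = energy_kj(xn)
        if en <= e or unif[i] < math.exp(-(en - e) / kt_kj):
            x, e = xn, en
            n_acc += 1
        if i >= burn_in and (i - burn_in) % thin == 0:
            out[j] = x
            j += 1
    if n_acc == 0:
        raise RuntimeError("Metropolis sampler accepted no moves (internal check)")
    return out


def make_umbrella_set(spec: SynthSpec | None = None, potential=None,
                      centres: np.ndarray | None = None,
                      k: float | None = None,
                      n_samples: int | None = None) -> tuple[list[UmbrellaWindow], dict]:
    """Umbrella windows Metropolis-sampled from a known 1-D potential.

    Defaults emulate the study layout: the staged centre scheme (0.05 nm
    steps near the minimum, then 0.1 and 0.15 nm) over the binding well,
    with the stated force constant.  Returns the windows and the ground
    truth (the potential and the exact dG of the well).
    """
    spec = spec or SynthSpec()
    rng = _rng(spec, 4)
    U = potential if potential is not None else binding_well_potential(spec)
    if centres is None:
        from .energetics import scheme_targets
        centres = scheme_targets(0.0)
        centres = centres[centres <= 6.0]
    k = spec.umbrella_k if k is None else k
    n = spec.umbrella_samples if n_samples is None else n_samples
    windows = [UmbrellaWindow(float(c), k,
                              _metropolis(U, float(c), k, spec.temperature, n, rng),
                              temperature=spec.temperature)
               for c in centres]
    truth = dict(potential=U, delta_g_bind=-spec.well_depth
                 if potential is None else None)
    return windows, truth
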