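"""Multi-stage post-scoring funnel for ensemble-docking poses.

Docking itself is external: poses enter as rigid transforms placing a ligand
conformer onto a receptor conformer.  Each pose is reconstructed into a
C5-symmetric pentameric complex (five toxin copies about the receptor's
symmetry axis, receptor scaffold fixed), then filtered through five gates in
fixed order:

1. plain correlation of the complex's simulated map with the experimental map,
2. required toxin residues must form specific contacts with the receptor,
3. packing triple: buried interface area, MHP complementarity, good-contact
   count,
4. symmetry-aware local refit (correlation-about-mean metric) with shift and
   rotation gates,
5. density-filling gates: the toxin sub-density must be covered and the
   ligand must not protrude from the map.

Per-pose metric failures (e.g. no interface) mark the pose failed; they never
abort the pipeline.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .contacts import (ContactCriteria, classify_contacts, count_good_contacts,
                       residue_has_specific_contact)
from .densfit import (MASK_FRACTION, SIGMA_FACTOR, DensityMap, fit_rigid,
                      map_correlation, simulate_map)
from .structio import Structure, Transform, c5_expand
from .surfmhp import buried_area, mhp_complementarity


@dataclass
class Pose:
    pose_id: int
    ligand_conformer: int
    receptor_conformer: int
    transform: Transform


@dataclass
class Ensembles:
    """Conformer ensembles plus the geometry shared by all poses."""

    receptors: list            # full (pre-oriented) receptor pentamers
    ligands: list              # ligand conformers in their free frame
    site_chains: tuple         # (primary, complementary) receptor chains of the site
    axis_point: np.ndarray     # C5 axis
    axis_direction: np.ndarray

    def __post_init__(self) -> None:
        self.axis_point = np.asarray(self.axis_point, dtype=float)
        self.axis_direction = np.asarray(self.axis_direction, dtype=float)


@dataclass
class FunnelConfig:
    """Thresholds of the post-scoring funnel."""

    corr_min: float = 0.83
    cam_min: float = 0.29
    shift_max: float = 5.0      # A
    rot_max: float = 5.0        # degrees
    buried_min: float = 350.0   # A^2
    mhp_min: float = 0.55
    good_contacts_min: int = 10
    required_residues: tuple = (("L", 31), ("L", 32))
    sim_resolution: float = 8.0  # A
    fill_min: float = 0.5
    protrude_max: float = 0.2
    stages_enabled: tuple = (True, True, True, True, True)
    contact_criteria: ContactCriteria = field(default_factory=ContactCriteria)
    sasa_points: int = 480

    def __post_init__(self) -> None:
        if not (0 <= self.fill_min <= 1 and 0 <= self.protrude_max <= 1):
            raise ValueError("fill/protrusion thresholds must lie in [0, 1]")
        if not (-1 <= self.corr_min <= 1 and -1 <= self.cam_min <= 1):
            raise ValueError("correlation thresholds must lie in [-1, 1]")


STAGE_NAMES = ("map_correlation", "required_contacts", "packing", "refit", "filling")

_METRIC_COLUMNS = ["corr", "required_ok", "buried", "mhp", "good_contacts",
                   "cam", "shift", "rot", "fill", "protrusion"]


def plan_ensemble_docking(n_ligand: int, n_receptor: int, n_solutions: int) -> tuple[int, int]:
    """Docking-run accounting: runs = n_ligand x n_receptor, poses = runs x n_solutions."""
    if n_ligand < 1 or n_receptor < 1 or n_solutions < 1:
        raise ValueError("all inputs must be >= 1")
    runs = n_ligand * n_receptor
    return runs, runs * n_solutions


# ---------------------------------------------------------------------------
# per-pose metric computation
# ---------------------------------------------------------------------------

def _assemble(pose: Pose, ens: Ensembles) -> tuple[Structure, Structure, Structure]:
    """Return (placed ligand, five symmetry ligand copies, full complex)."""
    receptor = ens.receptors[pose.receptor_conformer]
    ligand = ens.ligands[pose.ligand_conformer].apply(pose.transform)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # clashes among decoy copies are expected
        ligand5 = c5_expand(ligand, ens.axis_point, ens.axis_direction)
    full = Structure(list(receptor.atoms) + list(ligand5.atoms),
                     title="pose complex")
    return ligand, ligand5, full


def _site_structure(pose: Pose, ens: Ensembles, ligand: Structure):
    receptor = ens.receptors[pose.receptor_conformer]
    site_idx = [i for i, a in enumerate(receptor.atoms) if a.chain in ens.site_chains]
    site = Structure([receptor.atoms[i] for i in site_idx] + list(ligand.atoms))
    n_rec = len(site_idx)
    rec_sel = list(range(n_rec))
    lig_sel = list(range(n_rec, len(site)))
    return site, rec_sel, lig_sel


def _fill_and_protrusion(exp_map: DensityMap, receptor: Structure,
                         ligand5: Structure, cfg: FunnelConfig) -> tuple[float, float]:
    from scipy.spatial import cKDTree

    thr = MASK_FRACTION * exp_map.values.max()
    idx = np.indices(exp_map.shape, dtype=float)
    world = (exp_map.origin[:, None, None, None]
             + idx * exp_map.spacing[:, None, None, None]).reshape(3, -1).T
    exp_vals = exp_map.values.reshape(-1)
    rec_map = simulate_map(receptor, cfg.sim_resolution)
    rec_vals = rec_map.sample(world)
    toxin_voxels = (exp_vals > thr) & (rec_vals <= MASK_FRACTION * rec_map.values.max())
    if not toxin_voxels.any():
        return 1.0, 0.0
    sigma = SIGMA_FACTOR * cfg.sim_resolution
    tree = cKDTree(ligand5.coords)
    d, _ = tree.query(world[toxin_voxels])
    fill = float(np.mean(d <= 2.0 * sigma))
    lig_density = exp_map.sample(ligand5.coords)
    protrusion = float(np.mean(lig_density <= thr))
    return fill, protrusion


def score_pose(pose: Pose, ens: Ensembles, exp_map: DensityMap,
               cfg: FunnelConfig | None = None,
               stages: set[int] | None = None) -> dict:
    """Compute funnel metrics for one pose.

    `stages` limits which metric groups are evaluated (1-5); omitted groups
    stay NaN.  Errors become per-pose failures recorded in the row.
    """
    cfg = cfg or FunnelConfig()
    if stages is None:
        stages = {1, 2, 3, 4, 5}
    row: dict = {"pose_id": pose.pose_id,
                 "ligand_conformer": pose.ligand_conformer,
                 "receptor_conformer": pose.receptor_conformer,
                 "error": ""}
    for colname in _METRIC_COLUMNS:
        row[colname] = np.nan
    try:
        ligand, ligand5, full = _assemble(pose, ens)
        if 1 in stages:
            sim = simulate_map(full, cfg.sim_resolution)
            row["corr"] = map_correlation(sim, exp_map, mode="plain")
        if 2 in stages or 3 in stages:
            site, rec_sel, lig_sel = _site_structure(pose, ens, ligand)
            records = classify_contacts(site, lig_sel, rec_sel, cfg.contact_criteria)
            if 2 in stages:
                row["required_ok"] = all(residue_has_specific_contact(records, res)
                                         for res in cfg.required_residues)
            if 3 in stages:
                row["good_contacts"] = count_good_contacts(records)
                row["buried"] = buried_area(site, lig_sel, rec_sel,
                                            n_points=cfg.sasa_points)
                try:
                    row["mhp"] = mhp_complementarity(site, lig_sel, rec_sel,
                                                     n_points=cfg.sasa_points)
                except ValueError:
                    row["mhp"] = -1.0  # no interface: maximal mismatch
        if 4 in stages:
            fit = fit_rigid(full, exp_map, cfg.sim_resolution, metric="about_mean")
            row["cam"] = fit.correlation_about_mean
            row["shift"] = fit.shift
            row["rot"] = fit.rotation
        if 5 in stages:
            receptor = ens.receptors[pose.receptor_conformer]
            row["fill"], row["protrusion"] = _fill_and_protrusion(
                exp_map, receptor, ligand5, cfg)
    except Exception as exc:  # per-pose failure, not a pipeline abort
        row["error"] = f"{type(exc).__name__}: {exc}"
    return row


def _stage_pass(row: dict, stage: int, cfg: FunnelConfig) -> bool:
    if row.get("error"):
        return False

    def ok(x):
        return x is not None and not (isinstance(x, float) and np.isnan(x))

    if stage == 1:
        return ok(row["corr"]) and row["corr"] > cfg.corr_min
    if stage == 2:
        return ok(row["required_ok"]) and bool(row["required_ok"])
    if stage == 3:
        return (ok(row["buried"]) and ok(row["mhp"]) and ok(row["good_contacts"])
                and row["buried"] >= cfg.buried_min
                and row["mhp"] >= cfg.mhp_min
                and row["good_contacts"] >= cfg.good_contacts_min)
    if stage == 4:
        return (ok(row["cam"]) and row["cam"] >= cfg.cam_min
                and row["shift"] < cfg.shift_max and abs(row["rot"]) < cfg.rot_max)
    if stage == 5:
        return (ok(row["fill"]) and row["fill"] >= cfg.fill_min
                and row["protrusion"] <= cfg.protrude_max)
    raise ValueError(f"unknown stage {stage}")


@dataclass
class FunnelReport:
    table: pd.DataFrame
    stage_counts: list          # survivors after each enabled stage
    config: dict

    def to_csv(self, path_or_buf) -> None:
        buf = self.table.copy()
        buf.attrs = {}
        header = "#funnel-config " + json.dumps(self.config) + "\n"
        header += "#stage-counts " + json.dumps(self.stage_counts) + "\n"
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(header)
            buf.to_csv(path_or_buf, index=False)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(header)
                buf.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "FunnelReport":
        if hasattr(path_or_buf, "read"):
            text = path_or_buf.read()
        else:
            with open(path_or_buf) as fh:
                text = fh.read()
        lines = text.splitlines(keepends=True)
        config = json.loads(lines[0].split(" ", 1)[1])
        counts = json.loads(lines[1].split(" ", 1)[1])
        table = pd.read_csv(io.StringIO("".join(lines[2:])))
        return cls(table, counts, config)


def run_funnel(poses: list, ens: Ensembles, exp_map: DensityMap,
               cfg: FunnelConfig | None = None) -> FunnelReport:
    """Apply the five funnel stages in order, logging survivor counts.

    Stages are evaluated lazily: a pose rejected at stage k is not scored at
    later stages (its later metrics remain NaN).
    """
    cfg = cfg or FunnelConfig()
    if not poses:
        raise ValueError("need at least one pose")
    rows = {p.pose_id: {"pose_id": p.pose_id,
                        "ligand_conformer": p.ligand_conformer,
                        "receptor_conformer": p.receptor_conformer,
                        "error": "",
                        **{m: np.nan for m in _METRIC_COLUMNS},
                        **{f"pass_{n}": False for n in STAGE_NAMES}}
            for p in poses}
    alive = list(poses)
    stage_counts = []
    for stage in range(1, 6):
        if not cfg.stages_enabled[stage - 1]:
            for p in alive:
                rows[p.pose_id][f"pass_{STAGE_NAMES[stage - 1]}"] = True
            stage_counts.append(len(alive))
            continue
        survivors = []
        for p in alive:
            scored = score_pose(p, ens, exp_map, cfg, stages={stage})
            r = rows[p.pose_id]
            for m in _METRIC_COLUMNS:
                if not (isinstance(scored[m], float) and np.isnan(scored[m])):
                    r[m] = scored[m]
            if scored["error"]:
                r["error"] = scored["error"]
            passed = _stage_pass(scored, stage, cfg)
            r[f"pass_{STAGE_NAMES[stage - 1]}"] = passed
            if passed:
                survivors.append(p)
        alive = survivors
        stage_counts.append(len(alive))
    for r in rows.values():
        r["verdict"] = all(r[f"pass_{n}"] for n in STAGE_NAMES)
    table = pd.DataFrame([rows[p.pose_id] for p in poses])
    cfg_dict = asdict(cfg)
    cfg_dict["contact_criteria"] = asdict(cfg.contact_criteria)
    cfg_dict = json.loads(json.dumps(cfg_dict))  # JSON-normalised (tuples -> lists)
    return FunnelReport(table, stage_counts, cfg_dict)


def orientation_filter(poses: list, ens: Ensembles, plane_point: np.ndarray,
                       plane_normal: np.ndarray, loop_i_range: tuple,
                       loop_iii_range: tuple) -> list:
    """Keep poses whose loop-I centroid lies nearer the membrane plane than loop III.

    Distances are measured along the plane normal; ties are discarded (strict
    inequality) with a warning.
    """
    plane_point = np.asarray(plane_point, dtype=float)
    n = np.asarray(plane_normal, dtype=float)
    n = n / np.linalg.norm(n)
    kept = []
    for p in poses:
        ligand = ens.ligands[p.ligand_conformer].apply(p.transform)
        loops = []
        for lo, hi in (loop_i_range, loop_iii_range):
            idx = [i for i, a in enumerate(ligand.atoms) if lo <= a.res_id <= hi]
            if not idx:
                raise ValueError(f"no ligand atoms in residue range {lo}-{hi}")
            loops.append(ligand.coords[idx].mean(axis=0))
        d_i, d_iii = (abs(float(np.dot(c - plane_point, n))) for c in loops)
        if d_i < d_iii:
            kept.append(p)
        elif d_i == d_iii:
            warnings.warn(f"pose {p.pose_id}: loop centroids equidistant from the "
                          "membrane plane; discarded (strict rule)")
    return kept


# ---------------------------------------------------------------------------
# pose CSV I/O
# ---------------------------------------------------------------------------

_POSE_COLS = (["pose_id", "ligand_conformer", "receptor_conformer"]
              + [f"r{i}{j}" for i in range(3) for j in range(3)]
              + ["t0", "t1", "t2"])


def write_poses(poses: list, path) -> None:
    rows = []
    for p in poses:
        rows.append([p.pose_id, p.ligand_conformer, p.receptor_conformer,
                     *p.transform.rotation.reshape(-1), *p.transform.translation])
    pd.DataFrame(rows, columns=_POSE_COLS).to_csv(path, index=False)


def read_poses(path) -> list:
    df = pd.read_csv(path)
    poses = []
    for _, row in df.iterrows():
        R = np.array([[row[f"r{i}{j}"] for j in range(3)] for i in range(3)])
        t = np.array([row["t0"], row["t1"], row["t2"]])
        poses.append(Pose(int(row["pose_id"]), int(row["ligand_conformer"]),
                          int(row["receptor_conformer"]), Transform(R, t)))
    return poses
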