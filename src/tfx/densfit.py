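"""Simulated density maps, map-map correlation, and local rigid-body fitting.

Maps are sums of per-atom isotropic Gaussians with sigma = 0.225 x resolution
and amplitude proportional to the atomic number (the convention of
"molmap"-style simulated maps).  Correlation metrics:

* ``plain``      - normalised inner product over masked voxels,
* ``about_mean`` - Pearson correlation (means subtracted), the "correlation
  about mean" penalty used as the fitting metric.

The mask is the union of the two maps' own footprints (voxels above
0.1 x each map's maximum by default), which makes the metric symmetric.

``fit_rigid`` performs a deterministic steepest-ascent hill climb with step
halving over the six rigid degrees of freedom, mirroring a bounded local
"fitmap"-style optimisation rather than a global search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial.transform import Rotation

from . import _chem
from .structio import Structure, Transform

SIGMA_FACTOR = 0.225  # sigma = SIGMA_FACTOR * resolution
MASK_FRACTION = 0.1   # default mask threshold = MASK_FRACTION * map max


@dataclass
class DensityMap:
    """Voxel grid: origin (A), per-axis spacing (A/voxel), values[z-last? no: ijk]."""

    origin: np.ndarray   # (3,) position of voxel (0,0,0) centre, A
    spacing: np.ndarray  # (3,) A per voxel along x, y, z
    values: np.ndarray   # (nx, ny, nz)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive on every axis")
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValueError("grid must be a non-empty 3-D array")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def max_corner(self) -> np.ndarray:
        return self.origin + (np.array(self.shape) - 1) * self.spacing

    def world_to_grid(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.origin) / self.spacing

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation at world-coordinate points (0 outside)."""
        g = self.world_to_grid(points)
        return map_coordinates(self.values, g.T, order=1, mode="constant", cval=0.0)


def read_mrc(path) -> DensityMap:
    """Read an MRC/CCP4 map (mode-2 float) via gemmi."""
    import gemmi

    m = gemmi.read_ccp4_map(str(path), setup=True)
    grid = m.grid
    arr = np.array(grid, copy=True)
    spacing = np.array([grid.unit_cell.a / grid.nu,
                       grid.unit_cell.b / grid.nv,
                       grid.unit_cell.c / grid.nw])
    origin = np.array([m.header_float(50), m.header_float(51), m.header_float(52)])
    return DensityMap(origin, spacing, arr)


def write_mrc(density: DensityMap, path) -> None:
    """Write an MRC/CCP4 map (mode-2 float) via gemmi."""
    import gemmi

    nx, ny, nz = density.shape
    grid = gemmi.FloatGrid(nx, ny, nz)
    grid.set_unit_cell(gemmi.UnitCell(nx * density.spacing[0], ny * density.spacing[1],
                                      nz * density.spacing[2], 90, 90, 90))
    arr = np.asarray(grid, copy=False)
    arr[...] = density.values
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header(2, True)
    for k, v in zip((50, 51, 52), density.origin):
        m.set_header_float(k, float(v))
    m.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_map(s: Structure, resolution: float, spacing: float | None = None) -> DensityMap:
    """Simulate a density map: sum of per-atom Gaussians.

    sigma = 0.225 x resolution, amplitude = atomic number, grid padded 3 sigma
    beyond the atoms (per-atom Gaussians evaluated within a 3-sigma cube).
    """
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    if spacing is None:
        spacing = resolution / 3.0
    if spacing > resolution / 2.0:
        raise ValueError("spacing must be <= resolution / 2")
    sigma = SIGMA_FACTOR * resolution
    pad = 3.0 * sigma
    coords = s.coords
    amps = np.array([_chem.atomic_number(a.element) for a in s.atoms], dtype=float)
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    values = np.zeros(shape)
    sp = np.array([spacing] * 3)
    reach = int(np.ceil(pad / spacing))
    axes_cache = [np.arange(n) for n in shape]
    for xyz, amp in zip(coords, amps):
        centre = (xyz - lo) / spacing
        i0 = np.maximum(np.floor(centre).astype(int) - reach, 0)
        i1 = np.minimum(np.floor(centre).astype(int) + reach + 1, shape)
        ax = [(axes_cache[k][i0[k]:i1[k]] - centre[k]) * spacing for k in range(3)]
        gx = np.exp(-ax[0] ** 2 / (2 * sigma ** 2))
        gy = np.exp(-ax[1] ** 2 / (2 * sigma ** 2))
        gz = np.exp(-ax[2] ** 2 / (2 * sigma ** 2))
        values[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] += (
            amp * gx[:, None, None] * gy[None, :, None] * gz[None, None, :])
    return DensityMap(lo, sp, values)


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def _resample_common(a: DensityMap, b: DensityMap) -> tuple[np.ndarray, np.ndarray]:
    """Resample both maps onto a common grid spanning the union footprint."""
    lo = np.minimum(a.origin, b.origin)
    hi = np.maximum(a.max_corner(), b.max_corner())
    spacing = a.spacing
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    idx = np.indices(shape, dtype=float)
    world = lo[:, None, None, None] + idx * spacing[:, None, None, None]
    pts = world.reshape(3, -1).T
    A = a.sample(pts)
    B = b.sample(pts)
    return A, B


def _masked_values(a: DensityMap, b: DensityMap,
                   mask_threshold: float | None) -> tuple[np.ndarray, np.ndarray]:
    A, B = _resample_common(a, b)
    thr_a = MASK_FRACTION * a.values.max() if mask_threshold is None else mask_threshold
    thr_b = MASK_FRACTION * b.values.max() if mask_threshold is None else mask_threshold
    mask = (A > thr_a) | (B > thr_b)
    if not mask.any():
        raise ValueError("empty mask: no voxels above threshold")
    return A[mask], B[mask]


def map_correlation(a: DensityMap, b: DensityMap, mode: str = "plain",
                    mask_threshold: float | None = None) -> float:
    """Map-map correlation over the union-footprint mask.

    ``plain``: <a,b>/(|a||b|); ``about_mean``: Pearson correlation.
    """
    A, B = _masked_values(a, b, mask_threshold)
    if mode == "plain":
        denom = np.linalg.norm(A) * np.linalg.norm(B)
        if denom == 0:
            raise ValueError("zero-norm map inside mask")
        return float(np.dot(A, B) / denom)
    if mode == "about_mean":
        A = A - A.mean()
        B = B - B.mean()
        denom = np.linalg.norm(A) * np.linalg.norm(B)
        if denom == 0:
            raise ValueError("zero-variance map inside mask")
        return float(np.dot(A, B) / denom)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# rigid fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    transform: Transform
    correlation: float
    correlation_about_mean: float
    shift: float        # A, centroid displacement from the start
    rotation: float     # degrees from the start
    steps_used: int

    def __post_init__(self) -> None:
        if self.shift < 0 or not -180.0 <= self.rotation <= 180.0:
            raise ValueError("invalid shift/rotation")


def _metric_for_params(sim: DensityMap, target: DensityMap, centre: np.ndarray,
                       params: np.ndarray, grid_pts: np.ndarray,
                       sim_vals: np.ndarray, sim_mask: np.ndarray,
                       thr_t: float, mode: str) -> float:
    """Correlation of the transformed model map with the target.

    Rather than re-simulating the model map at every trial transform, the
    target is sampled at the rigidly transformed positions of the model
    map's own grid points - the same correlation, evaluated in the model
    frame.
    """
    R = Rotation.from_rotvec(params[3:], degrees=True).as_matrix()
    pts = (grid_pts - centre) @ R.T + centre + params[:3]
    T = map_coordinates(target.values, ((pts - target.origin) / target.spacing).T,
                        order=1, mode="constant", cval=0.0)
    mask = sim_mask | (T > thr_t)
    A = sim_vals[mask]
    B = T[mask]
    if mode == "about_mean":
        A = A - A.mean()
        B = B - B.mean()
    denom = np.linalg.norm(A) * np.linalg.norm(B)
    if denom == 0:
        return -1.0
    return float(np.dot(A, B) / denom)


def fit_rigid(s: Structure, target: DensityMap, resolution: float,
              max_steps: int = 100, metric: str = "about_mean",
              spacing: float | None = None) -> FitResult:
    """Local rigid-body fit of a structure into a target map.

    Deterministic steepest-ascent over (tx, ty, tz, rx, ry, rz) with step
    halving; the metric never decreases below its starting value.  Reports
    the final metric values, the net centroid shift (A) and net rotation
    (degrees) relative to the starting pose.
    """
    if metric not in ("plain", "about_mean"):
        raise ValueError(f"unknown metric {metric!r}")
    sim = simulate_map(s, resolution, spacing)
    centre = s.centroid()
    if float(target.sample(s.coords).max()) <= 0.0:
        raise ValueError("structure does not overlap the target map")
    idx = np.indices(sim.shape, dtype=float)
    grid_pts = (sim.origin[:, None, None, None]
                + idx * sim.spacing[:, None, None, None]).reshape(3, -1).T
    sim_vals = sim.values.reshape(-1)
    thr_s = MASK_FRACTION * sim_vals.max()
    thr_t = MASK_FRACTION * target.values.max()
    sim_mask = sim_vals > thr_s

    def score(p: np.ndarray) -> float:
        return _metric_for_params(sim, target, centre, p, grid_pts, sim_vals,
                                  sim_mask, thr_t, metric)

    params = np.zeros(6)
    best = score(params)
    trans_step, rot_step = 2.0, 4.0
    steps_used = 0
    while steps_used < max_steps and (trans_step >= 0.05 or rot_step >= 0.1):
        improved = False
        for dof in range(6):
            step = trans_step if dof < 3 else rot_step
            for sign in (1.0, -1.0):
                trial = params.copy()
                trial[dof] += sign * step
                val = score(trial)
                if val > best + 1e-12:
                    best, params = val, trial
                    improved = True
        steps_used += 1
        if not improved:
            trans_step *= 0.5
            rot_step *= 0.5

    R = Rotation.from_rotvec(params[3:], degrees=True).as_matrix()
    # x -> R (x - c) + c + t
    transform = Transform(R, centre - R @ centre + params[:3])
    shift = float(np.linalg.norm(params[:3]))
    rot_angle = Transform(R, np.zeros(3)).rotation_angle_deg()
    final_plain = _metric_for_params(sim, target, centre, params, grid_pts,
                                     sim_vals, sim_mask, thr_t, "plain")
    final_cam = _metric_for_params(sim, target, centre, params, grid_pts,
                                   sim_vals, sim_mask, thr_t, "about_mean")
    return FitResult(transform, final_plain, final_cam, shift, rot_angle, steps_used)
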