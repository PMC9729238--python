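"""Umbrella-sampling window selection, WHAM, and binding free energies.

The reaction coordinate xi (nm) is the pulled distance between the toxin and
its binding partner.  Window centres follow the staged selection scheme used
for the pulling trace (dense near the bound minimum, sparser towards the
unbound plateau); the biased samples are combined with the self-consistent
weighted-histogram equations into a potential of mean force, whose zero is
set to the curve minimum.  The binding free energy is the plateau average
minus the minimum, reported with the binding sign convention (bound state
lower => negative dG).

Units: xi in nm, force constants in kJ mol^-1 nm^-2 (GROMACS convention),
free energies in kcal/mol (1 kcal = 4.184 kJ).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

KB_KJ = 0.00831446261815324  # kJ/(mol K)
KJ_PER_KCAL = 4.184
DEFAULT_TEMPERATURE = 310.0  # K


@dataclass
class PullingTrace:
    """Time series of the reaction coordinate during a pulling run."""

    times: np.ndarray  # ps
    xi: np.ndarray     # nm

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.xi = np.asarray(self.xi, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class UmbrellaWindow:
    xi0: float                 # bias centre, nm
    k: float                   # kJ mol^-1 nm^-2
    samples: np.ndarray        # xi values, nm
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.k <= 0:
            raise ValueError("force constant must be > 0")
        if len(self.samples) < 100:
            raise ValueError("need >= 100 samples per window for WHAM")


@dataclass
class PMFProfile:
    xi_grid: np.ndarray  # nm (bin centres)
    g: np.ndarray        # kcal/mol, min = 0
    se: np.ndarray       # kcal/mol, bootstrap
    zero_convention: str = "minimum of the curve"


@dataclass
class DeltaG:
    value: float         # kcal/mol, binding convention (negative = favourable)
    sd: float            # kcal/mol
    plateau_start: float  # nm

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


# default scheme: 20 x 0.05 nm in [0, 1), 10 x 0.1 nm in [1, 2), 43 x 0.15 nm beyond
DEFAULT_WINDOW_SCHEME = (((0.0, 1.0), 0.05), ((1.0, 2.0), 0.1), ((2.0, 8.45), 0.15))


def scheme_targets(xi_min: float, scheme=DEFAULT_WINDOW_SCHEME) -> np.ndarray:
    """Desired window distances: staged offsets added to the rounded minimum."""
    offsets = []
    for (lo, hi), step in scheme:
        offsets.extend(np.arange(lo, hi - 1e-9, step))
    return np.round(xi_min + np.asarray(offsets), 10)


def select_windows(trace: PullingTrace, scheme=DEFAULT_WINDOW_SCHEME) -> list[tuple[float, float]]:
    """Pick trace samples closest to the staged target distances.

    The minimum xi of the trace is rounded to the nearest 0.01 nm before
    offsets are applied.  Ties resolve to the earliest time.  Targets beyond
    the trace's range (by more than half the local step) raise an error
    listing the uncovered targets.
    """
    xi_min = np.round(trace.xi.min(), 2)
    targets = scheme_targets(xi_min, scheme)
    steps = []
    for (lo, hi), step in scheme:
        steps.extend([step] * len(np.arange(lo, hi - 1e-9, step)))
    chosen = []
    uncovered = []
    for target, step in zip(targets, steps):
        diffs = np.abs(trace.xi - target)
        i = int(np.argmin(diffs))  # argmin takes first: earliest time on ties
        if diffs[i] > step / 2 + 1e-9:
            uncovered.append(float(target))
            continue
        chosen.append((float(target), float(trace.times[i])))
    if uncovered:
        raise ValueError(f"trace does not cover {len(uncovered)} target distances: "
                         f"{uncovered[:5]}{'...' if len(uncovered) > 5 else ''}")
    return chosen


def wham_pmf(windows: list[UmbrellaWindow], n_bins: int = 400, tol: float = 1e-6,
             max_iter: int = 50000, n_bootstrap: int = 50, seed: int = 0,
             min_bin_count: int = 10) -> PMFProfile:
    """Self-consistent WHAM estimate of the PMF from biased windows.

    Iterates the standard coupled equations for the unbiased distribution and
    the per-window free-energy shifts until the shifts change by less than
    `tol` (kJ/mol).  Bins with fewer than `min_bin_count` total samples are
    reported as +inf (far-tail bins otherwise produce spurious minima).
    The bootstrap standard error resamples whole windows.
    """
    if not windows:
        raise ValueError("need at least one window")
    _check_overlap(windows)
    T = windows[0].temperature
    beta = 1.0 / (KB_KJ * T)
    allx = np.concatenate([w.samples for w in windows])
    edges = np.linspace(allx.min(), allx.max() + 1e-12, n_bins + 1)
    centres = 0.5 * (edges[:-1] + edges[1:])

    def solve(idx: list[int]) -> np.ndarray:
        H = np.array([np.histogram(windows[i].samples, bins=edges)[0] for i in idx],
                     dtype=float)
        N = H.sum(axis=1)
        bias = np.array([0.5 * windows[i].k * (centres - windows[i].xi0) ** 2
                         for i in idx])
        expb = np.exp(-beta * bias)
        f = np.zeros(len(idx))
        num = H.sum(axis=0)
        for _ in range(max_iter):
            denom = (N * np.exp(beta * f)) @ expb
            with np.errstate(divide="ignore", invalid="ignore"):
                P = np.where(denom > 0, num / denom, 0.0)
            z = expb @ P
            f_new = np.where(z > 0, -np.log(z) / beta, f)
            f_new -= f_new[0]
            if np.max(np.abs(f_new - f)) < tol:
                f = f_new
                break
            f = f_new
        else:
            raise RuntimeError(f"WHAM did not converge in {max_iter} iterations")
        with np.errstate(divide="ignore"):
            g = np.where((P > 0) & (num >= min_bin_count), -np.log(P) / beta, np.inf)
        g = g / KJ_PER_KCAL
        return g - g[np.isfinite(g)].min()

    g = solve(list(range(len(windows))))

    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_bootstrap):
        idx = sorted(rng.integers(0, len(windows), size=len(windows)).tolist())
        try:
            boots.append(solve(idx))
        except (RuntimeError, ValueError):
            continue
    if boots:
        B = np.array(boots)
        B[~np.isfinite(B)] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            se = np.nanstd(B, axis=0)
        se = np.nan_to_num(se)
    else:
        se = np.zeros_like(g)
    return PMFProfile(centres, g, se)


def _check_overlap(windows: list[UmbrellaWindow]) -> None:
    """Adjacent windows' sampled ranges must overlap."""
    order = sorted(range(len(windows)), key=lambda i: windows[i].xi0)
    for a, b in zip(order[:-1], order[1:]):
        if windows[a].samples.max() < windows[b].samples.min():
            raise ValueError(
                f"non-overlapping windows: gap between xi0={windows[a].xi0:.3f} "
                f"and xi0={windows[b].xi0:.3f} nm")


def single_window_pmf(window: UmbrellaWindow, n_bins: int = 50) -> PMFProfile:
    """PMF of one unbiased window: -kT ln(histogram), min set to 0."""
    T = window.temperature
    kt_kcal = KB_KJ * T / KJ_PER_KCAL
    hist, edges = np.histogram(window.samples, bins=n_bins)
    centres = 0.5 * (edges[:-1] + edges[1:])
    with np.errstate(divide="ignore"):
        g = np.where(hist > 0, -kt_kcal * np.log(hist.astype(float)), np.inf)
    g -= g[np.isfinite(g)].min()
    return PMFProfile(centres, g, np.zeros_like(g))


def delta_g(profile: PMFProfile, plateau_start: float = 4.2) -> DeltaG:
    """Binding free energy: plateau average minus the (zeroed) minimum.

    dG_bind is reported as the negative of the plateau height, so a deep
    bound-state well gives a negative (favourable) binding energy.
    """
    mask = (profile.xi_grid > plateau_start) & np.isfinite(profile.g)
    if not mask.any():
        raise ValueError(f"no PMF points beyond plateau_start = {plateau_start} nm")
    plateau = profile.g[mask]
    return DeltaG(value=-float(plateau.mean()), sd=float(plateau.std()),
                  plateau_start=plateau_start)
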