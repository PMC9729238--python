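"""Pore-radius profile along a channel axis and open/closed classification.

At each position z along the axis the largest sphere that fits in the pore is
found by maximising the clearance min_i(|c - x_i| - r_i) over the in-plane
sphere centre c.  The search is deterministic: 16 ring starts around the
previous slice's centre plus the axis point, each refined by Nelder-Mead.
A slice is water-permeable iff its radius is at least the water probe radius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .structio import Structure

WATER_RADIUS = 1.4  # A
RADIUS_CAP = 15.0   # A: reported when no atoms bound the sphere


@dataclass
class PoreProfile:
    z: np.ndarray              # A along the axis
    radius: np.ndarray         # A
    center_xy: np.ndarray      # (n, 2) in-plane offsets of the pore centre
    permeable: np.ndarray      # bool per slice
    capped: np.ndarray         # bool: radius hit the search cap (no bounding atoms)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.z) <= 0):
            raise ValueError("z must be strictly increasing")
        if np.any(self.radius < 0):
            raise ValueError("radius must be >= 0")


def _plane_basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = direction / np.linalg.norm(direction)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, d)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(d, ref)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


def pore_profile(s: Structure, axis_point: np.ndarray, axis_direction: np.ndarray,
                 z_range: tuple[float, float], step: float = 1.0,
                 water_radius: float = WATER_RADIUS,
                 radius_cap: float = RADIUS_CAP) -> PoreProfile:
    """Largest-sphere pore radius at each z along the axis.

    `z_range` is measured along the (normalised) axis direction from
    `axis_point`.  Slices whose best sphere reaches `radius_cap` carry the
    capped flag (no atoms bound the pore there).
    """
    z0, z1 = z_range
    if z1 <= z0:
        raise ValueError("empty z range")
    axis_point = np.asarray(axis_point, dtype=float)
    d = np.asarray(axis_direction, dtype=float)
    d = d / np.linalg.norm(d)
    u, v = _plane_basis(d)
    coords = s.coords
    radii = np.array([a.vdw_radius if a.vdw_radius is not None else 1.7
                      for a in s.atoms])

    zs = np.arange(z0, z1 + 1e-9, step)
    n = len(zs)
    out_r = np.empty(n)
    out_c = np.empty((n, 2))
    capped = np.zeros(n, dtype=bool)
    prev = np.zeros(2)
    ring = np.array([[np.cos(t), np.sin(t)]
                     for t in np.linspace(0, 2 * np.pi, 16, endpoint=False)])

    for k, z in enumerate(zs):
        base = axis_point + z * d

        def clearance(c2):
            p = base + c2[0] * u + c2[1] * v
            return float(np.min(np.linalg.norm(coords - p, axis=1) - radii))

        starts = [prev, np.zeros(2)] + [prev + 2.0 * r for r in ring]
        best_c, best_r = None, -np.inf
        for c0 in starts:
            res = minimize(lambda c: -clearance(c), x0=c0, method="Nelder-Mead",
                           options=dict(xatol=1e-3, fatol=1e-4, maxiter=200))
            r = -res.fun
            if r > best_r:
                best_r, best_c = r, res.x
        if best_r >= radius_cap:
            best_r = radius_cap
            capped[k] = True
        out_r[k] = max(best_r, 0.0)
        out_c[k] = best_c
        prev = best_c
    return PoreProfile(zs, out_r, out_c, out_r >= water_radius, capped)
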