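"""Vesicle-titration and cell-assay binding analytics.

Covers three experiments:

* per-residue NMR cross-peak attenuation upon vesicle addition, normalised to
  the dataset maximum and thresholded into interacting / non-interacting
  residues;
* one-site Langmuir binding isotherms for the apparent free-toxin fraction
  P_free(C_L) = 1 - B*C_L/(C_L + K_app), fitted to dilution-corrected
  observations;
* Hill-equation competition curves, in normalised
  (y = 100 / (1 + ([T]/IC50)^nH)) or raw
  (y = A0 + A1 / (1 + ([T]/IC50)^nH)) form.

Fits use bounded least squares with deterministic multi-starts from four
log-spaced IC50/K seeds spanning the dose range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares


@dataclass
class TitrationSeries:
    """Vesicle titration: lipid concentration (mM) vs apparent free fraction."""

    lipid_conc: np.ndarray       # mM, strictly increasing, >= 0
    p_free_obs: np.ndarray       # in [0, 1]
    dilution_factor: np.ndarray  # >= 1
    lipid_composition: str = ""

    def __post_init__(self) -> None:
        self.lipid_conc = np.asarray(self.lipid_conc, dtype=float)
        self.p_free_obs = np.asarray(self.p_free_obs, dtype=float)
        self.dilution_factor = np.asarray(self.dilution_factor, dtype=float)
        if np.any(self.lipid_conc < 0) or np.any(np.diff(self.lipid_conc) <= 0):
            raise ValueError("lipid_conc must be non-negative and strictly increasing")
        if np.any(self.dilution_factor < 1):
            raise ValueError("dilution_factor must be >= 1")


@dataclass
class CompetitionSeries:
    """Competition dose-response: toxin concentration (M) vs response."""

    toxin_conc: np.ndarray  # M, > 0
    response: np.ndarray    # % (normalized) or MFI a.u. (raw)
    sem: np.ndarray | None = None
    normalized: bool = True

    def __post_init__(self) -> None:
        self.toxin_conc = np.asarray(self.toxin_conc, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)
        if np.any(self.toxin_conc <= 0):
            raise ValueError("toxin_conc must be > 0")


@dataclass
class FitResult1D:
    params: dict
    stderr: dict
    rss: float
    converged: bool


def _stderr_from_jac(res, n_obs: int) -> np.ndarray:
    dof = max(n_obs - res.x.size, 1)
    s2 = 2 * res.cost / dof
    try:
        cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
        return np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        return np.full(res.x.size, np.nan)


# ---------------------------------------------------------------------------
# attenuation classification
# ---------------------------------------------------------------------------

def classify_attenuation(table: pd.DataFrame, threshold: float = 0.5) -> pd.DataFrame:
    """Normalised relative attenuation per residue and interaction flags.

    relative_attenuation_i = (1 - I_ves,i / I_free,i) / max_j (1 - I_ves,j / I_free,j);
    a residue interacts with the vesicles iff its value is >= `threshold`.
    Expects columns ``res_id``, ``intensity_free``, ``intensity_with_vesicles``.
    """
    t = table.dropna(subset=["intensity_free", "intensity_with_vesicles"]).copy()
    if len(t) == 0:
        raise ValueError("need at least one residue with both intensities")
    if np.any(t["intensity_free"] <= 0):
        raise ValueError("intensity_free must be > 0")
    raw = 1.0 - t["intensity_with_vesicles"] / t["intensity_free"]
    m = raw.max()
    if m <= 0:
        raise ValueError("no binding signal: all attenuations are zero or negative")
    t["relative_attenuation"] = raw / m
    t["interacting"] = t["relative_attenuation"] >= threshold
    return t[["res_id", "relative_attenuation", "interacting"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Langmuir isotherm
# ---------------------------------------------------------------------------

def fit_langmuir(t: TitrationSeries) -> FitResult1D:
    """One-site Langmuir fit of the dilution-corrected free fraction.

    Model: p_free(C_L) = 1 - B * C_L / (C_L + K_app); the observed fractions
    are multiplied by the dilution factor before fitting.
    """
    if len(t.lipid_conc) < 4:
        raise ValueError("need at least 4 titration points")
    y = t.p_free_obs * t.dilution_factor
    C = t.lipid_conc

    def resid(theta):
        B, logK = theta
        K = 10.0 ** logK
        return 1.0 - B * C / (C + K) - y

    pos = C[C > 0]
    lo, hi = pos.min(), pos.max()
    seeds = np.log10(np.geomspace(lo, hi, 4))
    bounds = ([0.0, np.log10(lo) - 3], [1.0, np.log10(hi) + 3])
    best = None
    for s in seeds:
        res = least_squares(resid, x0=[0.5, s], bounds=bounds)
        if best is None or res.cost < best.cost:
            best = res
    B, logK = best.x
    K = 10.0 ** logK
    err = _stderr_from_jac(best, len(C))
    K_err = K * np.log(10) * err[1]
    at_bound = (logK <= bounds[0][1] + 1e-6) or (logK >= bounds[1][1] - 1e-6)
    # K far outside the sampled range (or a vanishing amplitude) means the
    # isotherm did not constrain the binding constant
    identifiable = lo / 10 <= K <= hi * 10
    converged = bool(best.success and B > 0.05 and not at_bound and identifiable)
    return FitResult1D(params={"K_app": float(K), "B": float(B)},
                       stderr={"K_app": float(K_err), "B": float(err[0])},
                       rss=float(2 * best.cost), converged=converged)


# ---------------------------------------------------------------------------
# Hill equation
# ---------------------------------------------------------------------------

def fit_hill(c: CompetitionSeries, form: str = "normalized") -> FitResult1D:
    """Hill-equation fit of a competition series.

    ``normalized``: y = 100 / (1 + ([T]/IC50)^nH), parameters (IC50, nH);
    ``raw``: y = A0 + A1 / (1 + ([T]/IC50)^nH), parameters (A0, A1, IC50, nH).
    IC50 is optimised on a log grid with four deterministic multi-starts.
    """
    if form not in ("normalized", "raw"):
        raise ValueError(f"unknown form {form!r}")
    x = c.toxin_conc
    y = c.response
    if len(x) < 5:
        raise ValueError("need at least 5 dose points")
    lo, hi = x.min(), x.max()
    seeds = np.log10(np.geomspace(lo, hi, 4))
    log_lo, log_hi = np.log10(lo) - 2, np.log10(hi) + 2

    if form == "normalized":
        def resid(theta):
            logI, n = theta
            return 100.0 / (1.0 + (x / 10.0 ** logI) ** n) - y
        x0s = [[s, 1.0] for s in seeds]
        bounds = ([log_lo, 0.2], [log_hi, 6.0])
    else:
        span = y.max() - y.min()
        def resid(theta):
            A0, A1, logI, n = theta
            return A0 + A1 / (1.0 + (x / 10.0 ** logI) ** n) - y
        x0s = [[y.min(), span, s, 1.0] for s in seeds]
        bounds = ([y.min() - 2 * span - 1, 0.0, log_lo, 0.2],
                  [y.max() + 2 * span + 1, 4 * span + 1, log_hi, 6.0])

    best = None
    for x0 in x0s:
        res = least_squares(resid, x0=x0, bounds=bounds)
        if best is None or res.cost < best.cost:
            best = res
    err = _stderr_from_jac(best, len(x))
    if form == "normalized":
        logI, n = best.x
        names = ["IC50", "nH"]
        values = [10.0 ** logI, n]
        errs = [10.0 ** logI * np.log(10) * err[0], err[1]]
        idx_logI = 0
    else:
        A0, A1, logI, n = best.x
        names = ["A0", "A1", "IC50", "nH"]
        values = [A0, A1, 10.0 ** logI, n]
        errs = [err[0], err[1], 10.0 ** logI * np.log(10) * err[2], err[3]]
        idx_logI = 2
    # IC50 pinned to the extended bounds means the data do not constrain it
    at_bound = (best.x[idx_logI] <= log_lo + 1e-6) or (best.x[idx_logI] >= log_hi - 1e-6)
    identifiable = 10.0 ** best.x[idx_logI] <= 100 * hi and 10.0 ** best.x[idx_logI] >= lo / 100
    converged = bool(best.success and not at_bound and identifiable)
    return FitResult1D(params=dict(zip(names, (float(v) for v in values))),
                       stderr=dict(zip(names, (float(e) for e in errs))),
                       rss=float(2 * best.cost), converged=converged)
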