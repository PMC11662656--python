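"""Single-site binding isotherm for NMR titrations, and melting midpoints.

Chemical shift perturbations (CSP, ppm) observed while titrating a ligand
at concentration [L] into a labeled species held at [P_tot] follow the
quadratic (ligand-depletion) single-site isotherm

    CSP = CSP_max * ((L + P_tot + Kd) - sqrt((L + P_tot + Kd)^2 - 4 L P_tot))
          / (2 P_tot)

from which (Kd, CSP_max) are estimated by unweighted least squares.  The
melting temperature T_m of a normalized intensity-vs-temperature curve is
read at the first crossing of half the low-temperature plateau, linearly
interpolated between bracketing samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "TitrationSeries",
    "BindingFit",
    "MeltCurve",
    "isotherm",
    "fit_isotherm",
    "melting_midpoint",
]


@dataclass(frozen=True)
class TitrationSeries:
    """Titration table: constant [P_tot] (uM) and (L, CSP) points (uM, ppm)."""

    p_tot: float
    L: np.ndarray
    csp: np.ndarray

    def __post_init__(self) -> None:
        L = np.asarray(self.L, dtype=float)
        csp = np.asarray(self.csp, dtype=float)
        if self.p_tot <= 0:
            raise ValueError("P_tot must be > 0")
        if L.shape != csp.shape or L.ndim != 1:
            raise ValueError("L and CSP must be 1-D arrays of equal length")
        if L.size < 4:
            raise ValueError("need at least 4 titration points for fitting")
        if np.any(L < 0) or np.any(csp < 0):
            raise ValueError("concentrations and CSPs must be non-negative")
        object.__setattr__(self, "L", L)
        object.__setattr__(self, "csp", csp)


@dataclass(frozen=True)
class BindingFit:
    k_d: float  # uM
    csp_max: float  # ppm
    rss: float
    converged: bool


@dataclass(frozen=True)
class MeltCurve:
    """(temperature, normalized intensity) points; T strictly increasing."""

    T: np.ndarray
    intensity: np.ndarray
    reference: str = ""

    def __post_init__(self) -> None:
        T = np.asarray(self.T, dtype=float)
        I = np.asarray(self.intensity, dtype=float)
        if T.shape != I.shape or T.ndim != 1 or T.size < 3:
            raise ValueError("need matching 1-D arrays with >= 3 points")
        if np.any(np.diff(T) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if np.any(I < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "T", T)
        object.__setattr__(self, "intensity", I)


def isotherm(L, p_tot: float, k_d: float, csp_max: float):
    """Quadratic single-site isotherm CSP(L); discriminant clamped at >= 0."""
    if p_tot <= 0:
        raise ValueError("P_tot must be > 0")
    L = np.asarray(L, dtype=float)
    s = L + p_tot + k_d
    disc = np.maximum(s**2 - 4.0 * L * p_tot, 0.0)
    out = csp_max * (s - np.sqrt(disc)) / (2.0 * p_tot)
    return out if out.ndim else float(out)


def fit_isotherm(series: TitrationSeries) -> BindingFit:
    """Least-squares estimate of (Kd, CSP_max) from a titration series.

    A coarse log grid over Kd in [1e-2, 1e5] uM (with CSP_max solved in
    closed form per grid point, the model being linear in CSP_max) seeds a
    local trust-region refinement of both parameters.
    """
    L, y = series.L, series.csp
    if np.allclose(y, y[0]):
        raise ValueError("CSP values have zero variance; nothing to fit")

    def shape(kd: float) -> np.ndarray:
        return isotherm(L, series.p_tot, kd, 1.0)

    best = None
    for kd in np.geomspace(1e-2, 1e5, 60):
        f = shape(kd)
        denom = float(f @ f)
        if denom <= 0:
            continue
        a = max(float(f @ y) / denom, 1e-12)
        rss = float(np.sum((y - a * f) ** 2))
        if best is None or rss < best[2]:
            best = (kd, a, rss)
    assert best is not None
    kd0, a0, _ = best

    def resid(theta: np.ndarray) -> np.ndarray:
        kd, a = np.exp(theta)
        return isotherm(L, series.p_tot, kd, a) - y

    sol = least_squares(
        resid,
        x0=np.log([kd0, a0]),
        method="lm",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-12,
    )
    kd, a = np.exp(sol.x)
    return BindingFit(
        k_d=float(kd),
        csp_max=float(a),
        rss=float(np.sum(sol.fun**2)),
        converged=bool(sol.success),
    )


def melting_midpoint(curve: MeltCurve) -> float:
    """T_m: first crossing of half the low-temperature plateau.

    The plateau is the mean of the first two intensities; the curve is
    normalized to it and T_m is the temperature of the first downward
    crossing of 0.5, linearly interpolated between the bracketing samples
    (a sample lying exactly at 0.5 returns that sample's temperature).
    """
    plateau = float(np.mean(curve.intensity[:2]))
    if plateau <= 0:
        raise ValueError("low-temperature plateau intensity is zero")
    y = curve.intensity / plateau
    T = curve.T
    for i in range(len(y)):
        if y[i] == 0.5:
            return float(T[i])
        if i and y[i - 1] > 0.5 > y[i]:
            frac = (y[i - 1] - 0.5) / (y[i - 1] - y[i])
            return float(T[i - 1] + frac * (T[i] - T[i - 1]))
    raise ValueError("melting not reached: intensity never crosses half the plateau")
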