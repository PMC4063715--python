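"""Linear-demographic layer: objective function, Euler-Lotka fitness, R0,
breeding-age density and cumulants, renewal-equation diagnostics.

The bridge object is the :class:`ErsCurve`: the expectation of reproductive
success ``F(tau)`` (net reproduction function), either on an age grid
(iteroparous), as a list of point-mass atoms (semelparous maturity bursts),
or both.  Its Laplace transform

    phi(lam) = int_0^inf e^{-lam tau} F(tau) dtau   (+ exact atom sums)

is the objective function of the optimal life-schedule problem; the fitness
(intrinsic rate of natural increase) is the unique root of phi(lam) = 1, and
log phi is the cumulant generating function of breeding age in the stable
population.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ErsCurve",
    "DemographicSolution",
    "objective_from_ers",
    "solve_euler_lotka",
    "breeding_age_density",
    "breeding_age_cumulants",
    "renewal_residual",
    "ExtinctionRangeError",
]


class ExtinctionRangeError(RuntimeError):
    """phi(lam) < 1 for every probed lam: fitness below the probe range."""


@dataclass
class ErsCurve:
    """Net reproduction function F(tau) >= 0 on an age grid and/or atoms."""

    ages: np.ndarray | None = None
    values: np.ndarray | None = None
    atoms: list[tuple[float, float]] = field(default_factory=list)
    se: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.ages is not None:
            self.ages = np.asarray(self.ages, float)
            self.values = np.asarray(self.values, float)
            if np.any(self.values < -1e-12):
                raise ValueError("ERS must be nonnegative")
            self.values = np.clip(self.values, 0.0, None)
        for _, w in self.atoms:
            if w < 0:
                raise ValueError("atom weights must be nonnegative")

    def to_frame(self):
        import pandas as pd

        if self.ages is not None:
            return pd.DataFrame({"age": self.ages, "F": self.values})
        return pd.DataFrame(self.atoms, columns=["age", "weight"])


@dataclass
class DemographicSolution:
    """Fitness and derived population structure for one life history."""

    fitness: float
    R0: float
    psi_ages: np.ndarray | None = None
    psi: np.ndarray | None = None
    cumulants: dict[int, float] = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)


def objective_from_ers(ers: ErsCurve, lam: float) -> float:
    """phi(lam): trapezoid over the grid part plus exact sums over atoms."""
    total = 0.0
    if ers.ages is not None and len(ers.ages) > 1:
        with np.errstate(over="raise"):
            try:
                total += float(
                    np.trapezoid(np.exp(-lam * ers.ages) * ers.values, ers.ages)
                )
            except FloatingPointError:
                return math.inf
    if ers.atoms:
        arr = np.asarray(ers.atoms, float)
        with np.errstate(over="ignore"):
            total += float(np.sum(arr[:, 1] * np.exp(-lam * arr[:, 0])))
    return total


def _as_phi(ers_or_phi) -> Callable[[float], float]:
    if isinstance(ers_or_phi, ErsCurve):
        return lambda lam: objective_from_ers(ers_or_phi, lam)

    def safe(lam: float) -> float:
        # poles/overflow below the abscissa of convergence read as +inf
        try:
            v = ers_or_phi(lam)
        except (ZeroDivisionError, OverflowError, FloatingPointError):
            return math.inf
        return v if not math.isnan(v) else math.inf

    return safe


def solve_euler_lotka(
    ers_or_phi,
    tol: float = 1e-10,
    lam_init: tuple[float, float] = (-1.0, 1.0),
    max_doublings: int = 60,
    cumulant_orders: Sequence[int] = (1, 2, 3, 4),
) -> DemographicSolution:
    """Solve the Euler-Lotka equation phi(lam) = 1 for the fitness.

    phi must be (weakly) monotone decreasing with phi -> 0 as lam -> inf.
    The bracket is expanded by doubling outward from ``lam_init`` and the
    root polished with a bracketed solver to ``tol`` on ``phi - 1``.  The
    solution carries R0 = phi(0), the breeding-age density (when an
    :class:`ErsCurve` was supplied), and the first four breeding-age
    cumulants from finite differences of log phi.
    """
    phi = _as_phi(ers_or_phi)
    lo, hi = float(lam_init[0]), float(lam_init[1])

    f_hi = phi(hi)
    k = 0
    while f_hi >= 1.0 and k < max_doublings:
        hi = hi * 2.0 if hi > 0 else 1.0
        f_hi = phi(hi)
        k += 1
    if f_hi >= 1.0:
        raise RuntimeError("phi does not fall below 1: no finite fitness root")

    f_lo = phi(lo)
    k = 0
    while f_lo <= 1.0 and k < max_doublings:
        lo = lo * 2.0 if lo < 0 else -1.0
        f_lo = phi(lo)
        if math.isinf(f_lo):  # passed the abscissa of convergence: root inside
            f_lo = math.inf
            break
        k += 1
    if f_lo <= 1.0:
        raise ExtinctionRangeError(
            f"phi({lo}) = {f_lo} <= 1 for the whole probe range"
        )

    # shrink an infinite left endpoint back to a finite bracket
    while math.isinf(phi(lo)):
        lo = 0.5 * (lo + hi)

    root = brentq(lambda l: phi(l) - 1.0, lo, hi, xtol=1e-14, rtol=8.9e-16)
    root = float(root)
    resid = phi(root) - 1.0
    if abs(resid) > tol:
        warnings.warn(f"Euler-Lotka residual {resid:.2e} above tol {tol:.1e}")

    R0 = phi(0.0)
    sol = DemographicSolution(
        fitness=root,
        R0=float(R0),
        diagnostics={"bracket": (lo, hi), "residual": float(resid)},
    )
    try:
        for k_ord in cumulant_orders:
            sol.cumulants[k_ord] = breeding_age_cumulants(phi, root, k_ord)
    except Exception as exc:  # cumulants are auxiliary; never block the root
        sol.diagnostics["cumulant_error"] = repr(exc)
    if isinstance(ers_or_phi, ErsCurve):
        ages, psi, Z = breeding_age_density(ers_or_phi, root)
        sol.psi_ages, sol.psi = ages, psi
        sol.diagnostics["psi_normalization"] = Z
    return sol


def breeding_age_density(ers: ErsCurve, lam: float):
    """Stable-population breeding-age density ``psi(a) ~ e^{-lam a} F(a)``.

    Returns ``(ages, psi, Z)`` where Z is the raw normalization constant;
    at the Euler-Lotka root Z = phi(lam) = 1, so its deviation from 1 is a
    solver diagnostic.  Atom-only curves return the reweighted atoms as
    ``(ages, masses, Z)`` with masses summing to 1.
    """
    Z = objective_from_ers(ers, lam)
    if ers.ages is not None and len(ers.ages) > 1:
        psi = np.exp(-lam * ers.ages) * ers.values
        if ers.atoms:
            raise NotImplementedError("mixed grid+atom density not supported")
        return ers.ages, psi / Z, float(Z)
    arr = np.asarray(ers.atoms, float)
    ts = arr[:, 0]
    ws = arr[:, 1] * np.exp(-lam * ts)
    order = np.argsort(ts)
    return ts[order], ws[order] / Z, float(Z)


_FD_COEFFS = {
    1: (np.array([-0.5, 0.0, 0.5]), 1),
    2: (np.array([1.0, -2.0, 1.0]), 1),
    3: (np.array([-0.5, 1.0, 0.0, -1.0, 0.5]), 2),
    4: (np.array([1.0, -4.0, 6.0, -4.0, 1.0]), 2),
}


def breeding_age_cumulants(
    phi: Callable[[float], float], lam_star: float, k: int, h: float | None = None
) -> float:
    """k-th cumulant of breeding age from derivatives of log phi.

    The moment generating function of the breeding-age density is
    ``M(s) = phi(lam* - s) / phi(lam*)``, so the k-th cumulant equals
    ``(-1)^k d^k log phi / d lam^k`` at lam*.  Central finite differences
    with a three-point step-halving stability check.
    """
    if k not in _FD_COEFFS:
        raise ValueError("cumulant order must be 1..4")
    phi = _as_phi(phi)
    coeffs, half = _FD_COEFFS[k]

    def fd(hh: float) -> float:
        pts = [
            math.log(phi(lam_star + (i - half) * hh))
            for i in range(len(coeffs))
        ]
        return float(np.dot(coeffs, pts) / hh ** k)

    if h is None:
        h = max(1e-3, 1e-2 * abs(lam_star)) * (1.0 if k <= 2 else 3.0)
    v1, v2 = fd(h), fd(h / 2.0)
    if abs(v1 - v2) > 1e-3 * max(1.0, abs(v2)) + 1e-6:
        v3 = fd(h / 4.0)
        if abs(v2 - v3) > abs(v1 - v2):
            warnings.warn(f"cumulant order {k}: finite-difference step instability")
        v2 = v3
    return ((-1.0) ** k) * v2


def renewal_residual(
    ers: ErsCurve, lam: float, horizon: float, dt: float = 0.02
):
    """Forward renewal-equation diagnostic.

    Simulates the offspring dynamics ``B(t) = G(t) + int_0^t F(a) B(t-a) da``
    from a unit founding cohort (G = F), fits the log-slope of B on the tail,
    and returns ``(slope - lam, oscillation amplitude, (times, B))``.  The
    slope should converge to the Euler-Lotka root (Sharp-Lotka-Feller).
    """
    nt = int(round(horizon / dt)) + 1
    times = np.arange(nt) * dt
    # F sampled on the dt grid; atoms spread onto their nearest cell
    F = np.zeros(nt)
    if ers.ages is not None and len(ers.ages) > 1:
        F += np.interp(times, ers.ages, ers.values, left=0.0, right=0.0)
    if ers.atoms:
        arr = np.asarray(ers.atoms, float)
        j = np.round(arr[:, 0] / dt).astype(int)
        keep = (j >= 0) & (j < nt)
        np.add.at(F, j[keep], arr[keep, 1] / dt)
    # implicit trapezoid for B(t) = F(t) + int_0^t F(a) B(t-a) da; the a = 0
    # endpoint involves B(t) itself, hence the (1 - dt F0 / 2) divisor
    B = np.zeros(nt)
    B[0] = F[0]
    denom = 1.0 - 0.5 * dt * F[0]
    if denom <= 0:
        raise ValueError("renewal step too coarse for this fertility scale")
    for i in range(1, nt):
        inner = float(F[1:i] @ B[i - 1 : 0 : -1]) if i >= 2 else 0.0
        conv = dt * (inner + 0.5 * F[i] * B[0])
        B[i] = (F[i] + conv) / denom
    tail = times >= 0.5 * horizon
    mask = tail & (B > 0)
    if mask.sum() < 10:
        warnings.warn("renewal horizon too short for the transient to decay")
        return math.nan, math.nan, (times, B)
    t_fit, logb = times[mask], np.log(B[mask])
    slope, intercept = np.polyfit(t_fit, logb, 1)
    osc = float(np.std(logb - (slope * t_fit + intercept)))
    return float(slope - lam), osc, (times, B)
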