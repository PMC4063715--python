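"""Hamilton-Jacobi-Bellman solvers and policy extraction.

The value function V is the controlled supremum of the discounted ERS.  Its
control Hamiltonian at a state x is

    H(u) = g(x,u) Vx + 1/2 sigma^2(x,u) Vxx - (lam + mu(x,u)) V + b(x),

(the fertility source b is present for iteroparous models; semelparous
models carry fertility only through the Dirichlet boundary value V(x*) = q).
Semelparous (age-free) problems solve the stationary HJB as a Dirichlet
boundary-value problem by Howard policy iteration; iteroparous problems with
a finite maximum lifespan solve the age-backward HJB from the terminal
condition V(omega, .) = 0.  The outer fitness loop closes the unification:
the fitness of the optimally controlled life history is the lam at which the
optimized objective V_lam(0, x0) equals one.

Scheme notes: implicit upwind finite differences (monotone, consistent,
stable -> convergence to the viscosity solution is the standard argument; no
smoothness of V is assumed).  Multiplicative models are discretized on a
log-uniform grid, where the pointwise Hamiltonian maximization in the
transformed derivatives coincides with the x-space one (chain rule).  The
degenerate lower boundary (x -> 0 for GBM) carries a vanishing operator, so
truncation with a homogeneous Dirichlet value is used and tested for
insensitivity.  Ties in the argmax break toward the smaller control.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Optional

import numpy as np
from scipy.linalg import solve_banded
from scipy.optimize import brentq

from .demography import solve_euler_lotka
from .life_history import ControlPolicy, LifeHistory
from .pde_engine import Grid1D

__all__ = [
    "HjbConfig",
    "ValueGrid",
    "control_hamiltonian",
    "minimize_hamiltonian_pointwise",
    "solve_stationary_hjb",
    "solve_finite_horizon_hjb",
    "optimal_fitness",
    "brute_force_constant_policy",
]


@dataclass(frozen=True)
class HjbConfig:
    """Solver settings.

    ``control_mode="analytic"`` exploits the (clamped) closed-form extremum
    of a Hamiltonian quadratic in the scalar control; ``"grid"`` scans ``m``
    equispaced control points.  Policy updates are damped to avoid cycling.
    """

    scheme: Literal["policy_iteration"] = "policy_iteration"
    control_mode: Literal["analytic", "grid"] = "analytic"
    m: int = 101
    tol_value: float = 1e-9
    tol_policy: float = 1e-9
    damping: float = 0.5
    max_iter: int = 200


@dataclass
class ValueGrid:
    """Value function on a state (x age) grid with its extracted policy."""

    grid: Grid1D
    V: np.ndarray            # (M,) stationary or (n_ages, M) finite horizon
    policy: np.ndarray       # same shape
    lam: float
    ages: np.ndarray | None = None
    residuals: list = field(default_factory=list)
    iterations: int = 0

    def value_at(self, x: float, age: float | None = None) -> float:
        xs = self.grid.coords
        xq = math.log(x) if self.grid.spacing == "log-uniform" else x
        if self.V.ndim == 1:
            return float(np.interp(xq, xs, self.V))
        k = int(np.argmin(np.abs(self.ages - (age or 0.0))))
        return float(np.interp(xq, xs, self.V[k]))

    def as_policy(self, age: float | None = None) -> ControlPolicy:
        tab = self.policy if self.policy.ndim == 1 else self.policy[0]
        return ControlPolicy("grid", (self.grid.nodes, tab))


def control_hamiltonian(
    lh: LifeHistory, x: float, Vx: float, Vxx: float, V: float, lam: float, u, a: float = 0.0
) -> float:
    """H(u) = g Vx + 1/2 sigma^2 Vxx - (lam + mu) V + b  (natural x scale)."""
    xv = np.array([float(x)])
    uv = np.atleast_1d(np.asarray(u, float))
    g = float(np.ravel(lh.sde.drift(xv, uv, a))[0])
    sig = np.ravel(lh.sde.diffusion(xv, uv, a))
    var = float(np.dot(sig, sig))
    mu = float(np.ravel(lh.mortality.rate(xv, uv, a))[0])
    b = 0.0 if lh.is_semelparous else lh.fertility(xv, a)
    return g * Vx + 0.5 * var * Vxx - (lam + mu) * V + b


def _maximize_quadratic(hfun: Callable[[float], float], lo: float, hi: float,
                        mode: str, m: int) -> tuple[float, float]:
    """Argmax of a scalar Hamiltonian over [lo, hi]; ties -> smaller u."""
    if mode == "grid":
        us = np.linspace(lo, hi, m)
        vals = np.array([hfun(u) for u in us])
        j = int(np.argmax(vals))  # argmax returns the first (smallest u) tie
        return float(us[j]), float(vals[j])
    mid = 0.5 * (lo + hi)
    h_lo, h_mid, h_hi = hfun(lo), hfun(mid), hfun(hi)
    # exact quadratic through the three points: curvature and slope at mid
    a2 = 2.0 * (h_lo - 2.0 * h_mid + h_hi) / (hi - lo) ** 2
    a1 = (h_hi - h_lo) / (hi - lo)
    candidates = [(lo, h_lo), (hi, h_hi)]
    if a2 < 0.0:
        u_v = min(hi, max(lo, mid - a1 / (2.0 * a2)))
        candidates.append((u_v, hfun(u_v)))
    # max value; strict comparison over u-ascending candidates -> smaller-u tie
    candidates.sort(key=lambda t: t[0])
    best_u, best_h = candidates[0]
    for u_c, h_c in candidates[1:]:
        if h_c > best_h:
            best_u, best_h = u_c, h_c
    return best_u, best_h


def minimize_hamiltonian_pointwise(
    lh: LifeHistory,
    x: float,
    Vx: float,
    Vxx: float,
    V: float,
    lam: float,
    cfg: HjbConfig = HjbConfig(),
    a: float = 0.0,
) -> tuple[float, float]:
    """Pointwise optimal control: the u achieving the Hamiltonian extremum.

    With the sign convention used here the objective phi is *maximized*, so
    the extremum is a supremum.  Analytic mode fits the exact quadratic in u
    through three evaluations and clamps its vertex into the control box,
    falling back to the endpoints when the quadratic is not concave; grid
    mode scans ``m`` control points.  (The name keeps the control-theory
    phrasing: minimizing the adjoint Hamiltonian is the same extremum.)
    """
    lo = float(lh.sde.control_lower[0])
    hi = float(lh.sde.control_upper[0])
    if hi == lo:
        return lo, control_hamiltonian(lh, x, Vx, Vxx, V, lam, lo, a)
    hfun = lambda u: control_hamiltonian(lh, x, Vx, Vxx, V, lam, u, a)
    return _maximize_quadratic(hfun, lo, hi, cfg.control_mode, cfg.m)


def _transformed_coeffs(lh: LifeHistory, grid: Grid1D, u: np.ndarray, a: float):
    """nu, D, mu, b per node for the working coordinate, given controls u."""
    x = grid.nodes
    uv = np.clip(u[:, None], lh.sde.control_lower, lh.sde.control_upper)
    xs = x[:, None]
    g = np.asarray(lh.sde.drift(xs, uv, a), float).reshape(len(x))
    sig = np.asarray(lh.sde.diffusion(xs, uv, a), float).reshape(len(x), -1)
    var = np.einsum("ij,ij->i", sig, sig)
    mu = np.broadcast_to(np.asarray(lh.mortality.rate(xs, uv, a), float), (len(x),))
    if grid.spacing == "log-uniform":
        nu = g / x - 0.5 * var / x ** 2
        D = 0.5 * var / x ** 2
    else:
        nu = g
        D = 0.5 * var
    if lh.is_semelparous:
        b = np.zeros(len(x))
    else:
        b = np.broadcast_to(
            np.squeeze(np.asarray(lh.fertility.rate(xs, a), float)), (len(x),)
        )
    return nu, D, mu, b


def _update_policy(
    lh: LifeHistory, grid: Grid1D, V: np.ndarray, lam: float, cfg: HjbConfig,
    a: float = 0.0,
) -> np.ndarray:
    """Pointwise Hamiltonian maximization from discrete derivatives of V."""
    xs = grid.coords
    h = grid.h
    Vx = np.gradient(V, h)
    Vxx = np.zeros_like(V)
    Vxx[1:-1] = (V[2:] - 2.0 * V[1:-1] + V[:-2]) / h ** 2
    Vxx[0], Vxx[-1] = Vxx[1], Vxx[-2]
    lo = float(lh.sde.control_lower[0])
    hi = float(lh.sde.control_upper[0])
    if hi == lo:
        return np.full(len(xs), lo)

    # vectorized three-point quadratic fit over nodes (transformed variables)
    def ham(u_scalar):
        u = np.full(len(xs), u_scalar)
        nu, D, mu, b = _transformed_coeffs(lh, grid, u, a)
        return nu * Vx + D * Vxx - (lam + mu) * V + b

    def ham_arr(u_nodes):
        nu, D, mu, b = _transformed_coeffs(lh, grid, u_nodes, a)
        return nu * Vx + D * Vxx - (lam + mu) * V + b

    M = len(xs)
    if cfg.control_mode == "grid":
        us = np.linspace(lo, hi, cfg.m)
        vals = np.stack([ham(u) for u in us])  # (m, M)
        return us[np.argmax(vals, axis=0)]  # first (smallest u) tie wins
    mid = 0.5 * (lo + hi)
    h_lo, h_mid, h_hi = ham(lo), ham(mid), ham(hi)
    a2 = 2.0 * (h_lo - 2.0 * h_mid + h_hi) / (hi - lo) ** 2
    a1 = (h_hi - h_lo) / (hi - lo)  # slope at mid of the exact quadratic
    with np.errstate(divide="ignore", invalid="ignore"):
        u_vertex = np.where(a2 < 0.0, mid - a1 / (2.0 * a2), lo)
    u_vertex = np.clip(u_vertex, lo, hi)
    h_vertex = ham_arr(u_vertex)
    # candidates in ascending u; strict improvement keeps the smaller u on ties
    best_u = np.full(M, lo)
    best_h = h_lo.copy()
    for u_c, h_c in ((u_vertex, h_vertex), (np.full(M, hi), h_hi)):
        improve = h_c > best_h
        best_u = np.where(improve, u_c, best_u)
        best_h = np.where(improve, h_c, best_h)
    return best_u


def _linear_solve(
    lh: LifeHistory, grid: Grid1D, u: np.ndarray, lam: float, a: float,
    dirichlet: tuple[float, float], source_scale: float = 1.0,
    implicit_shift: float = 0.0, rhs_extra: np.ndarray | None = None,
    upper_bc: str = "dirichlet",
) -> np.ndarray:
    """Solve (shift*I - L_u) V = shift*rhs_extra + b under the boundary rows.

    With ``implicit_shift = 0`` this is the stationary equation L_u V + b = 0;
    with ``implicit_shift = 1/da`` it is one implicit backward age step.
    ``upper_bc="advective"`` replaces the upper Dirichlet row by the
    degenerate (diffusion-free, upwind) equation — the right closure for an
    artificial truncation of a growing domain when the drift points outward.
    """
    xs = grid.coords
    h = grid.h
    M = len(xs)
    nu, D, mu, b = _transformed_coeffs(lh, grid, u, a)
    lower = np.zeros(M)
    diag = np.zeros(M)
    upper = np.zeros(M)
    # upwind advection on V (non-conservative), central diffusion
    pos = nu >= 0
    diag += -2.0 * D / h ** 2 - (lam + mu)
    upper += D / h ** 2 + np.where(pos, nu / h, 0.0)
    lower += D / h ** 2 + np.where(~pos, -nu / h, 0.0)
    diag += np.where(pos, -nu / h, nu / h)

    rhs = -(source_scale * b).astype(float)
    if implicit_shift:
        diag -= implicit_shift
        rhs = rhs - implicit_shift * rhs_extra
    # assemble banded (-A) so system is A V = -rhs ... sign bookkeeping:
    # we solve  (L - shift) V = -(b + shift * prev)  i.e.  M V = rhs with
    # M rows from lower/diag/upper.
    ab = np.zeros((3, M))
    ab[0, 1:] = upper[:-1]
    ab[1, :] = diag
    ab[2, :-1] = lower[1:]
    ab[1, 0] = 1.0
    ab[0, 1] = 0.0
    rhs[0] = dirichlet[0]
    if upper_bc == "onesided" and nu[-1] >= 0.0:
        # full PDE row at the truncation boundary with backward (one-sided)
        # differences: transparent for outward drift, fully implicit
        ab2 = np.zeros((4, M))
        ab2[:3, :] = ab
        ab2[1, -1] = nu[-1] / h + D[-1] / h ** 2 - (lam + mu[-1]) - implicit_shift
        ab2[2, -2] = -nu[-1] / h - 2.0 * D[-1] / h ** 2
        ab2[3, -3] = D[-1] / h ** 2
        return solve_banded((2, 1), ab2, rhs)
    if upper_bc == "advective" and nu[-1] >= 0.0:
        ab[1, -1] = nu[-1] / h - (lam + mu[-1]) - implicit_shift
        ab[2, -2] = -nu[-1] / h
        # rhs already holds -(b + shift*prev) at the last node
    else:
        ab[1, -1] = 1.0
        ab[2, -2] = 0.0
        rhs[-1] = dirichlet[1]
    return solve_banded((1, 1), ab, rhs)


def solve_stationary_hjb(
    lh: LifeHistory,
    lam: float,
    grid: Grid1D,
    cfg: HjbConfig = HjbConfig(),
    policy_init: np.ndarray | None = None,
) -> ValueGrid:
    """Howard policy iteration for the stationary (age-free) HJB equation.

    Applies to semelparous life histories (Dirichlet value q(x*) at the
    mature boundary) and to iteroparous ones with unbounded lifespan.  The
    iteration alternates an implicit finite-difference linear solve for V
    under the current policy with a pointwise Hamiltonian maximization, with
    damped policy updates, until both the policy and the value are
    stationary.
    """
    M = len(grid.nodes)
    if lh.is_semelparous:
        _, _, thr = lh.mature_threshold()
        q = lh.fertility(np.array([thr]), 0.0)
        bc = (0.0, q)
    else:
        if math.isfinite(lh.fertility.max_lifespan):
            raise ValueError(
                "stationary solver needs semelparous or unbounded-lifespan models"
            )
        bc = (0.0, 0.0)
    lo = float(lh.sde.control_lower[0])
    u = (np.full(M, 0.5 * (lo + float(lh.sde.control_upper[0])))
         if policy_init is None else np.asarray(policy_init, float).copy())
    V = np.zeros(M)
    residuals = []
    ub = "dirichlet" if lh.is_semelparous else "onesided"
    for it in range(cfg.max_iter):
        V_new = _linear_solve(lh, grid, u, lam, 0.0, bc, upper_bc=ub, rhs_extra=V)
        u_cand = _update_policy(lh, grid, V_new, lam, cfg)
        du = float(np.max(np.abs(u_cand - u)))
        dv = float(np.max(np.abs(V_new - V)))
        residuals.append((dv, du))
        u = u + cfg.damping * (u_cand - u)
        V = V_new
        if du < cfg.tol_policy and dv < cfg.tol_value:
            break
    else:
        if residuals[-1][0] > 100 * cfg.tol_value:
            raise RuntimeError(
                f"policy iteration did not converge: residuals {residuals[-3:]}"
            )
        warnings.warn("policy iteration stopped at max_iter with small residual")
    return ValueGrid(grid, V, u, lam, residuals=residuals, iterations=it + 1)


def solve_finite_horizon_hjb(
    lh: LifeHistory,
    lam: float,
    grid: Grid1D,
    ages: np.ndarray,
    cfg: HjbConfig = HjbConfig(),
    terminal: np.ndarray | None = None,
) -> ValueGrid:
    """Backward-in-age implicit sweep for the finite-lifespan HJB equation.

    From the terminal condition V(omega, .) = 0 (or ``terminal``), each step
    extracts the policy from the pointwise Hamiltonian maximum on the current
    value surface (semi-Lagrangian in the control) and then takes one
    implicit linear step.  Returns V(a, x) and policy(a, x).
    """
    ages = np.asarray(ages, float)
    M = len(grid.nodes)
    n_a = len(ages)
    V = np.zeros((n_a, M))
    U = np.zeros((n_a, M))
    V[-1] = 0.0 if terminal is None else np.asarray(terminal, float)
    U[-1] = float(lh.sde.control_lower[0])
    for k in range(n_a - 2, -1, -1):
        da = ages[k + 1] - ages[k]
        a = ages[k]
        u = _update_policy(lh, grid, V[k + 1], lam, cfg, a=a)
        V[k] = _linear_solve(
            lh, grid, u, lam, a, (0.0, 0.0),
            implicit_shift=1.0 / da, rhs_extra=V[k + 1],
            upper_bc="onesided",
        )
        U[k] = u
    return ValueGrid(grid, V, U, lam, ages=ages)


def optimal_fitness(
    lh: LifeHistory,
    grid: Grid1D,
    cfg: HjbConfig = HjbConfig(),
    ages: np.ndarray | None = None,
    lam_bracket: tuple[float, float] = (-1.0, 1.0),
    tol: float = 1e-9,
    max_doublings: int = 40,
) -> tuple[float, ValueGrid]:
    """Fitness of the optimally controlled life history.

    Outer bracketed root-finding on lam for V_lam(0, x0) = 1 — the optimized
    objective equals one exactly at the Euler-Lotka root — re-solving the
    HJB at each lam with warm-started policies.
    """
    x0 = float(lh.sde.x0[0])
    warm: dict = {"policy": None}

    def solve(lam: float) -> ValueGrid:
        if lh.is_semelparous or not math.isfinite(lh.fertility.max_lifespan):
            vg = solve_stationary_hjb(lh, lam, grid, cfg, policy_init=warm["policy"])
            warm["policy"] = vg.policy
        else:
            if ages is None:
                raise ValueError("finite-lifespan model needs an age grid")
            vg = solve_finite_horizon_hjb(lh, lam, grid, ages, cfg)
        return vg

    def h(lam: float) -> float:
        # below the abscissa of convergence the discounted problem diverges;
        # report +inf so the bracket logic reads it as "objective above 1"
        try:
            return solve(lam).value_at(x0, 0.0) - 1.0
        except (RuntimeError, FloatingPointError):
            return math.inf

    lo, hi = lam_bracket
    k = 0
    while h(hi) >= 0 and k < max_doublings:
        hi = hi * 2.0 if hi > 0 else 1.0
        k += 1
    k = 0
    while h(lo) <= 0 and k < max_doublings:
        lo = lo * 2.0 if lo < 0 else -1.0
        k += 1
    if h(lo) <= 0:
        raise RuntimeError("extinction range: V_lam(x0) < 1 for all probed lam")
    while math.isinf(h(lo)):
        lo = 0.5 * (lo + hi)
    lam_star = float(brentq(h, lo, hi, xtol=tol))
    return lam_star, solve(lam_star)


def brute_force_constant_policy(
    lh: LifeHistory,
    u_values,
    fitness_of_u: Callable[[float], float],
):
    """Table of (u, lam(u)) over constant policies, with its argmax.

    ``fitness_of_u`` is the demographic route (closed form, PDE, or MC based)
    that maps a constant control to its Euler-Lotka fitness; this function is
    deliberately a plain sweep so it can serve as the independent oracle for
    the HJB optimality claims.
    """
    import pandas as pd

    u_values = np.asarray(u_values, float)
    lams = np.array([fitness_of_u(float(u)) for u in u_values])
    j = int(np.argmax(lams))
    table = pd.DataFrame({"u": u_values, "lam": lams})
    return table, float(u_values[j]), float(lams[j])
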