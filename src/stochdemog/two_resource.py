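"""Two-resource utilization model: closed forms for both breeding systems.

An individual of size ``x`` splits its foraging effort between a high-risk /
high-return resource R1 (drift ``m1``, noise intensity ``s1``) and a low-risk /
low-return resource R2 (``m2 < m1``, ``s2 < s1``).  The two resources
fluctuate independently, so under utilization frequency ``u`` (the weight on
R1) size follows the geometric Brownian motion

    dx = g(u) x da + u s1 x dW1 + (1-u) s2 x dW2,
    g(u) = u m1 + (1-u) m2,      sigma2(u) = u^2 s1^2 + (1-u)^2 s2^2,

with a control-free baseline mortality ``mu0``.  This is the classic
portfolio-selection diffusion, repurposed: the "utility" being maximized is
the Laplace transform of the expectation of reproductive success, so the
optimal mix maximizes the population growth rate (fitness).

Every closed form is defined exactly once in this module; structural unit
tests verify each against its defining equation (the characteristic quadratic,
the stationary HJB equation, the backward iteroparous PDE), so the formulas
are checked symbolically rather than merely numerically.

Key scalar results (semelparous: mature at size ``xm``, burst fertility ``q``):

* characteristic exponent: ``theta(lam)`` = positive root of
  ``1/2 s^2 th^2 + (g - 1/2 s^2) th - (lam + mu0) = 0``;
* objective: ``phi(lam) = q (x0/xm)^theta(lam)`` (GBM first-passage Laplace
  transform with killing);
* convexity index: ``n = ln q / ln(xm/x0)``;
* fitness at index n: ``lam = g n + 1/2 s^2 n (n-1) - mu0``;
* optimal mix (n < 1): ``u* = (s2^2 + (m1-m2)/(1-n)) / (s1^2 + s2^2)``
  clamped to [0, 1]; for n >= 1 stochasticity helps, u* = 1;
* generalist window: ``0 < n < 1 - (m1-m2)/s1^2``.

Iteroparous species with allometric fertility ``b(x) = b0 x^alpha`` and
maximum lifespan ``omega`` mirror the same algebra with ``alpha`` in the role
of ``n``; their value function is
``V(a,x) = b0 x^alpha (1 - e^{-(lam-K)(omega-a)}) / (lam - K)`` with ``K`` the
semelparous-fitness function evaluated at index ``alpha``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .life_history import (
    ControlledSDE,
    ControlPolicy,
    Fertility,
    InvalidModelError,
    LifeHistory,
    Mortality,
    StateSpace,
)

__all__ = [
    "TwoResourceParams",
    "MixResult",
    "ModelRangeError",
    "effective_drift",
    "effective_variance",
    "theta_root",
    "single_resource_objective",
    "convexity_index",
    "single_resource_fitness",
    "fitness_at_index",
    "semelparous_optimal_mix",
    "iteroparous_optimal_mix",
    "iteroparous_value",
    "iteroparous_objective",
    "iteroparous_demography",
    "mature_age_density",
    "stochasticity_sensitivity_scan",
    "optimal_mature_size",
    "suggested_grid",
    "build_sde",
    "build_life_history",
]


class ModelRangeError(ValueError):
    """Parameters outside the range where the closed forms are real/viable."""


@dataclass(frozen=True)
class TwoResourceParams:
    """Parameters of the two-resource utilization model.

    ``m1 > m2`` and ``s1 > s2 >= 0`` encode "high risk, high return" versus
    "low risk, low return".  Semelparous runs use ``(xm, q)``; iteroparous
    runs use ``(b0, alpha, omega)``.
    """

    m1: float
    m2: float
    s1: float
    s2: float
    mu0: float
    x0: float = 1.0
    xm: float = 5.0
    q: float = 2.0
    b0: float = 0.5
    alpha: float = 0.4
    omega: float = 20.0

    def __post_init__(self) -> None:
        if not (self.m1 > self.m2):
            raise InvalidModelError("need m1 > m2 (R1 is high return)")
        if not (self.s1 > self.s2 >= 0.0):
            raise InvalidModelError("need s1 > s2 >= 0 (R1 is high risk)")
        if not (self.xm > self.x0 > 0.0):
            raise InvalidModelError("need xm > x0 > 0")
        if self.q < 0 or self.b0 < 0 or self.mu0 < 0:
            raise InvalidModelError("rates must be nonnegative")
        if not (0.0 < self.alpha < 1.0):
            raise InvalidModelError("allometric exponent must lie in (0, 1)")


@dataclass(frozen=True)
class MixResult:
    """Optimal resource mix for one breeding system.

    ``u_star`` is the weight on the risky resource R1 (``r2_weight = 1 -
    u_star`` is also reported to stay convention-proof), ``exponent`` the
    power of the value function, ``window`` the (n_lo, n_hi) generalist range.
    """

    u_star: float
    lambda_star: float
    exponent: float
    regime: Literal["R1-specialist", "generalist", "R2-specialist"]
    window: tuple[float, float]

    @property
    def r2_weight(self) -> float:
        return 1.0 - self.u_star


# ----------------------------------------------------------------------
# effective GBM coefficients of a mix
# ----------------------------------------------------------------------

def effective_drift(p: TwoResourceParams, u) -> float | np.ndarray:
    """g(u) = u m1 + (1-u) m2."""
    return u * p.m1 + (1.0 - u) * p.m2


def effective_variance(p: TwoResourceParams, u) -> float | np.ndarray:
    """sigma^2(u) = u^2 s1^2 + (1-u)^2 s2^2 (independent noises add in variance)."""
    return (u * p.s1) ** 2 + ((1.0 - u) * p.s2) ** 2


# ----------------------------------------------------------------------
# semelparous closed forms
# ----------------------------------------------------------------------

def theta_root(g: float, s: float, lam: float, mu0: float) -> float:
    """Positive root of ``1/2 s^2 th^2 + (g - 1/2 s^2) th - (lam + mu0) = 0``.

    This is the exponent of the GBM first-passage Laplace transform:
    ``E[e^{-(lam+mu0) T}] = (x0/xm)^theta``.  Returns ``-inf`` when the
    discriminant is negative (the transform diverges: lam below the abscissa
    of convergence).
    """
    a = lam + mu0
    if s == 0.0:
        if g <= 0.0:
            raise ModelRangeError("deterministic growth needs positive drift")
        return a / g
    nu = g - 0.5 * s * s
    disc = nu * nu + 2.0 * s * s * a
    if disc < 0.0:
        return -math.inf
    return (-nu + math.sqrt(disc)) / (s * s)


def single_resource_objective(
    g: float, s: float, mu0: float, x0: float, xm: float, q: float, lam: float
) -> float:
    """Closed-form semelparous objective ``phi(lam) = q (x0/xm)^theta(lam)``.

    The Laplace transform of the ERS for first passage of GBM from ``x0`` to
    ``xm`` under killing rate ``mu0``; ``+inf`` signals divergence.
    """
    th = theta_root(g, s, lam, mu0)
    if th == -math.inf:
        return math.inf
    return q * (x0 / xm) ** th


def convexity_index(p: TwoResourceParams) -> float:
    """Convexity index ``n = ln q / ln(xm / x0)``.

    Grows with the burst fertility ``q`` and shrinks with the size ratio
    ``xm/x0``; it measures the convexity of the objective in log-size and
    hence the species' risk appetite.
    """
    if p.xm == p.x0:
        raise ModelRangeError("xm = x0 makes the index degenerate")
    return math.log(p.q) / math.log(p.xm / p.x0)


def fitness_at_index(g: float, s2_eff: float, n: float, mu0: float) -> float:
    """Semelparous fitness ``lam = g n + 1/2 sigma^2 n (n - 1) - mu0``.

    The Euler-Lotka root of the closed-form objective: ``phi(lam)=1`` forces
    ``theta(lam) = n``, and the characteristic quadratic then yields ``lam``.
    ``s2_eff`` is the variance rate sigma^2 (not the intensity).
    """
    return g * n + 0.5 * s2_eff * n * (n - 1.0) - mu0


def single_resource_fitness(g: float, s: float, p: TwoResourceParams) -> float:
    """Closed-form fitness of a single-resource semelparous strategy."""
    n = convexity_index(p)
    if n <= 0.0:
        raise ModelRangeError("q <= 1 gives R0 < 1: extinction range")
    return fitness_at_index(g, s * s, n, p.mu0)


def _u_star_of_index(p: TwoResourceParams, idx: float) -> float:
    """Optimal weight on R1 for value-function exponent ``idx``, clamped.

    Interior extremum of the quadratic ``lam(u) = g(u) idx + 1/2 sigma^2(u)
    idx (idx-1) - mu0``; for idx >= 1 the quadratic is convex in u and
    stochasticity raises fitness, so the optimum sits at u = 1.
    """
    if idx >= 1.0:
        return 1.0
    u = (p.s2 ** 2 + (p.m1 - p.m2) / (1.0 - idx)) / (p.s1 ** 2 + p.s2 ** 2)
    return min(1.0, max(0.0, u))


def _generalist_window(p: TwoResourceParams) -> tuple[float, float]:
    """Index range (n_lo, n_hi) where the optimal mix is interior.

    ``n_hi = 1 - (m1 - m2) / s1^2`` (the clamping event ``u* = 1``); below
    ``n_lo = 0`` the species is non-viable (q < 1 implies R0 < 1), so the
    window is bounded below by viability rather than by an R2-specialist
    regime — the R2-specialist is never selected when m1 > m2.
    """
    n_hi = 1.0 - (p.m1 - p.m2) / p.s1 ** 2
    return (0.0, max(0.0, n_hi))


def semelparous_optimal_mix(p: TwoResourceParams) -> MixResult:
    """Optimal constant resource mix and fitness of a semelparous species.

    Solves the stationary HJB problem in closed form: the value function is
    the power law ``V(x) = q (x/xm)^gamma`` whose exponent at the fitness
    root equals the convexity index ``n``; the optimal utilization is
    constant over the lifetime.
    """
    n = convexity_index(p)
    if n <= 0.0:
        raise ModelRangeError("q <= 1 gives R0 < 1: extinction range")
    u = _u_star_of_index(p, n)
    lam = fitness_at_index(
        effective_drift(p, u), effective_variance(p, u), n, p.mu0
    )
    window = _generalist_window(p)
    if u >= 1.0:
        regime = "R1-specialist"
    elif u <= 0.0:
        regime = "R2-specialist"
    else:
        regime = "generalist"
    return MixResult(u, lam, n, regime, window)


# ----------------------------------------------------------------------
# iteroparous closed forms
# ----------------------------------------------------------------------

def _itero_growth_rate(p: TwoResourceParams, u: float) -> float:
    """K = semelparous-fitness function evaluated at index alpha.

    The ERS of the allometric iteroparous model is the pure exponential
    ``F(a) = b0 x0^alpha e^{K a}`` on [0, omega]: the allometric moment of
    GBM grows at rate ``K + mu0`` and survivorship removes ``mu0``.
    """
    return fitness_at_index(
        effective_drift(p, u), effective_variance(p, u), p.alpha, p.mu0
    )


def iteroparous_value(
    p: TwoResourceParams, lam: float, a, x, u: float | None = None
):
    """Closed-form iteroparous value function.

    ``V(a, x) = b0 x^alpha (1 - e^{-(lam - K)(omega - a)}) / (lam - K)``,
    the unique (viscosity) solution of the backward HJB with terminal value
    ``V(omega, .) = 0``; at ``lam = K`` it degenerates to
    ``b0 x^alpha (omega - a)``.
    """
    if u is None:
        u = _u_star_of_index(p, p.alpha)
    K = _itero_growth_rate(p, u)
    a = np.asarray(a, float)
    x = np.asarray(x, float)
    z = lam - K
    horizon = p.omega - a
    if abs(z) < 1e-12:
        shape = horizon
    else:
        shape = (1.0 - np.exp(-z * horizon)) / z
    return p.b0 * x ** p.alpha * shape


def iteroparous_objective(
    p: TwoResourceParams, lam: float, u: float | None = None
) -> float:
    """phi(lam) = V(0, x0): Laplace transform of the iteroparous ERS."""
    return float(iteroparous_value(p, lam, 0.0, p.x0, u=u))


def iteroparous_optimal_mix(p: TwoResourceParams) -> MixResult:
    """Optimal mix of an iteroparous species with allometric fertility.

    The utilization mirrors the semelparous formula with ``alpha`` in the
    role of the convexity index (identical risk appetite at ``alpha = n``);
    the exact fitness solves the transcendental Euler-Lotka equation
    ``phi(lam) = 1`` numerically.  The closed-form comparison root
    ``K + b0 x0^alpha`` (infinite-lifespan limit) is exposed via
    :func:`iteroparous_fitness_bound`.
    """
    u = _u_star_of_index(p, p.alpha)
    from .demography import solve_euler_lotka  # local import: layering

    sol = solve_euler_lotka(lambda lam: iteroparous_objective(p, lam, u=u))
    window = _generalist_window(p)
    if u >= 1.0:
        regime = "R1-specialist"
    elif u <= 0.0:
        regime = "R2-specialist"
    else:
        regime = "generalist"
    return MixResult(u, float(sol.fitness), p.alpha, regime, window)


def iteroparous_fitness_bound(p: TwoResourceParams, u: float | None = None) -> float:
    """Upper bound ``K + b0 x0^alpha`` on the iteroparous fitness.

    The infinite-lifespan objective ``b0 x0^alpha / (lam - K)`` dominates the
    finite-omega one, so (basic monotonicity theorem) its root bounds the
    fitness from above; the bound tightens as the initial-state contribution
    ``b0 x0^alpha`` becomes small.
    """
    if u is None:
        u = _u_star_of_index(p, p.alpha)
    return _itero_growth_rate(p, u) + p.b0 * p.x0 ** p.alpha


def iteroparous_demography(p: TwoResourceParams, mix: MixResult):
    """Closed-form R0, breeding-age density, and minimum viable lifespan.

    Returns ``(R0, (ages, psi), omega_min, shape)`` where ``psi(a) \\propto
    e^{(K - lam*) a}`` on [0, omega] (normalized), ``omega_min`` is the
    smallest lifespan with R0 >= 1 (``inf`` if never viable), and ``shape``
    classifies the density: "increasing" (J-shaped, skewed to older ages),
    "uniform", or "decreasing".
    """
    u = mix.u_star
    K = _itero_growth_rate(p, u)
    c = p.b0 * p.x0 ** p.alpha

    def r0_of_omega(om: float) -> float:
        if abs(K) < 1e-12:
            return c * om
        return c * (math.exp(K * om) - 1.0) / K

    R0 = r0_of_omega(p.omega)

    r = K - mix.lambda_star
    ages = np.linspace(0.0, p.omega, 801)
    if abs(r) < 1e-10:
        psi = np.full_like(ages, 1.0 / p.omega)
        shape = "uniform"
    else:
        psi = r * np.exp(r * ages) / (math.exp(r * p.omega) - 1.0)
        shape = "increasing" if r > 0 else "decreasing"

    # minimum viable lifespan by monotone bisection on R0(omega) = 1
    r0_sup = math.inf if K >= 0 else c / (-K)
    if r0_sup < 1.0:
        omega_min = math.inf
    else:
        lo, hi = 1e-8, 1.0
        while r0_of_omega(hi) < 1.0:
            hi *= 2.0
        from scipy.optimize import brentq

        omega_min = float(brentq(lambda om: r0_of_omega(om) - 1.0, lo, hi))
    return float(R0), (ages, psi), omega_min, shape


# ----------------------------------------------------------------------
# mature-age density (semelparous first-passage density)
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class MatureAgeDensity:
    """First-passage-time density of maturity, with killing by mortality.

    ``pdf`` is normalized over paths that mature *and* survive to maturity;
    ``unnormalized(t)`` = (inverse-Gaussian hitting density) x e^{-mu0 t},
    whose integral equals R0/q.
    """

    nu: float
    s2_eff: float
    distance: float
    mu0: float
    norm: float
    _grid_t: np.ndarray
    _grid_cdf: np.ndarray

    def unnormalized(self, t):
        t = np.asarray(t, float)
        L, nu, s2 = self.distance, self.nu, self.s2_eff
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (
                L / np.sqrt(2.0 * math.pi * s2 * t ** 3)
                * np.exp(-((L - nu * t) ** 2) / (2.0 * s2 * t))
            )
        f = np.where(t > 0, f, 0.0)
        return f * np.exp(-self.mu0 * t)

    def pdf(self, t):
        return self.unnormalized(t) / self.norm

    def cdf(self, t):
        return np.interp(np.asarray(t, float), self._grid_t, self._grid_cdf)


def mature_age_density(p: TwoResourceParams, u: float) -> MatureAgeDensity:
    """Maturity-age density of the mixed GBM strategy ``u``.

    Log-size is Brownian motion with drift ``nu = g(u) - sigma^2(u)/2`` and
    variance rate ``sigma^2(u)``; the hitting density of the log-distance
    ``L = ln(xm/x0)`` is inverse-Gaussian.  Multiplying by the survivorship
    ``e^{-mu0 t}`` and renormalizing gives the observed mature-age density.
    """
    s2 = float(effective_variance(p, u))
    g = float(effective_drift(p, u))
    L = math.log(p.xm / p.x0)
    if s2 == 0.0:
        nu = g
        if nu <= 0.0:
            raise ModelRangeError("non-positive drift with s = 0: never matures")
        # point mass at L/nu; represent with a narrow surrogate for plotting
        t0 = L / nu
        grid = np.linspace(0.0, 2 * t0, 4001)
        cdf = (grid >= t0).astype(float)
        return MatureAgeDensity(nu, s2, L, p.mu0, math.exp(-p.mu0 * t0), grid, cdf)
    nu = g - 0.5 * s2
    obj = MatureAgeDensity(nu, s2, L, p.mu0, 1.0, np.zeros(2), np.zeros(2))
    # choose a horizon holding all but ~1e-12 of the killed mass
    t_hi = 10.0 * L / max(nu, 0.05 * math.sqrt(s2))
    while True:
        grid = np.linspace(0.0, t_hi, 20001)
        dens = obj.unnormalized(grid)
        if dens[-1] < 1e-14 * max(dens.max(), 1e-300):
            break
        t_hi *= 2.0
    cdf_raw = cumulative_trapezoid(dens, grid, initial=0.0)
    norm = float(cdf_raw[-1])
    if norm <= 0.0:
        raise ModelRangeError("degenerate maturity density")
    return MatureAgeDensity(nu, s2, L, p.mu0, norm, grid, cdf_raw / norm)


# ----------------------------------------------------------------------
# stochasticity sensitivity
# ----------------------------------------------------------------------

def stochasticity_sensitivity_scan(
    p: TwoResourceParams,
    n_values,
    s_base: float = 0.05,
    h: float = 0.005,
    tol: float = 1e-6,
):
    """Sign of d(lambda)/d(s) at small s across the convexity index n.

    For each ``n`` the fitness is recomputed from scratch as the numerical
    Euler-Lotka root of the closed-form first-passage objective (drift
    ``m1``), and the derivative in the noise intensity is a central
    difference at ``s = s_base``.  Returns ``(table, n_threshold)`` where
    the threshold is located by bisection on the derivative's sign.
    """
    from .demography import solve_euler_lotka

    def lam_of(n: float, s: float) -> float:
        q = (p.xm / p.x0) ** n
        sol = solve_euler_lotka(
            lambda lam: single_resource_objective(p.m1, s, p.mu0, p.x0, p.xm, q, lam)
        )
        return float(sol.fitness)

    def deriv(n: float) -> float:
        return (lam_of(n, s_base + h) - lam_of(n, s_base - h)) / (2.0 * h)

    n_values = np.asarray(n_values, float)
    table = [(float(n), deriv(float(n))) for n in n_values]

    negs = [n for n, d in table if d < 0]
    poss = [n for n, d in table if d > 0]
    if not negs or not poss:
        return table, math.nan
    lo, hi = max(negs), min(poss)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if deriv(mid) < 0:
            lo = mid
        else:
            hi = mid
    return table, 0.5 * (lo + hi)


# ----------------------------------------------------------------------
# model builders (bridge to the generic machinery)
# ----------------------------------------------------------------------

def optimal_mature_size(
    p: TwoResourceParams,
    q_of_x: Callable[[float], float],
    lam: float,
    u: float = 1.0,
    x_hi: float | None = None,
) -> tuple[float, float]:
    """Objective-maximizing mature size for a size-dependent burst fertility.

    Given a fertility-rate family ``q(x)`` with a unique interior optimum
    (e.g. ``q0 x e^{-x/xc}``: larger breeders produce more offspring up to a
    physiological cap), maximizes the first-passage objective
    ``q(xm) (x0/xm)^theta(lam)`` over the mature size at fixed discount
    ``lam`` and mix ``u``.  The first-order condition is
    ``q'(x*)/q(x*) = theta/x*``.  Returns ``(xm*, phi*)``.
    """
    from scipy.optimize import minimize_scalar

    g = float(effective_drift(p, u))
    s = math.sqrt(float(effective_variance(p, u)))
    lo = p.x0 * 1.001
    hi = x_hi if x_hi is not None else p.x0 * 1e3

    def neg_phi(xm: float) -> float:
        return -single_resource_objective(g, s, p.mu0, p.x0, xm, q_of_x(xm), lam)

    res = minimize_scalar(neg_phi, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    if not res.success or not math.isfinite(res.fun):
        raise ModelRangeError("no interior optimal mature size in the bounds")
    return float(res.x), float(-res.fun)


def suggested_grid(
    p: TwoResourceParams,
    breeding: Literal["semelparous", "iteroparous"] = "semelparous",
    n_nodes: int = 800,
    span_low: float = 8.0,
):
    """Log-uniform state grid sized for the PDE/HJB solvers.

    Semelparous problems end at the mature size ``xm``.  Iteroparous value
    functions feel sizes reachable within the lifespan, so the top is placed
    ``m1 * omega + 2 s1 sqrt(omega)`` log-units above ``xm`` (a conservative
    bound on drift plus spread), keeping the artificial truncation outside
    the region that influences the solution.
    """
    from .pde_engine import Grid1D

    lo = p.x0 * math.exp(-span_low)
    if breeding == "semelparous":
        return Grid1D.regular(lo, p.xm, n_nodes, log=True)
    top = p.xm * math.exp(p.m1 * p.omega + 2.0 * p.s1 * math.sqrt(p.omega))
    return Grid1D.regular(lo, top, n_nodes, log=True)


def build_sde(p: TwoResourceParams, u) -> ControlledSDE:
    """Controlled SDE of the two-resource model.

    ``u`` may be a number (constant policy folded in) or ``None`` to leave
    the control free in [0, 1].  Two independent noise channels with
    intensities ``u s1 x`` and ``(1-u) s2 x``.
    """

    def drift(x, uu, a):
        x = np.asarray(x, float)
        uu = np.asarray(uu, float)
        return effective_drift(p, uu) * x

    def diffusion(x, uu, a):
        x = np.asarray(x, float)
        uu = np.asarray(uu, float)
        ch1 = uu * p.s1 * x
        ch2 = (1.0 - uu) * p.s2 * x
        return np.stack([ch1, ch2], axis=-1)

    lo, hi = (u, u) if u is not None else (0.0, 1.0)
    return ControlledSDE(
        drift=drift,
        diffusion=diffusion,
        n_noise=2,
        control_lower=np.array([lo]),
        control_upper=np.array([hi]),
        x0=np.array([p.x0]),
        multiplicative=True,
    )


def build_life_history(
    p: TwoResourceParams,
    breeding: Literal["semelparous", "iteroparous"] = "semelparous",
    u: float | None = None,
) -> LifeHistory:
    """Assemble the full two-resource life history for either breeding system."""
    sde = build_sde(p, u)
    mort = Mortality(lambda x, uu, a: p.mu0)
    if breeding == "semelparous":
        space = StateSpace(
            dim=1,
            lower=(p.x0 * 1e-6,),
            upper=(p.xm,),
            upper_kind=("absorbing-maturity",),
        )
        fert = Fertility("semelparous", lambda x, a: p.q)
    else:
        space = StateSpace(dim=1, lower=(p.x0 * 1e-6,), upper=(p.xm * 1e3,))
        fert = Fertility(
            "iteroparous",
            lambda x, a: p.b0 * np.asarray(x, float)[..., 0] ** p.alpha,
            max_lifespan=p.omega,
        )
    return LifeHistory(sde=sde, mortality=mort, fertility=fert, space=space)
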