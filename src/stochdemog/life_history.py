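"""Domain types for controlled stochastic life histories.

A life history couples three ingredients defined on a common state space:

* a controlled Ito diffusion for the individual state (size, reserves, ...),
  ``dX = g(X, u, a) da + sigma(X, u, a) dW``;
* a mortality hazard ``mu(x, u, a) >= 0`` whose pathwise integral gives the
  survivorship ``S(a) = exp(-int_0^a mu dt)``;
* a fertility rule.  Two breeding systems are supported: *iteroparous*
  (a nonnegative rate ``b(x, a)`` paid continuously up to a maximum lifespan
  ``omega``) and *semelparous* (a single reproductive burst ``q(x*)`` at the
  first hitting time of the mature boundary, after which the individual dies).

The functions in this module evaluate survivorship, maturity, and fertility
along *discretized paths*; the Monte-Carlo and PDE layers build on them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

__all__ = [
    "StateSpace",
    "ControlledSDE",
    "Mortality",
    "Fertility",
    "LifeHistory",
    "ControlPolicy",
    "Path",
    "InvalidModelError",
    "UsageError",
    "NOT_REACHED",
    "survivorship_along_path",
    "maturity_time",
    "fertility_along_path",
]

BoundaryKind = Literal["absorbing-maturity", "reflecting", "truncation"]

#: Sentinel returned by :func:`maturity_time` when the path never matures.
NOT_REACHED = None


class InvalidModelError(ValueError):
    """A model callable returned an inadmissible value (negative rate, NaN...)."""


class UsageError(TypeError):
    """An operation was called on the wrong kind of life history."""


@dataclass(frozen=True)
class StateSpace:
    """Truncated state domain with per-face boundary semantics.

    Parameters
    ----------
    dim:
        Number of state coordinates N.
    lower, upper:
        Truncation bounds per coordinate (``upper`` may stand in for +inf).
    lower_kind, upper_kind:
        Boundary kind of each face; faces marked ``"absorbing-maturity"``
        constitute the mature boundary used by semelparous fertility.
    """

    dim: int
    lower: tuple[float, ...]
    upper: tuple[float, ...]
    lower_kind: tuple[BoundaryKind, ...] = ()
    upper_kind: tuple[BoundaryKind, ...] = ()

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise InvalidModelError("state dimension must be positive")
        lo, up = np.asarray(self.lower, float), np.asarray(self.upper, float)
        if lo.shape != (self.dim,) or up.shape != (self.dim,):
            raise InvalidModelError("bounds must have length dim")
        if not np.all(lo < up):
            raise InvalidModelError("lower bounds must lie strictly below upper")
        if not self.lower_kind:
            object.__setattr__(self, "lower_kind", ("truncation",) * self.dim)
        if not self.upper_kind:
            object.__setattr__(self, "upper_kind", ("truncation",) * self.dim)

    @property
    def mature_faces(self) -> list[tuple[int, str]]:
        """(coordinate, side) pairs of absorbing-maturity faces."""
        faces = []
        for i, k in enumerate(self.lower_kind):
            if k == "absorbing-maturity":
                faces.append((i, "lower"))
        for i, k in enumerate(self.upper_kind):
            if k == "absorbing-maturity":
                faces.append((i, "upper"))
        return faces


@dataclass
class ControlledSDE:
    """Controlled Ito SDE ``dX = g(x,u,a) da + sigma(x,u,a) dW``.

    ``drift`` maps ``(x, u, a) -> (N,)``; ``diffusion`` maps
    ``(x, u, a) -> (N, M)`` with M = ``n_noise`` independent Brownian
    channels.  The control set is a box in R^k.  ``multiplicative=True``
    declares GBM-like dynamics that the simulator and PDE engine may treat in
    log-state to preserve positivity (1-D only).
    """

    drift: Callable[[np.ndarray, np.ndarray, float], np.ndarray]
    diffusion: Callable[[np.ndarray, np.ndarray, float], np.ndarray]
    n_noise: int
    control_lower: np.ndarray
    control_upper: np.ndarray
    x0: np.ndarray
    multiplicative: bool = False

    def __post_init__(self) -> None:
        self.control_lower = np.atleast_1d(np.asarray(self.control_lower, float))
        self.control_upper = np.atleast_1d(np.asarray(self.control_upper, float))
        self.x0 = np.atleast_1d(np.asarray(self.x0, float))
        if self.n_noise < 1:
            raise InvalidModelError("n_noise must be positive")
        if np.any(self.control_lower > self.control_upper):
            raise InvalidModelError("empty control set")

    def clamp_control(self, u: np.ndarray) -> np.ndarray:
        return np.clip(u, self.control_lower, self.control_upper)


@dataclass
class Mortality:
    """Nonnegative hazard ``mu(x, u, a)``."""

    rate: Callable[[np.ndarray, np.ndarray, float], float]

    def __call__(self, x, u, a) -> float:
        m = float(self.rate(x, u, a))
        if not math.isfinite(m) or m < 0.0:
            raise InvalidModelError(f"mortality rate {m!r} at x={x}, a={a}")
        return m


@dataclass
class Fertility:
    """Breeding system: iteroparous rate ``b(x,a)`` or semelparous burst.

    For the semelparous kind ``rate(x, a)`` is the burst size ``q`` evaluated
    on the mature boundary.  ``max_lifespan`` (omega) applies to the
    iteroparous kind only; ``math.inf`` recovers the general survivorship
    (death by accident only).
    """

    kind: Literal["semelparous", "iteroparous"]
    rate: Callable[[np.ndarray, float], float]
    max_lifespan: float = math.inf

    def __call__(self, x, a) -> float:
        b = float(self.rate(x, a))
        if not math.isfinite(b) or b < 0.0:
            raise InvalidModelError(f"fertility {b!r} at x={x}, a={a}")
        return b


@dataclass
class LifeHistory:
    """Bundle (SDE, mortality, fertility) on one state space."""

    sde: ControlledSDE
    mortality: Mortality
    fertility: Fertility
    space: StateSpace

    def __post_init__(self) -> None:
        lo = np.asarray(self.space.lower)
        up = np.asarray(self.space.upper)
        if not np.all((self.sde.x0 > lo) & (self.sde.x0 < up)):
            raise InvalidModelError("x0 must lie strictly inside the domain")
        if self.fertility.kind == "semelparous" and not self.space.mature_faces:
            raise InvalidModelError(
                "semelparous fertility needs an absorbing-maturity face"
            )

    @property
    def is_semelparous(self) -> bool:
        return self.fertility.kind == "semelparous"

    def mature_threshold(self) -> tuple[int, str, float]:
        """(coordinate, side, threshold value) of the first mature face."""
        dim, side = self.space.mature_faces[0]
        thr = (self.space.lower if side == "lower" else self.space.upper)[dim]
        return dim, side, float(thr)


@dataclass
class ControlPolicy:
    """Mapping from (state, age) to a point of the control set.

    kind="constant"     -> ``value`` is the control point.
    kind="grid"         -> ``value`` is (nodes, table); linear interpolation in
                           the first state coordinate, optionally x age.
    kind="closed_form"  -> ``value`` is a callable ``(x, a) -> u``.

    Returned controls are always clamped into the SDE's control box by the
    consumer; stationary policies simply ignore ``a``.
    """

    kind: Literal["constant", "grid", "closed_form"]
    value: object

    def __call__(self, x: np.ndarray, a: float) -> np.ndarray:
        if self.kind == "constant":
            return np.atleast_1d(np.asarray(self.value, float))
        if self.kind == "closed_form":
            return np.atleast_1d(np.asarray(self.value(x, a), float))
        nodes, table = self.value
        return np.atleast_1d(np.interp(float(np.ravel(x)[0]), nodes, table))

    def control_at(self, x_values: np.ndarray, a: float) -> np.ndarray:
        """Vectorized evaluation over the first state coordinate."""
        x_values = np.asarray(x_values, float)
        if self.kind == "constant":
            return np.full(x_values.shape, float(np.ravel(self.value)[0]))
        if self.kind == "grid":
            nodes, table = self.value
            return np.interp(x_values, nodes, table)
        return np.array(
            [float(np.ravel(self.value(np.atleast_1d(xv), a))[0]) for xv in x_values]
        )


@dataclass
class Path:
    """One discretized trajectory: ages (strictly increasing from 0) and states."""

    ages: np.ndarray
    states: np.ndarray  # (steps, N)

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, float)
        self.states = np.asarray(self.states, float)
        if self.states.ndim == 1:
            self.states = self.states[:, None]
        if self.ages[0] != 0.0 or np.any(np.diff(self.ages) <= 0):
            raise InvalidModelError("path ages must increase strictly from 0")


def _mortality_series(lh: LifeHistory, path: Path, policy: ControlPolicy) -> np.ndarray:
    mus = np.empty(len(path.ages))
    for i, (a, x) in enumerate(zip(path.ages, path.states)):
        u = lh.sde.clamp_control(policy(x, float(a)))
        mus[i] = lh.mortality(x, u, float(a))
    return mus


def maturity_time(lh: LifeHistory, path: Path):
    """First age at which the path crosses an absorbing-maturity face.

    The crossing age is linearly interpolated between the bracketing grid
    points.  Returns :data:`NOT_REACHED` if the path stays immature over the
    whole simulated horizon.
    """
    if not lh.is_semelparous:
        raise UsageError("maturity_time applies to semelparous life histories")
    dim, side, thr = lh.mature_threshold()
    x = path.states[:, dim]
    hit = x <= thr if side == "lower" else x >= thr
    if not hit.any():
        return NOT_REACHED
    k = int(np.argmax(hit))
    if k == 0:
        return float(path.ages[0])
    x0, x1 = x[k - 1], x[k]
    frac = 0.0 if x1 == x0 else (thr - x0) / (x1 - x0)
    return float(path.ages[k - 1] + frac * (path.ages[k] - path.ages[k - 1]))


def survivorship_along_path(
    lh: LifeHistory, path: Path, policy: ControlPolicy
) -> float:
    """``exp(-int mu dt)`` by the trapezoid rule, with breeding-system cutoffs.

    Iteroparous: hard zero beyond the maximum lifespan omega.  Semelparous:
    zero after the first boundary hit (the individual reproduces and dies);
    the value returned is the survivorship at the end of the path, i.e. at
    ``min(horizon, tau_mature)`` for semelparous and ``horizon`` (or 0 past
    omega) for iteroparous.
    """
    mus = _mortality_series(lh, path, policy)
    a_end = float(path.ages[-1])
    if lh.is_semelparous:
        tau = maturity_time(lh, path)
        if tau is not NOT_REACHED and tau < a_end:
            a_end = tau
    elif a_end > lh.fertility.max_lifespan:
        return 0.0
    ages = path.ages
    mask = ages <= a_end
    integ = np.trapezoid(mus[mask], ages[mask])
    if a_end > ages[mask][-1]:  # partial last interval up to the cutoff
        i = int(mask.sum()) - 1
        mu_end = np.interp(a_end, ages, mus)
        integ += 0.5 * (mus[i] + mu_end) * (a_end - ages[i])
    return float(math.exp(-integ))


def fertility_along_path(lh: LifeHistory, path: Path, policy: ControlPolicy):
    """Per-age fertility values along a path.

    Iteroparous: the rate ``b(x(a), a)`` at every grid age up to
    ``min(horizon, omega)`` (zeros beyond omega).  Semelparous: a single
    point mass ``q(x*)`` at the (interpolated) maturity time, represented as
    ``(tau, q)``; ``(None, 0.0)`` if the path never matures.
    """
    if lh.is_semelparous:
        tau = maturity_time(lh, path)
        if tau is NOT_REACHED:
            return NOT_REACHED, 0.0
        dim, side, thr = lh.mature_threshold()
        xstar = np.array(np.interp(tau, path.ages, path.states[:, dim]), ndmin=1)
        xstar[0] = thr
        return tau, lh.fertility(xstar, tau)
    omega = lh.fertility.max_lifespan
    vals = np.zeros(len(path.ages))
    for i, (a, x) in enumerate(zip(path.ages, path.states)):
        if a <= omega:
            vals[i] = lh.fertility(x, float(a))
    return vals
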