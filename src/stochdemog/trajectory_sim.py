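"""Seeded Euler-Maruyama simulation of controlled life histories and
Monte-Carlo estimators of the ERS, the objective function, and breeding ages.

Vectorization contract: the drift / diffusion / mortality / fertility
callables of the model must broadcast over a leading paths axis (``x`` of
shape ``(n, N)`` yields drift ``(n, N)``, diffusion ``(n, N, M)``, scalars are
broadcast).  The registered model families satisfy this; hand-built models
that do not can still be evaluated pathwise through :mod:`.life_history`.

Randomness: one global seed spawns an independent Philox substream per fixed
8192-path chunk, so enlarging ``n_paths`` extends the ensemble without
reshuffling the paths already drawn.

Survivorship is carried as a multiplicative weight ``exp(-int mu dt)`` rather
than by killing paths (lower variance); a killing mode that draws actual
deaths is available for validation and for sampling observed maturity ages.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .demography import ErsCurve
from .life_history import ControlPolicy, LifeHistory

__all__ = [
    "SimConfig",
    "PathEnsemble",
    "simulate_paths",
    "estimate_ers_mc",
    "estimate_objective_mc",
    "sample_breeding_ages",
]

_CHUNK = 8192


@dataclass(frozen=True)
class SimConfig:
    """Monte-Carlo settings.

    ``bridge_correction`` enables the Brownian-bridge within-step crossing
    test for semelparous maturity (removes the O(sqrt(dt)) first-passage
    discretization bias of discrete-time threshold checks); off by default.
    ``killing`` switches from survivorship weighting to sampled deaths.
    """

    dt: float
    horizon: float
    n_paths: int
    seed: int
    bridge_correction: bool = False
    killing: bool = False
    store_states: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.dt < self.horizon):
            raise ValueError("need 0 < dt << horizon")
        if self.n_paths < 1:
            raise ValueError("n_paths >= 1")


@dataclass
class PathEnsemble:
    """Realization ensemble of the controlled SDE.

    ``states``: (n_paths, n_steps+1, N); ``weights``: accumulated
    survivorship weight per path/age (non-increasing); semelparous paths are
    frozen at the mature boundary with their maturity age, and survivorship
    weight at maturity, recorded.  ``flagged`` marks paths that escaped the
    truncation bounds (excluded from estimators).
    """

    ages: np.ndarray
    states: np.ndarray
    weights: np.ndarray
    maturity_times: np.ndarray  # NaN where not reached / iteroparous
    maturity_weights: np.ndarray
    flagged: np.ndarray
    config: SimConfig
    alive: np.ndarray | None = None  # killing mode only

    @property
    def n_paths(self) -> int:
        return self.states.shape[0]

    @property
    def valid(self) -> np.ndarray:
        return ~self.flagged

    def export(self, table_path: str, sidecar_path: str) -> None:
        """Columnar dump (path id, age, states, weight) + JSON config sidecar."""
        import pandas as pd

        n, s, dim = self.states.shape
        rec = {
            "path": np.repeat(np.arange(n), s),
            "age": np.tile(self.ages, n),
            "weight": self.weights.reshape(-1),
        }
        for d in range(dim):
            rec[f"x{d}"] = self.states[:, :, d].reshape(-1)
        pd.DataFrame(rec).to_csv(table_path, index=False)
        with open(sidecar_path, "w") as fh:
            json.dump({"config": asdict(self.config)}, fh, indent=2)


def _policy_controls(policy: ControlPolicy, x: np.ndarray, a: float) -> np.ndarray:
    """Vectorized control evaluation, shape (n, 1) from states (n, N)."""
    u = policy.control_at(x[:, 0], a)
    return np.asarray(u, float)[:, None]


def simulate_paths(
    lh: LifeHistory,
    policy: ControlPolicy,
    cfg: SimConfig,
    x_init: Optional[np.ndarray] = None,
) -> PathEnsemble:
    """Euler-Maruyama ensemble of the controlled life history.

    Multiplicative (GBM-like) 1-D models are stepped in log-state to preserve
    positivity; for state-independent coefficients the per-step increment is
    then exact in distribution.  Semelparous paths freeze at the first
    boundary hit with a linearly interpolated crossing age (optionally
    bridge-corrected).  Fully reproducible from ``cfg.seed``.
    """
    n_steps = int(round(cfg.horizon / cfg.dt))
    ages = np.arange(n_steps + 1) * cfg.dt
    dim = lh.space.dim
    n = cfg.n_paths
    dt, sq_dt = cfg.dt, math.sqrt(cfg.dt)
    log_mode = lh.sde.multiplicative and dim == 1

    # store_states=False keeps only the initial and final snapshot, which is
    # all the semelparous estimators need; saves memory on large ensembles
    n_store = n_steps + 1 if cfg.store_states else 2
    states = np.empty((n, n_store, dim))
    weights = np.empty((n, n_store))
    maturity_times = np.full(n, np.nan)
    maturity_weights = np.zeros(n)
    flagged = np.zeros(n, bool)
    alive_out = np.ones(n, bool) if cfg.killing else None

    semel = lh.is_semelparous
    if semel:
        mdim, mside, thr = lh.mature_threshold()
        if mside != "upper" or mdim != 0:
            raise NotImplementedError("maturity supported on the upper face of x[0]")
        y_thr = math.log(thr) if log_mode else thr
    lo_tr = np.asarray(lh.space.lower, float)
    hi_tr = np.asarray(lh.space.upper, float)

    x_start = lh.sde.x0 if x_init is None else np.asarray(x_init, float)
    if x_start.ndim == 1 and x_init is not None and len(x_start) == n:
        x_start = x_start[:, None]

    ss = np.random.SeedSequence(cfg.seed)
    n_chunks = (n + _CHUNK - 1) // _CHUNK
    child_seeds = ss.spawn(n_chunks)

    for c in range(n_chunks):
        i0, i1 = c * _CHUNK, min((c + 1) * _CHUNK, n)
        m = i1 - i0
        rng = np.random.Generator(np.random.Philox(child_seeds[c]))
        if x_start.ndim == 2 and x_start.shape[0] == n:
            x = x_start[i0:i1].astype(float).copy()
        else:
            x = np.tile(np.ravel(x_start)[None, :].astype(float), (m, 1))
        w = np.ones(m)
        active = np.ones(m, bool)  # not matured, not flagged, not dead
        states[i0:i1, 0] = x
        weights[i0:i1, 0] = w
        y = np.log(x[:, 0]) if log_mode else None

        for k in range(n_steps):
            a = k * dt
            u = _policy_controls(policy, x, a)
            u = np.clip(u, lh.sde.control_lower, lh.sde.control_upper)
            g = np.asarray(lh.sde.drift(x, u, a), float).reshape(m, dim)
            sig = np.asarray(lh.sde.diffusion(x, u, a), float).reshape(
                m, dim, lh.sde.n_noise
            )
            mu = np.broadcast_to(
                np.asarray(lh.mortality.rate(x, u, a), float), (m,)
            )
            if np.any(mu < 0):
                from .life_history import InvalidModelError

                raise InvalidModelError("negative mortality rate")
            # draws are always chunk-width so a partial last chunk consumes
            # the stream identically to a full one (prefix stability in n)
            z = rng.standard_normal((_CHUNK, lh.sde.n_noise))[:m]
            kill_u = rng.random(_CHUNK)[:m] if cfg.killing else None
            bridge_u = (
                rng.random(_CHUNK)[:m] if cfg.bridge_correction else None
            )

            if log_mode:
                xx = x[:, 0]
                srow = sig[:, 0, :] / xx[:, None]
                var_y = np.einsum("ij,ij->i", srow, srow)
                nu = g[:, 0] / xx - 0.5 * var_y
                y_old = y.copy()
                step = nu * dt + np.einsum("ij,ij->i", srow, z) * sq_dt
                y_new = np.where(active, y + step, y)
                x_new = np.exp(y_new)[:, None]
            else:
                incr = g * dt + np.einsum("ijk,ik->ij", sig, z) * sq_dt
                x_new = np.where(active[:, None], x + incr, x)

            # survivorship weighting / killing on still-active paths
            decay = np.exp(-mu * dt)
            if cfg.killing:
                die = active & (kill_u > decay)
                active &= ~die
            else:
                w = np.where(active, w * decay, w)

            if semel:
                xv_old = x[:, 0]
                xv_new = x_new[:, 0]
                crossed = active & (xv_new >= thr)
                if crossed.any():
                    if log_mode:
                        num = y_thr - y_old[crossed]
                        den = y_new[crossed] - y_old[crossed]
                    else:
                        num = thr - xv_old[crossed]
                        den = xv_new[crossed] - xv_old[crossed]
                    frac = np.where(den > 0, np.clip(num / den, 0.0, 1.0), 0.0)
                    t_hit = a + frac * dt
                    idx = np.where(crossed)[0]
                    maturity_times[i0 + idx] = t_hit
                    if cfg.killing:
                        # decay was a whole-step Bernoulli; matured paths count
                        w_hit = np.ones(len(idx))
                    else:
                        # undo the part of the step decay past the hitting age
                        w_hit = w[idx] * np.exp(mu[idx] * dt * (1.0 - frac))
                    maturity_weights[i0 + idx] = w_hit
                    x_new[crossed, 0] = thr
                    if log_mode:
                        y_new[crossed] = y_thr
                    active &= ~crossed
                if cfg.bridge_correction and sq_dt > 0:
                    below = active & (xv_new < thr) & (xv_old < thr)
                    if below.any() and log_mode:
                        var_step = var_y[below] * dt
                        with np.errstate(divide="ignore"):
                            p_cross = np.exp(
                                -2.0
                                * (y_thr - y_old[below])
                                * (y_thr - y_new[below])
                                / np.where(var_step > 0, var_step, np.inf)
                            )
                        hit = bridge_u[below] < p_cross
                        if hit.any():
                            idx = np.where(below)[0][hit]
                            t_hit = a + 0.5 * dt
                            maturity_times[i0 + idx] = t_hit
                            if cfg.killing:
                                maturity_weights[i0 + idx] = 1.0
                            else:
                                maturity_weights[i0 + idx] = w[idx] * np.exp(
                                    0.5 * mu[idx] * dt
                                )
                            x_new[idx, 0] = thr
                            y_new[idx] = y_thr
                            active[idx] = False

            if not log_mode:
                esc = active & np.any(
                    (x_new < lo_tr[None, :]) | (x_new > hi_tr[None, :]), axis=1
                )
                if semel:
                    esc &= x_new[:, 0] < thr
                if esc.any():
                    flagged[i0:i1][esc] = True
                    active &= ~esc

            x = x_new
            if log_mode:
                y = y_new
            ks = k + 1 if cfg.store_states else 1
            states[i0:i1, ks] = x
            weights[i0:i1, ks] = (
                w if not cfg.killing else active.astype(float)
            )
        if cfg.killing:
            alive_out[i0:i1] = active

    frac_flagged = flagged.mean()
    if frac_flagged > 0.01:
        warnings.warn(
            f"{100 * frac_flagged:.1f}% of paths escaped the truncation bounds"
        )
    # weights at and after maturity reflect the frozen survivorship
    if semel and not cfg.killing:
        matured = ~np.isnan(maturity_times)
        if cfg.store_states:
            for i in np.where(matured)[0]:
                k_hit = int(math.ceil(maturity_times[i] / dt))
                weights[i, k_hit:] = maturity_weights[i]
        else:
            weights[matured, 1] = maturity_weights[matured]
    return PathEnsemble(
        ages=ages,
        states=states,
        weights=weights,
        maturity_times=maturity_times,
        maturity_weights=maturity_weights,
        flagged=flagged,
        config=cfg,
        alive=alive_out,
    )


def _fertility_grid(lh: LifeHistory, ens: PathEnsemble) -> np.ndarray:
    """b(x, a) over (paths, ages), zero beyond the maximum lifespan."""
    b = np.asarray(
        lh.fertility.rate(ens.states, ens.ages[None, :, None]), float
    )
    if b.ndim == 3:
        b = b[:, :, 0]
    b = np.broadcast_to(b, ens.weights.shape).copy()
    b[:, ens.ages > lh.fertility.max_lifespan] = 0.0
    return b


def estimate_ers_mc(ens: PathEnsemble, lh: LifeHistory) -> ErsCurve:
    """Monte-Carlo ERS estimate ``F_hat(tau)``.

    Iteroparous: mean of fertility x survivorship weight at each grid age
    with per-age standard errors.  Semelparous: the weighted point-mass
    representation — one atom per matured path at its maturity age with
    weight ``q S(tau) / n_valid``.
    """
    valid = ens.valid
    nv = int(valid.sum())
    if lh.is_semelparous:
        matured = valid & ~np.isnan(ens.maturity_times)
        taus = ens.maturity_times[matured]
        _, _, thr = lh.mature_threshold()
        qs = np.array(
            [lh.fertility(np.array([thr]), t) for t in np.atleast_1d(taus)]
        ) if taus.size else np.empty(0)
        ws = qs * ens.maturity_weights[matured] / nv
        atoms = list(zip(taus.tolist(), ws.tolist()))
        return ErsCurve(atoms=atoms)
    if not ens.config.store_states:
        raise RuntimeError("iteroparous estimators need store_states=True")
    b = _fertility_grid(lh, ens)[valid]
    fw = b * ens.weights[valid]
    F = fw.mean(axis=0)
    se = fw.std(axis=0, ddof=1) / math.sqrt(nv) if nv > 1 else np.zeros_like(F)
    return ErsCurve(ages=ens.ages, values=F, se=se)


def estimate_objective_mc(
    ens: PathEnsemble, lh: LifeHistory, lam: float, tail_tol: float = 1e-3
):
    """phi_hat(lam) with its standard error, from per-path discounted ERS.

    Trapezoid over the age grid for iteroparous paths; exact sums over the
    maturity atoms for semelparous paths.  Warns with a truncation-bias bound
    when the surviving tail mass at the horizon is above ``tail_tol``.
    """
    valid = ens.valid
    nv = int(valid.sum())
    if lh.is_semelparous:
        matured = valid & ~np.isnan(ens.maturity_times)
        taus = np.where(matured, ens.maturity_times, 0.0)
        _, _, thr = lh.mature_threshold()
        q = lh.fertility(np.array([thr]), 0.0)
        vals = np.where(
            matured, q * ens.maturity_weights * np.exp(-lam * taus), 0.0
        )[valid]
        tail = float(
            np.mean(
                np.where(matured, 0.0, ens.weights[:, -1])[valid]
            )
            * q
            * math.exp(-lam * ens.ages[-1])
        )
    else:
        if not ens.config.store_states:
            raise RuntimeError("iteroparous estimators need store_states=True")
        b = _fertility_grid(lh, ens)[valid]
        disc = np.exp(-lam * ens.ages)[None, :]
        vals = np.trapezoid(b * ens.weights[valid] * disc, ens.ages, axis=1)
        end_rate = float((b[:, -1] * ens.weights[valid][:, -1]).mean())
        tail = (
            end_rate * math.exp(-lam * ens.ages[-1]) / max(lam, 1e-12)
            if ens.ages[-1] < lh.fertility.max_lifespan
            else 0.0
        )
    est = float(vals.mean())
    se = float(vals.std(ddof=1) / math.sqrt(nv)) if nv > 1 else 0.0
    if tail > tail_tol:
        warnings.warn(
            f"objective truncation bias bound {tail:.2e} above {tail_tol:.0e}; "
            "extend the horizon"
        )
    return est, se


def sample_breeding_ages(
    ens: PathEnsemble, lh: LifeHistory, lam: float, n: int, seed: int
) -> np.ndarray:
    """Importance-resampled breeding ages, weights ~ e^{-lam a} F_hat(a)."""
    rng = np.random.default_rng(seed)
    if lh.is_semelparous:
        matured = ens.valid & ~np.isnan(ens.maturity_times)
        taus = ens.maturity_times[matured]
        w = ens.maturity_weights[matured] * np.exp(-lam * taus)
        if taus.size == 0 or w.sum() <= 0:
            raise RuntimeError("degenerate model: no matured reproductive mass")
        return rng.choice(taus, size=n, p=w / w.sum())
    ers = estimate_ers_mc(ens, lh)
    wgrid = np.exp(-lam * ers.ages) * ers.values
    # trapezoid cell masses with uniform jitter inside each cell
    cell = 0.5 * (wgrid[1:] + wgrid[:-1]) * np.diff(ers.ages)
    if cell.sum() <= 0:
        raise RuntimeError("degenerate model: zero reproductive mass")
    j = rng.choice(len(cell), size=n, p=cell / cell.sum())
    return ers.ages[j] + rng.random(n) * np.diff(ers.ages)[j]
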