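"""Scenario runner and cross-formulation agreement reports.

:func:`compare_formulations` computes the fitness of one life history four
independent ways — Monte-Carlo ERS + Euler-Lotka, Fokker-Planck ERS +
Euler-Lotka, the age-size transition-matrix dominant eigenvalue, and the
renewal-equation log-slope — and reports the pairwise gaps.  Their agreement
(and its improvement under refinement) is the operational meaning of the
correspondence between the path-wise, kernel, and matrix formulations of
linear demographic models.

:func:`run_scenario` drives the library from a config mapping, writing
delimited tables, a JSON summary, and (on request) qualitative figures whose
defining property is asserted, not eyeballed.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import demography, hjb_control, pde_engine, trajectory_sim, two_resource
from .config import build_from_config
from .life_history import ControlPolicy, LifeHistory

__all__ = ["Scenario", "ComparisonSettings", "compare_formulations", "run_scenario"]


@dataclass(frozen=True)
class ComparisonSettings:
    """Resolution knobs for the four-way fitness comparison."""

    n_paths: int = 10000
    dt: float = 0.01
    horizon: float = 30.0
    seed: int = 0
    n_grid: int = 400
    kernel_da: float = 0.05
    kernel_dt: float = 0.0125
    tmm_da: float = 0.25
    tmm_size: int = 160
    x_min_factor: float = 6.0  # log-span below x0 for the PDE grid
    renewal_dt: float = 0.02
    tolerance: float = 1e-2


@dataclass
class AgreementReport:
    lambdas: dict
    gaps: dict
    tolerance: float
    passed: bool


def _pde_grid(lh: LifeHistory, settings: ComparisonSettings) -> pde_engine.Grid1D:
    x0 = float(lh.sde.x0[0])
    hi = float(lh.space.upper[0])
    lo = x0 * math.exp(-settings.x_min_factor)
    return pde_engine.Grid1D.regular(lo, hi, settings.n_grid, log=True)


def compare_formulations(
    lh: LifeHistory, policy: ControlPolicy, settings: ComparisonSettings
) -> AgreementReport:
    """Fitness by MC, PDE, TMM, and renewal slope, with pairwise gaps."""
    out: dict[str, float] = {}

    cfg = trajectory_sim.SimConfig(
        dt=settings.dt,
        horizon=settings.horizon,
        n_paths=settings.n_paths,
        seed=settings.seed,
        bridge_correction=lh.is_semelparous,
    )
    ens = trajectory_sim.simulate_paths(lh, policy, cfg)
    ers_mc = trajectory_sim.estimate_ers_mc(ens, lh)
    out["mc"] = demography.solve_euler_lotka(ers_mc).fitness

    grid = _pde_grid(lh, settings)
    ages = np.arange(0.0, settings.horizon + settings.kernel_da, settings.kernel_da)
    kern = pde_engine.solve_fokker_planck(
        lh, policy, grid, ages, dt=settings.kernel_dt
    )
    ers_pde = pde_engine.ers_from_kernel(kern, lh)
    out["pde"] = demography.solve_euler_lotka(ers_pde).fitness

    n_age = int(round(settings.horizon / settings.tmm_da))
    x0 = float(lh.sde.x0[0])
    tmm = pde_engine.build_age_size_tmm(
        lh, policy, settings.tmm_da, settings.tmm_size, n_age,
        x_min=x0 * math.exp(-4.0),
    )
    out["tmm"] = pde_engine.tmm_fitness(tmm)

    slope_gap, _, _ = demography.renewal_residual(
        ers_pde, out["pde"], horizon=2.0 * settings.horizon, dt=settings.renewal_dt
    )
    out["renewal"] = out["pde"] + slope_gap

    keys = list(out)
    gaps = {
        f"{a}-{b}": abs(out[a] - out[b])
        for i, a in enumerate(keys)
        for b in keys[i + 1 :]
    }
    passed = max(gaps.values()) < settings.tolerance
    return AgreementReport(out, gaps, settings.tolerance, passed)


@dataclass
class Scenario:
    """One reproducible run: model config + requested analyses + settings."""

    model: dict
    analyses: list
    out_dir: str
    seed: int | None = None
    mc: dict = field(default_factory=dict)
    hjb: dict = field(default_factory=dict)
    comparison: dict = field(default_factory=dict)
    sweep: dict = field(default_factory=dict)
    make_figures: bool = False

    _STOCHASTIC = {"simulate", "correspondence"}

    def validate(self) -> None:
        bad = [a for a in self.analyses if a not in
               {"simulate", "fitness", "hjb", "two-resource", "correspondence"}]
        if bad:
            raise ValueError(f"unknown analyses {bad}")
        if self.seed is None and set(self.analyses) & self._STOCHASTIC:
            raise ValueError("a seed is mandatory for stochastic analyses")


def _fitness_analysis(lh, settings: ComparisonSettings) -> dict:
    grid = _pde_grid(lh, settings)
    ages = np.arange(0.0, settings.horizon + settings.kernel_da, settings.kernel_da)
    kern = pde_engine.solve_fokker_planck(lh, ControlPolicy("constant", 0.0),
                                          grid, ages, dt=settings.kernel_dt)
    ers = pde_engine.ers_from_kernel(kern, lh)
    sol = demography.solve_euler_lotka(ers)
    return {
        "lambda": sol.fitness,
        "R0": sol.R0,
        "cumulants": sol.cumulants,
        "diagnostics": sol.diagnostics,
    }


def _two_resource_analysis(model: dict, sweep: dict, out: Path, figures: bool) -> dict:
    import pandas as pd

    p = two_resource.TwoResourceParams(**model["params"])
    res: dict = {}
    mix = two_resource.semelparous_optimal_mix(p)
    res["semelparous"] = asdict(mix)
    imix = two_resource.iteroparous_optimal_mix(p)
    R0, (ages, psi), omega_min, shape = two_resource.iteroparous_demography(p, imix)
    res["iteroparous"] = {**asdict(imix), "R0": R0,
                          "omega_min": omega_min, "density_shape": shape}
    n_grid = np.asarray(sweep.get("n_values",
                                  np.round(np.linspace(0.05, 1.2, 24), 4)))
    rows = []
    for n in n_grid:
        pn = two_resource.TwoResourceParams(
            **{**model["params"], "q": (p.xm / p.x0) ** float(n)}
        )
        m = two_resource.semelparous_optimal_mix(pn)
        rows.append((float(n), m.u_star, m.lambda_star, m.regime))
    sweep_df = pd.DataFrame(rows, columns=["n", "u_star", "lambda_star", "regime"])
    sweep_df.to_csv(out / "semelparous_sweep.csv", index=False)
    # qualitative contract of the sweep: risky weight non-decreasing in n,
    # and no more than two regimes along the sweep
    du = np.diff(sweep_df["u_star"].to_numpy())
    assert np.all(du >= -1e-12), "u*(n) must be non-decreasing"
    assert sweep_df["regime"].nunique() <= 2
    res["sweep_file"] = "semelparous_sweep.csv"
    if figures:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
        axes[0].plot(sweep_df["n"], sweep_df["u_star"])
        axes[0].set(xlabel="convexity index n", ylabel="optimal weight on R1")
        axes[1].plot(sweep_df["n"], sweep_df["lambda_star"])
        axes[1].set(xlabel="convexity index n", ylabel="fitness")
        fig.tight_layout()
        fig.savefig(out / "two_resource_sweep.png", dpi=120)
        plt.close(fig)
        res["figure"] = "two_resource_sweep.png"
    return res


def run_scenario(scenario: Scenario) -> dict:
    """Execute the requested analyses; write tables, summary, and a log."""
    scenario.validate()
    out = Path(scenario.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    results: dict = {"errors": {}}
    lh = build_from_config(scenario.model)
    settings = ComparisonSettings(
        **{**({"seed": scenario.seed} if scenario.seed is not None else {}),
           **scenario.comparison}
    )
    policy = ControlPolicy(
        "constant", scenario.model.get("control", {}).get("fixed_u", 0.0)
    )
    for analysis in scenario.analyses:
        try:
            if analysis == "simulate":
                cfg = trajectory_sim.SimConfig(
                    dt=scenario.mc.get("dt", 0.01),
                    horizon=scenario.mc.get("horizon", 30.0),
                    n_paths=scenario.mc.get("n_paths", 1000),
                    seed=scenario.seed,
                )
                ens = trajectory_sim.simulate_paths(lh, policy, cfg)
                ens.export(str(out / "paths.csv"), str(out / "paths.json"))
                results["simulate"] = {
                    "n_paths": ens.n_paths,
                    "flagged": int(ens.flagged.sum()),
                    "final_mean_state": float(
                        ens.states[ens.valid, -1, 0].mean()
                    ),
                }
            elif analysis == "fitness":
                results["fitness"] = _fitness_analysis(lh, settings)
            elif analysis == "hjb":
                grid = _pde_grid(lh, settings)
                lam, vg = hjb_control.optimal_fitness(
                    lh, grid, hjb_control.HjbConfig(**scenario.hjb)
                )
                np.savetxt(
                    out / "value_function.tsv",
                    np.column_stack([grid.nodes, vg.V, vg.policy]),
                    delimiter="\t", header="x\tV\tu", comments="",
                )
                results["hjb"] = {"lambda": lam, "iterations": vg.iterations}
            elif analysis == "two-resource":
                results["two-resource"] = _two_resource_analysis(
                    scenario.model, scenario.sweep, out, scenario.make_figures
                )
            elif analysis == "correspondence":
                rep = compare_formulations(lh, policy, settings)
                results["correspondence"] = asdict(rep)
        except Exception as exc:  # recorded per-analysis; CLI exits nonzero
            results["errors"][analysis] = repr(exc)
    results["elapsed_s"] = time.time() - t0
    results["resolved_config"] = {
        "model": scenario.model,
        "analyses": scenario.analyses,
        "seed": scenario.seed,
        "comparison": asdict(settings),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(results, fh, indent=2, default=float)
    return results
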