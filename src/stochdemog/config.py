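"""Model-family registry and YAML configuration round-trip.

A life history is constructible from a mapping (or YAML file) naming a
registered model family plus numeric parameters, e.g.::

    family: two_resource_gbm
    breeding: semelparous
    params: {m1: 1.0, m2: 0.4, s1: 1.2, s2: 0.4, mu0: 0.05,
             x0: 1.0, xm: 5.0, q: 2.24}
    control: {fixed_u: 0.7}        # optional: freeze the control set

``single_gbm`` is the one-resource special case (no control).  The writer
emits the canonical form so that load(dump(cfg)) round-trips.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from .life_history import (
    ControlledSDE,
    Fertility,
    LifeHistory,
    Mortality,
    StateSpace,
)
from .two_resource import TwoResourceParams, build_life_history

__all__ = ["build_from_config", "load_config", "dump_config", "FAMILIES"]


def _build_two_resource(cfg: dict) -> LifeHistory:
    p = TwoResourceParams(**cfg["params"])
    u = cfg.get("control", {}).get("fixed_u")
    return build_life_history(p, cfg.get("breeding", "semelparous"), u=u)


def _build_single_gbm(cfg: dict) -> LifeHistory:
    prm = cfg["params"]
    g, s, mu0, x0 = prm["g"], prm["s"], prm["mu0"], prm["x0"]

    def drift(x, u, a):
        return g * np.asarray(x, float)

    def diffusion(x, u, a):
        return (s * np.asarray(x, float))[..., None]

    sde = ControlledSDE(
        drift=drift,
        diffusion=diffusion,
        n_noise=1,
        control_lower=np.array([0.0]),
        control_upper=np.array([0.0]),
        x0=np.array([x0]),
        multiplicative=True,
    )
    mort = Mortality(lambda x, u, a: mu0)
    breeding = cfg.get("breeding", "semelparous")
    if breeding == "semelparous":
        space = StateSpace(
            1, (x0 * 1e-6,), (prm["xm"],), upper_kind=("absorbing-maturity",)
        )
        fert = Fertility("semelparous", lambda x, a: prm["q"])
    else:
        space = StateSpace(1, (x0 * 1e-6,), (prm["xm"] * 1e3,))
        fert = Fertility(
            "iteroparous",
            lambda x, a: prm["b0"] * np.asarray(x, float)[..., 0] ** prm["alpha"],
            max_lifespan=prm.get("omega", float("inf")),
        )
    return LifeHistory(sde=sde, mortality=mort, fertility=fert, space=space)


FAMILIES = {
    "two_resource_gbm": _build_two_resource,
    "single_gbm": _build_single_gbm,
}


def build_from_config(cfg: dict) -> LifeHistory:
    family = cfg.get("family")
    if family not in FAMILIES:
        raise KeyError(f"unknown model family {family!r}; know {sorted(FAMILIES)}")
    return FAMILIES[family](cfg)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_config(cfg: dict, path) -> None:
    """Write the canonical (sorted-key) YAML form of a config mapping."""
    canon = {
        "family": cfg["family"],
        "breeding": cfg.get("breeding", "semelparous"),
        "params": dict(sorted(cfg["params"].items())),
    }
    if cfg.get("control"):
        canon["control"] = dict(sorted(cfg["control"].items()))
    Path(path).write_text(yaml.safe_dump(canon, sort_keys=False))
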