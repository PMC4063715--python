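"""Shared fixtures: the reference two-resource study conditions and cached
simulation/solver products reused across test modules."""

from __future__ import annotations

import math

import numpy as np
import pytest

from stochdemog import two_resource as tr
from stochdemog.life_history import ControlPolicy


#: reference study conditions: R1 high risk / high return, R2 low risk /
#: low return, generalist window n in (0, 0.583), persistent for mid-range n
REF = dict(m1=1.0, m2=0.4, s1=1.2, s2=0.4, mu0=0.05, x0=1.0, xm=5.0)


@pytest.fixture(scope="session")
def p_ref() -> tr.TwoResourceParams:
    """Semelparous reference parameters at convexity index n = 0.5."""
    return tr.TwoResourceParams(**REF, q=5.0 ** 0.5)


@pytest.fixture(scope="session")
def p_itero() -> tr.TwoResourceParams:
    """Iteroparous reference parameters (allometric exponent 0.4)."""
    return tr.TwoResourceParams(**REF, b0=0.3, alpha=0.4, omega=15.0)


def params_at_index(n: float, **overrides) -> tr.TwoResourceParams:
    """Reference parameters with the burst fertility set to give index n."""
    base = {**REF, **overrides}
    q = (base["xm"] / base["x0"]) ** n
    return tr.TwoResourceParams(**base, q=q)


@pytest.fixture(scope="session")
def mix_ref(p_ref):
    return tr.semelparous_optimal_mix(p_ref)


@pytest.fixture(scope="session")
def ens_ref(p_ref, mix_ref):
    """Mid-size semelparous ensemble at the optimal constant mix."""
    from stochdemog.trajectory_sim import SimConfig, simulate_paths

    lh = tr.build_life_history(p_ref, "semelparous", u=mix_ref.u_star)
    cfg = SimConfig(dt=0.01, horizon=30.0, n_paths=20000, seed=20240901,
                    bridge_correction=True)
    return simulate_paths(lh, ControlPolicy("constant", mix_ref.u_star), cfg), lh
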