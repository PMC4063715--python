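"""Monte-Carlo route to fitness: simulate, estimate the ERS, solve
Euler-Lotka — and check against the first-passage closed form.

Simulates 20,000 semelparous life histories at the optimal constant mix,
collects the maturity-age atoms of the expectation of reproductive success
F(tau), and finds the fitness as the root of the Laplace-transform equation
phi(lambda) = 1.
"""

import math

from stochdemog.demography import solve_euler_lotka
from stochdemog.life_history import ControlPolicy
from stochdemog.trajectory_sim import SimConfig, estimate_ers_mc, simulate_paths
from stochdemog.two_resource import (
    TwoResourceParams,
    build_life_history,
    semelparous_optimal_mix,
)

p = TwoResourceParams(m1=1.0, m2=0.4, s1=1.2, s2=0.4, mu0=0.05,
                      x0=1.0, xm=5.0, q=5.0 ** 0.5)
mix = semelparous_optimal_mix(p)
lh = build_life_history(p, "semelparous", u=mix.u_star)

cfg = SimConfig(dt=0.01, horizon=30.0, n_paths=20000, seed=2024,
                bridge_correction=True)
ens = simulate_paths(lh, ControlPolicy("constant", mix.u_star), cfg)
matured = (~__import__("numpy").isnan(ens.maturity_times)).mean()
print(f"simulated paths            : {ens.n_paths} (dt = {cfg.dt})")
print(f"matured within horizon     : {100 * matured:.1f} %")

ers = estimate_ers_mc(ens, lh)
sol = solve_euler_lotka(ers)
print(f"MC fitness lambda          : {sol.fitness:.4f}")
print(f"closed-form fitness        : {mix.lambda_star:.4f}")
print(f"MC lifetime reproduction R0: {sol.R0:.3f}")
print(f"mean breeding age          : {sol.cumulants[1]:.2f} time units")
print()
print("The Monte-Carlo root agrees with the closed form to a few parts in")
print("a thousand; the residual is sampling noise plus time-step bias.")
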