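"""HJB solvers: Hamiltonian extremum, value functions, optimal fitness."""

import math

import numpy as np
import pytest

from stochdemog import two_resource as tr
from stochdemog.hjb_control import (
    HjbConfig,
    brute_force_constant_policy,
    control_hamiltonian,
    minimize_hamiltonian_pointwise,
    optimal_fitness,
    solve_finite_horizon_hjb,
    solve_stationary_hjb,
)
from stochdemog.life_history import (
    ControlledSDE,
    ControlPolicy,
    Fertility,
    LifeHistory,
    Mortality,
    StateSpace,
)
from stochdemog.pde_engine import Grid1D


def two_noise_lh(m1, m2, s1, s2, mu0=0.1, xm=5.0, q=2.0):
    """Portfolio SDE with free control in [0, 1] (allows m1 = m2)."""

    def drift(x, u, a):
        return (u * m1 + (1.0 - u) * m2) * np.asarray(x, float)

    def diffusion(x, u, a):
        x = np.asarray(x, float)
        u = np.asarray(u, float)
        return np.stack([u * s1 * x, (1.0 - u) * s2 * x], axis=-1)

    sde = ControlledSDE(
        drift=drift, diffusion=diffusion, n_noise=2,
        control_lower=np.array([0.0]), control_upper=np.array([1.0]),
        x0=np.array([1.0]), multiplicative=True,
    )
    return LifeHistory(
        sde=sde,
        mortality=Mortality(lambda x, u, a: mu0),
        fertility=Fertility("semelparous", lambda x, a: q),
        space=StateSpace(1, (1e-8,), (xm,), upper_kind=("absorbing-maturity",)),
    )


class TestHamiltonian:
    def test_zero_value_zero_fertility(self, p_ref):
        lh = tr.build_life_history(p_ref, "semelparous")
        for u in (0.0, 0.5, 1.0):
            assert control_hamiltonian(lh, 2.0, 0.0, 0.0, 0.0, 0.2, u) == (
                pytest.approx(0.0)
            )

    def test_degenerate_diffusion_symbolic_oracle(self):
        # sigma = 0, V = e^x: H = (g x - lam - mu) e^x + b, checked with sympy
        import sympy as sp

        g, mu0, b0 = 0.2, 0.3, 1.5
        lh = two_noise_lh(g, g - 1e-12, 1e-9, 0.0, mu0=mu0)
        lh.fertility = Fertility("iteroparous", lambda x, a: b0)
        lh.space = StateSpace(1, (1e-8,), (50.0,))
        xs, us = sp.symbols("x u")
        H_sym = (us * g + (1 - us) * (g - 1e-12)) * xs * sp.exp(xs) \
            - (0.4 + mu0) * sp.exp(xs) + b0
        for xv in (0.5, 1.0, 2.0):
            got = control_hamiltonian(
                lh, xv, math.exp(xv), math.exp(xv), math.exp(xv), 0.4, 0.7
            )
            want = float(H_sym.subs({xs: xv, us: 0.7}))
            assert got == pytest.approx(want, rel=1e-6)

    def test_two_resource_quadratic_concave_when_vxx_negative(self, p_ref):
        lh = tr.build_life_history(p_ref, "semelparous")
        us = np.linspace(0.0, 1.0, 9)
        hs = [control_hamiltonian(lh, 2.0, 0.5, -0.8, 1.0, 0.1, u) for u in us]
        d2 = np.diff(hs, 2)
        assert np.all(d2 < 0)  # concave in u


class TestPointwiseOptimum:
    def test_linear_hamiltonian_hits_boundary(self):
        lh = two_noise_lh(0.5, 0.1, 1e-9, 0.0)
        u, _ = minimize_hamiltonian_pointwise(lh, 1.0, Vx=1.0, Vxx=0.0, V=1.0,
                                              lam=0.0)
        assert u == 1.0  # higher drift preferred when variance is free

    def test_pure_variance_minimization(self):
        # m1 = m2: optimum is the variance-minimizing mix s2^2/(s1^2+s2^2)
        s1, s2 = 0.9, 0.3
        lh = two_noise_lh(0.4, 0.4, s1, s2)
        u, _ = minimize_hamiltonian_pointwise(lh, 1.0, Vx=0.1, Vxx=-2.0, V=1.0,
                                              lam=0.0)
        assert u == pytest.approx(s2 ** 2 / (s1 ** 2 + s2 ** 2), abs=1e-9)

    def test_grid_mode_agrees_with_analytic(self, p_ref):
        lh = tr.build_life_history(p_ref, "semelparous")
        args = dict(x=2.0, Vx=0.4, Vxx=-0.5, V=1.0, lam=0.1)
        ua, _ = minimize_hamiltonian_pointwise(lh, **args)
        ug, _ = minimize_hamiltonian_pointwise(
            lh, cfg=HjbConfig(control_mode="grid", m=10001), **args
        )
        assert abs(ua - ug) <= 2.0 / 10001


class TestStationaryHjb:
    def test_deterministic_discounted_hitting_value(self):
        # no noise, g x drift: V(x) = q (x/x*)^{(lam+mu0)/g}
        g, mu0, lam, q, xm = 0.25, 0.1, 0.15, 2.0, 4.0
        lh = two_noise_lh(g, g - 1e-12, 1e-6, 0.0, mu0=mu0, xm=xm, q=q)
        grid = Grid1D.regular(math.exp(-6), xm, 3000, log=True)
        vg = solve_stationary_hjb(lh, lam, grid)
        expo = (lam + mu0) / g
        V_exact = q * (grid.nodes / xm) ** expo
        sel = grid.nodes >= 0.05
        assert np.max(np.abs(vg.V[sel] - V_exact[sel])) < 1e-3

    def test_two_resource_power_law_value_and_constant_policy(
        self, p_ref, mix_ref
    ):
        lh = tr.build_life_history(p_ref, "semelparous")
        grid = Grid1D.regular(p_ref.x0 * math.exp(-8), p_ref.xm, 800, log=True)
        vg = solve_stationary_hjb(lh, mix_ref.lambda_star, grid)
        V_exact = p_ref.q * (grid.nodes / p_ref.xm) ** mix_ref.exponent
        sel = grid.nodes >= p_ref.x0  # away from the truncated lower boundary
        rel = np.abs(vg.V[sel] - V_exact[sel]) / V_exact[sel]
        assert rel.max() < 0.01
        assert np.max(np.abs(vg.policy[sel] - mix_ref.u_star)) < 0.02

    def test_value_decreasing_in_lambda(self, p_ref, mix_ref):
        lh = tr.build_life_history(p_ref, "semelparous")
        grid = Grid1D.regular(p_ref.x0 * math.exp(-6), p_ref.xm, 400, log=True)
        v1 = solve_stationary_hjb(lh, 0.1, grid)
        v2 = solve_stationary_hjb(lh, 0.3, grid)
        assert np.all(v2.V[1:-1] <= v1.V[1:-1] + 1e-12)


class TestFiniteHorizonHjb:
    def test_constant_rates_closed_form(self):
        b0, mu0, lam, omega = 1.2, 0.3, 0.25, 8.0
        lh = two_noise_lh(0.1, 0.1 - 1e-12, 1e-6, 0.0, mu0=mu0)
        lh.fertility = Fertility("iteroparous", lambda x, a: b0,
                                 max_lifespan=omega)
        lh.space = StateSpace(1, (1e-8,), (1e6,))
        grid = Grid1D.regular(0.1, 100.0, 301, log=True)
        ages = np.linspace(0.0, omega, 801)
        vg = solve_finite_horizon_hjb(lh, lam, grid, ages)
        r = lam + mu0
        V_exact = b0 * (1.0 - np.exp(-r * (omega - ages))) / r
        mid = len(grid.nodes) // 2
        assert np.max(np.abs(vg.V[:, mid] - V_exact)) < 5e-3

    def test_two_resource_itero_value_and_age_free_policy(self, p_itero):
        lh = tr.build_life_history(p_itero, "iteroparous")
        grid = tr.suggested_grid(p_itero, "iteroparous", n_nodes=1100)
        ages = np.linspace(0.0, p_itero.omega, 601)
        lam = 0.5
        vg = solve_finite_horizon_hjb(lh, lam, grid, ages)
        u_exact = tr._u_star_of_index(p_itero, p_itero.alpha)
        V_cl = tr.iteroparous_value(p_itero, lam, 0.0, grid.nodes, u=u_exact)
        sel = (grid.nodes >= 0.5) & (grid.nodes <= 2 * p_itero.xm)
        rel = np.abs(vg.V[0][sel] - V_cl[sel]) / V_cl[sel]
        assert rel.max() < 0.01
        # mortality carries no control, so the policy is age-independent
        pol_young = vg.policy[0][sel]
        pol_mid = vg.policy[len(ages) // 2][sel]
        assert np.max(np.abs(pol_young - u_exact)) < 0.02
        assert np.max(np.abs(pol_mid - u_exact)) < 0.02

    def test_long_lifespan_approaches_stationary_value(self, p_itero):
        # at lam > K the value saturates: compare with the infinite-horizon
        # closed form b0 x0^alpha / (lam - K)
        lam = 0.5
        u = tr._u_star_of_index(p_itero, p_itero.alpha)
        K = tr._itero_growth_rate(p_itero, u)
        v_inf = p_itero.b0 * p_itero.x0 ** p_itero.alpha / (lam - K)
        v_fin = tr.iteroparous_value(p_itero, lam, 0.0, p_itero.x0, u=u)
        assert v_fin == pytest.approx(v_inf, rel=0.01)


class TestOptimalFitness:
    def test_fixed_control_matches_closed_form(self, p_ref, mix_ref):
        u = mix_ref.u_star
        lh = tr.build_life_history(p_ref, "semelparous", u=u)
        grid = Grid1D.regular(p_ref.x0 * math.exp(-8), p_ref.xm, 800, log=True)
        lam, _ = optimal_fitness(lh, grid)
        g = tr.effective_drift(p_ref, u)
        s2 = tr.effective_variance(p_ref, u)
        exact = tr.fitness_at_index(g, s2, mix_ref.exponent, p_ref.mu0)
        assert lam == pytest.approx(exact, abs=2e-3)

    def test_free_control_matches_closed_form_optimum(self, p_ref, mix_ref):
        lh = tr.build_life_history(p_ref, "semelparous")
        grid = Grid1D.regular(p_ref.x0 * math.exp(-8), p_ref.xm, 800, log=True)
        lam, vg = optimal_fitness(lh, grid)
        assert lam == pytest.approx(mix_ref.lambda_star, abs=1e-3)

    def test_enlarging_control_set_never_decreases_fitness(self, p_ref):
        grid = Grid1D.regular(p_ref.x0 * math.exp(-8), p_ref.xm, 600, log=True)
        lam_fixed, _ = optimal_fitness(
            tr.build_life_history(p_ref, "semelparous", u=0.3), grid
        )
        lam_free, _ = optimal_fitness(
            tr.build_life_history(p_ref, "semelparous"), grid
        )
        assert lam_free >= lam_fixed - 1e-6

    def test_brute_force_argmax_agrees_with_hjb_policy(self, p_ref, mix_ref):
        n = tr.convexity_index(p_ref)

        def lam_of(u):
            return tr.fitness_at_index(
                tr.effective_drift(p_ref, u),
                tr.effective_variance(p_ref, u), n, p_ref.mu0,
            )

        table, u_best, lam_best = brute_force_constant_policy(
            tr.build_life_history(p_ref, "semelparous"),
            np.linspace(0.0, 1.0, 101), lam_of,
        )
        assert abs(u_best - mix_ref.u_star) <= 0.01
        # lam(u) is continuous (no bang-bang jump): neighboring grid values
        # change smoothly
        lams = table["lam"].to_numpy()
        assert np.max(np.abs(np.diff(lams))) < 0.05

    def test_degenerate_resources_flat_fitness(self):
        # indistinguishable resources: lam(u) flat to tolerance
        s = 0.5
        lh = two_noise_lh(0.4, 0.4 - 1e-12, s, s - 1e-12, mu0=0.05)
        n = math.log(2.0) / math.log(5.0)

        def lam_of(u):
            g = 0.4
            s2 = (u * s) ** 2 + ((1 - u) * s) ** 2
            return tr.fitness_at_index(g, s2, n, 0.05)

        lams = [lam_of(u) for u in np.linspace(0, 1, 11)]
        assert max(lams) - min(lams) < 0.02

    def test_dynkin_martingale_consistency(self, p_ref, mix_ref, ens_ref):
        # along optimally-controlled paths the discounted value process is a
        # martingale: phi-hat(lam*) must equal V(x0) = 1 within MC error
        from stochdemog.trajectory_sim import estimate_objective_mc

        ens, lh = ens_ref
        est, se = estimate_objective_mc(ens, lh, mix_ref.lambda_star)
        assert abs(est - 1.0) < 3 * se
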