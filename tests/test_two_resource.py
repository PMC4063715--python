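"""Closed forms of the two-resource model, checked against their defining
equations (sympy) and against the generic numerical machinery."""

import math

import numpy as np
import pytest
import sympy as sp

from stochdemog import two_resource as tr
from stochdemog.demography import solve_euler_lotka

from conftest import REF, params_at_index


class TestStructuralIdentities:
    """Each closed form must satisfy the equation that defines it."""

    def test_theta_solves_characteristic_quadratic(self):
        for (g, s, lam, mu0) in [(0.5, 0.3, 0.2, 0.1), (1.0, 1.2, -0.05, 0.05)]:
            th = tr.theta_root(g, s, lam, mu0)
            resid = 0.5 * s * s * th * th + (g - 0.5 * s * s) * th - (lam + mu0)
            assert abs(resid) < 1e-12

    def test_fitness_at_index_inverts_theta(self):
        # phi(lam) = 1 forces theta(lam) = n; the fitness formula is that
        # inversion, verified symbolically on the quadratic
        g, s, n, mu0 = sp.symbols("g s n mu0", positive=True)
        lam = g * n + sp.Rational(1, 2) * s ** 2 * n * (n - 1) - mu0
        quad = sp.Rational(1, 2) * s ** 2 * n ** 2 + (g - sp.Rational(1, 2) * s ** 2) * n - (lam + mu0)
        assert sp.simplify(quad) == 0

    def test_power_ansatz_solves_stationary_hjb(self):
        # V = C x^gamma with u* from the interior extremum must satisfy
        # g(u) x V' + 1/2 sigma^2(u) x^2 V'' = (lam + mu0) V at u = u*(gamma),
        # lam = fitness_at_index(gamma), for every x
        x, C = sp.symbols("x C", positive=True)
        m1, m2, s1, s2, mu0, gamma = 1.0, 0.4, 1.2, 0.4, 0.05, sp.Rational(1, 2)
        u = sp.Rational(1, 1) * (s2 ** 2 + (m1 - m2) / (1 - gamma)) / (s1 ** 2 + s2 ** 2)
        g_u = u * m1 + (1 - u) * m2
        var_u = u ** 2 * s1 ** 2 + (1 - u) ** 2 * s2 ** 2
        lam = g_u * gamma + sp.Rational(1, 2) * var_u * gamma * (gamma - 1) - mu0
        V = C * x ** gamma
        resid = g_u * x * sp.diff(V, x) + sp.Rational(1, 2) * var_u * x ** 2 * sp.diff(V, x, 2) - (lam + mu0) * V
        assert sp.simplify(resid) == 0
        # and u* is a stationary point of lam(u) there
        uu = sp.Symbol("uu")
        lam_u = (uu * m1 + (1 - uu) * m2) * gamma + sp.Rational(1, 2) * (
            uu ** 2 * s1 ** 2 + (1 - uu) ** 2 * s2 ** 2
        ) * gamma * (gamma - 1) - mu0
        assert sp.simplify(sp.diff(lam_u, uu).subs(uu, u)) == 0

    def test_iteroparous_value_solves_backward_pde(self):
        # V(a,x) = b0 x^alpha (1-e^{-(lam-K)(omega-a)})/(lam-K) satisfies
        # dV/da + g x Vx + 1/2 sigma^2 x^2 Vxx - (lam+mu0) V + b0 x^alpha = 0
        a, x = sp.symbols("a x", positive=True)
        p = params_at_index(0.5, **{})
        alpha, lam, omega = sp.Rational(2, 5), sp.Rational(1, 2), 15
        u = tr._u_star_of_index(p, 0.4)
        g_u = tr.effective_drift(p, u)
        var_u = tr.effective_variance(p, u)
        K = g_u * alpha + sp.Rational(1, 2) * var_u * alpha * (alpha - 1) - p.mu0
        b0 = sp.Rational(3, 10)
        V = b0 * x ** alpha * (1 - sp.exp(-(lam - K) * (omega - a))) / (lam - K)
        resid = (
            sp.diff(V, a)
            + g_u * x * sp.diff(V, x)
            + sp.Rational(1, 2) * var_u * x ** 2 * sp.diff(V, x, 2)
            - (lam + p.mu0) * V
            + b0 * x ** alpha
        )
        assert sp.simplify(sp.nsimplify(resid, rational=False)) == 0 or \
            abs(float(resid.subs({a: 3.0, x: 2.0}))) < 1e-12


class TestSingleResource:
    def test_objective_deterministic_limit(self):
        g, mu0, x0, xm, q, lam = 0.5, 0.1, 1.0, 5.0, 3.0, 0.2
        T = math.log(xm / x0) / g
        got = tr.single_resource_objective(g, 0.0, mu0, x0, xm, q, lam)
        assert got == pytest.approx(q * math.exp(-(lam + mu0) * T), rel=1e-12)
        # no discounting, no killing -> exactly q
        assert tr.single_resource_objective(g, 0.0, 0.0, x0, xm, q, 0.0) == (
            pytest.approx(q)
        )

    def test_small_noise_continuity(self):
        g, mu0, x0, xm, q, lam = 0.5, 0.1, 1.0, 5.0, 3.0, 0.2
        v0 = tr.single_resource_objective(g, 0.0, mu0, x0, xm, q, lam)
        v1 = tr.single_resource_objective(g, 1e-4, mu0, x0, xm, q, lam)
        assert v1 == pytest.approx(v0, rel=1e-4)

    def test_fitness_agrees_with_numeric_euler_lotka(self):
        p = params_at_index(0.5)
        for s in (0.3, 0.8):
            lam_closed = tr.single_resource_fitness(p.m1, s, p)
            sol = solve_euler_lotka(
                lambda lam: tr.single_resource_objective(
                    p.m1, s, p.mu0, p.x0, p.xm, p.q, lam
                )
            )
            assert lam_closed == pytest.approx(sol.fitness, abs=1e-8)

    def test_noise_sensitivity_sign_flips_at_unit_index(self):
        for n, sign in ((0.5, -1.0), (1.5, +1.0)):
            p = params_at_index(n)
            d = tr.single_resource_fitness(p.m1, 0.2, p) - (
                tr.single_resource_fitness(p.m1, 0.1, p)
            )
            assert d * sign > 0


class TestConvexityIndex:
    def test_monotone_in_fertility(self):
        p1 = params_at_index(0.5)
        p2 = tr.TwoResourceParams(**REF, q=2 * p1.q)
        assert tr.convexity_index(p2) > tr.convexity_index(p1)

    def test_vanishes_for_huge_size_ratio(self):
        p = tr.TwoResourceParams(**{**REF, "xm": 1e9}, q=2.0)
        assert 0.0 < tr.convexity_index(p) < 0.04

    def test_scale_invariance(self):
        p1 = params_at_index(0.5)
        p2 = tr.TwoResourceParams(
            **{**REF, "x0": 3.0 * REF["x0"], "xm": 3.0 * REF["xm"]}, q=p1.q
        )
        assert tr.convexity_index(p1) == pytest.approx(tr.convexity_index(p2))


class TestSemelparousMix:
    def test_negligible_noise_selects_higher_drift(self):
        p = tr.TwoResourceParams(**{**REF, "s1": 1e-6, "s2": 0.0}, q=5.0 ** 0.5)
        assert tr.semelparous_optimal_mix(p).u_star == 1.0

    def test_equal_drift_minimizes_variance(self):
        p = tr.TwoResourceParams(**{**REF, "m2": REF["m1"] - 1e-10}, q=5.0 ** 0.5)
        mix = tr.semelparous_optimal_mix(p)
        expected = p.s2 ** 2 / (p.s1 ** 2 + p.s2 ** 2)
        assert mix.u_star == pytest.approx(expected, abs=1e-9)

    def test_high_index_drops_low_risk_resource(self):
        mix = tr.semelparous_optimal_mix(params_at_index(1.3))
        assert mix.u_star == 1.0 and mix.r2_weight == 0.0
        assert mix.regime == "R1-specialist"

    def test_brute_force_oracle_argmax(self, p_ref, mix_ref):
        n = tr.convexity_index(p_ref)
        us = np.linspace(0.0, 1.0, 4001)
        lams = tr.fitness_at_index(
            tr.effective_drift(p_ref, us), tr.effective_variance(p_ref, us),
            n, p_ref.mu0,
        )
        assert abs(us[np.argmax(lams)] - mix_ref.u_star) <= 1.0 / 4000
        assert lams.max() == pytest.approx(mix_ref.lambda_star, abs=1e-8)

    def test_window_matches_clamping_events(self, p_ref):
        _, n_hi = tr.semelparous_optimal_mix(p_ref).window
        eps = 1e-8
        assert tr.semelparous_optimal_mix(params_at_index(n_hi - 1e-4)).u_star < 1.0
        assert tr.semelparous_optimal_mix(params_at_index(n_hi + eps)).u_star == 1.0

    def test_fitness_and_weight_monotone_in_index(self):
        ns = np.linspace(0.2, 1.1, 19)
        mixes = [tr.semelparous_optimal_mix(params_at_index(n)) for n in ns]
        lams = np.array([m.lambda_star for m in mixes])
        us = np.array([m.u_star for m in mixes])
        persistent = lams >= 0.0
        assert np.all(np.diff(lams[persistent]) > 0)
        assert np.all(np.diff(us) >= -1e-12)
        assert np.max(np.abs(np.diff(us))) < 0.12  # continuous, no jump


class TestIteroparousMix:
    def test_matches_semelparous_at_equal_convexity(self, p_itero):
        # identical risk appetite when alpha equals the semelparous index
        p_sem = params_at_index(p_itero.alpha)
        u_sem = tr.semelparous_optimal_mix(p_sem).u_star
        u_it = tr.iteroparous_optimal_mix(p_itero).u_star
        assert abs(u_sem - u_it) < 1e-8

    def test_negligible_noise_selects_higher_drift(self):
        p = tr.TwoResourceParams(**{**REF, "s1": 1e-6, "s2": 0.0},
                                 b0=0.3, alpha=0.4, omega=15.0)
        assert tr.iteroparous_optimal_mix(p).u_star == 1.0

    def test_u_star_matches_brute_force(self, p_itero):
        us = np.linspace(0.0, 1.0, 2001)
        lams = []
        for u in us:
            sol = solve_euler_lotka(
                lambda lam: tr.iteroparous_objective(p_itero, lam, u=float(u))
            )
            lams.append(sol.fitness)
        u_best = us[int(np.argmax(lams))]
        assert abs(u_best - tr.iteroparous_optimal_mix(p_itero).u_star) <= 5e-4

    def test_fitness_below_infinite_lifespan_bound(self, p_itero):
        mix = tr.iteroparous_optimal_mix(p_itero)
        assert mix.lambda_star <= tr.iteroparous_fitness_bound(p_itero) + 1e-12

    def test_fitness_monotone_in_lifespan(self):
        lams = []
        for omega in (5.0, 10.0, 20.0, 40.0):
            p = tr.TwoResourceParams(**REF, b0=0.3, alpha=0.4, omega=omega)
            lams.append(tr.iteroparous_optimal_mix(p).lambda_star)
        assert np.all(np.diff(lams) > 0)

    def test_ers_monotone_in_alpha(self):
        # F(a) = b0 x0^alpha e^{K(alpha) a} increases with alpha at every age
        ages = np.linspace(0.1, 15.0, 30)
        prev = None
        for alpha in (0.3, 0.5, 0.7):
            p = tr.TwoResourceParams(**REF, b0=0.3, alpha=alpha, omega=15.0)
            u = tr._u_star_of_index(p, alpha)
            K = tr._itero_growth_rate(p, u)
            F = p.b0 * p.x0 ** alpha * np.exp(K * ages)
            if prev is not None:
                assert np.all(F >= prev)
            prev = F


class TestIteroparousDemography:
    def test_uniform_density_at_zero_exponent(self):
        # b0 x0^alpha omega = 1 makes lam* = K and the density uniform
        omega = 12.0
        p = tr.TwoResourceParams(**REF, b0=1.0 / omega, alpha=0.4, omega=omega)
        mix = tr.iteroparous_optimal_mix(p)
        R0, (ages, psi), omega_min, shape = tr.iteroparous_demography(p, mix)
        assert shape == "uniform"
        assert np.allclose(psi, 1.0 / omega, rtol=1e-6)

    def test_density_normalization_and_r0(self, p_itero):
        mix = tr.iteroparous_optimal_mix(p_itero)
        R0, (ages, psi), omega_min, shape = tr.iteroparous_demography(p_itero, mix)
        # the closed-form exponential density is normalized exactly: recover
        # its exponent from the grid and integrate analytically
        r = (math.log(psi[-1]) - math.log(psi[0])) / (ages[-1] - ages[0])
        psi0 = psi[0]
        assert psi0 * (math.exp(r * p_itero.omega) - 1.0) / r == (
            pytest.approx(1.0, abs=1e-10)
        )
        assert np.trapezoid(psi, ages) == pytest.approx(1.0, abs=1e-5)
        assert R0 == pytest.approx(
            tr.iteroparous_objective(p_itero, 0.0), rel=1e-6
        )
        # r0 crosses one exactly at the reported minimum viable lifespan
        p_at_min = tr.TwoResourceParams(
            **REF, b0=p_itero.b0, alpha=p_itero.alpha, omega=omega_min
        )
        mix_min = tr.MixResult(mix.u_star, 0.0, mix.exponent, mix.regime,
                               mix.window)
        R0_min, _, _, _ = tr.iteroparous_demography(p_at_min, mix_min)
        assert R0_min == pytest.approx(1.0, abs=1e-6)

    def test_j_shaped_when_exponent_positive(self):
        omega = 12.0
        p = tr.TwoResourceParams(**REF, b0=0.5 / omega, alpha=0.4, omega=omega)
        mix = tr.iteroparous_optimal_mix(p)
        _, (ages, psi), _, shape = tr.iteroparous_demography(p, mix)
        assert shape == "increasing"
        assert np.all(np.diff(psi) > 0)


class TestMatureAgeDensity:
    def test_deterministic_point_mass(self):
        p = params_at_index(0.5)
        dens = tr.mature_age_density(p, 1.0) if p.s2 == 0 else None
        # deterministic limit via a custom zero-noise parameter set
        p0 = tr.TwoResourceParams(**{**REF, "s1": 1e-9, "s2": 0.0}, q=p.q)
        d = tr.mature_age_density(p0, 0.0)  # pure R2: drift m2, s = 0
        t_star = math.log(p0.xm / p0.x0) / p0.m2
        assert d.cdf(t_star * 0.99) < 0.01 and d.cdf(t_star * 1.01) > 0.99

    def test_unnormalized_integral_equals_r0_over_q(self, p_ref, mix_ref):
        d = tr.mature_age_density(p_ref, mix_ref.u_star)
        g = tr.effective_drift(p_ref, mix_ref.u_star)
        s = math.sqrt(tr.effective_variance(p_ref, mix_ref.u_star))
        R0 = tr.single_resource_objective(
            g, s, p_ref.mu0, p_ref.x0, p_ref.xm, p_ref.q, 0.0
        )
        assert d.norm * p_ref.q == pytest.approx(R0, rel=1e-6)

    def test_matches_simulated_maturity_ages(self, p_ref, mix_ref):
        from stochdemog.life_history import ControlPolicy
        from stochdemog.trajectory_sim import SimConfig, simulate_paths
        from scipy import stats

        u = mix_ref.u_star
        lh = tr.build_life_history(p_ref, "semelparous", u=u)
        cfg = SimConfig(dt=0.005, horizon=40.0, n_paths=10000, seed=77,
                        bridge_correction=True, killing=True)
        ens = simulate_paths(lh, ControlPolicy("constant", u), cfg)
        taus = ens.maturity_times[~np.isnan(ens.maturity_times)]
        d = tr.mature_age_density(p_ref, u)
        ks = stats.kstest(taus, lambda t: d.cdf(t))
        assert ks.statistic < 0.02

    def test_density_shifts_younger_as_index_grows(self):
        # the index grows as the size ratio shrinks (q fixed): maturity is
        # closer, so the mature-age distribution of every utilization
        # behavior moves toward younger ages
        q = 2.0
        for u in (0.5, 0.85):
            means = []
            for n in (0.3, 0.5, 0.8):
                xm = REF["x0"] * math.exp(math.log(q) / n)
                p = tr.TwoResourceParams(**{**REF, "xm": xm}, q=q)
                d = tr.mature_age_density(p, u)
                grid = d._grid_t
                means.append(np.trapezoid(grid * d.pdf(grid), grid))
            assert means[0] > means[1] > means[2]


class TestOptimalMatureSize:
    def test_humped_fertility_family_first_order_condition(self, p_ref):
        # q(x) = q0 x e^{-x/xc}: the objective optimum solves
        # q'/q = theta/x, i.e. x* = xc (1 - theta) for this family
        xc, lam, u = 6.0, 0.1, 1.0
        q_of_x = lambda x: 3.0 * x * math.exp(-x / xc)
        g = tr.effective_drift(p_ref, u)
        s = math.sqrt(tr.effective_variance(p_ref, u))
        theta = tr.theta_root(g, s, lam, p_ref.mu0)
        assert theta < 1.0
        xm_star, phi_star = tr.optimal_mature_size(p_ref, q_of_x, lam, u=u,
                                                   x_hi=30.0)
        assert xm_star == pytest.approx(xc * (1.0 - theta), rel=1e-6)
        for xm in (0.8 * xm_star, 1.2 * xm_star):
            phi = tr.single_resource_objective(
                g, s, p_ref.mu0, p_ref.x0, xm, q_of_x(xm), lam
            )
            assert phi <= phi_star + 1e-12


class TestSensitivityScan:
    def test_threshold_located_at_unit_index(self, p_ref):
        table, n_thr = tr.stochasticity_sensitivity_scan(
            p_ref, np.linspace(0.4, 1.6, 7)
        )
        assert n_thr == pytest.approx(1.0, abs=1e-3)
        for n, d in table:
            if n < 0.9:
                assert d < 0
            if n > 1.1:
                assert d > 0
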