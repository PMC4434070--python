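"""Method-of-steps integrator: conservation, oracle agreement, reductions."""

import math
from dataclasses import replace

import numpy as np
import pytest

from monodde import (
    DomainError,
    History,
    InitialData,
    ModelParameters,
    GrowthModelSpec,
    SolverOptions,
    UsageError,
    ValidationError,
    euler_oracle,
    evaluate_at,
    make_history,
    rhs,
    sample_scenario,
    simulate,
)

MONOD = GrowthModelSpec("monod", mu_max=1.0, k_s=1.0)


def total_mass(params, traj):
    """gamma*s + x, the conserved quantity of the mortality-free model."""
    return params.gamma * traj._s + traj._x


class TestRhs:
    def test_substrate_exhaustion_stalls_both_equations(self):
        p = ModelParameters(growth=MONOD, gamma=2.0, k1=0.0, k2=0.5, tau=1.0)
        assert rhs(p, 0.0, 1.0, 0.0) == (0.0, 0.0)

    def test_direct_substitution(self):
        # mu(1) = 0.5 for monod with mu_max = k_s = 1
        p = ModelParameters(growth=MONOD, gamma=2.0, k1=0.1, k2=0.2, tau=1.0)
        ds, dx = rhs(p, 1.0, 1.0, 1.0)
        assert ds == pytest.approx(-0.25, abs=1e-15)
        assert dx == pytest.approx(0.2, abs=1e-15)

    def test_production_balancing_instant_decay(self):
        p = ModelParameters(growth=MONOD, gamma=1.0, k1=0.5, k2=0.0, tau=0.0)
        _, dx = rhs(p, 1.0, 3.0, 3.0)  # mu(1) = 0.5 = k1
        assert dx == pytest.approx(0.0, abs=1e-15)

    def test_negative_state_rejected(self):
        p = ModelParameters(growth=MONOD, gamma=1.0)
        with pytest.raises(DomainError):
            rhs(p, -1.0, 1.0, 1.0)


class TestValidation:
    def test_parameter_invariants(self):
        with pytest.raises(ValidationError):
            ModelParameters(growth=MONOD, gamma=0.0)
        with pytest.raises(ValidationError):
            ModelParameters(growth=MONOD, gamma=1.0, k1=-0.1)
        with pytest.raises(ValidationError):
            ModelParameters(growth=MONOD, gamma=1.0, tau=-1.0)

    def test_history_must_be_nondecreasing(self):
        with pytest.raises(ValidationError):
            History("tabular", tau=2.0, knots=[(-2.0, 0.5), (-1.0, 0.3), (0.0, 0.4)])

    def test_tabular_history_interpolates_monotonically(self):
        h = History("tabular", tau=2.0, knots=[(-2.0, 0.1), (-1.0, 0.1), (0.0, 0.4)])
        ts = np.linspace(-2.0, 0.0, 1001)
        vals = np.array([h(t) for t in ts])
        assert np.all(np.diff(vals) >= -1e-15)
        assert h(0.0) == pytest.approx(0.4)

    def test_initial_data_requires_positive_inoculum(self):
        with pytest.raises(ValidationError):
            InitialData(s0=-1.0, history=make_history("constant", 0.1, 1.0))

    def test_history_delay_must_match_model_delay(self):
        p = ModelParameters(growth=MONOD, gamma=1.0, k2=0.1, tau=2.0)
        init = InitialData(s0=5.0, history=make_history("constant", 0.1, tau=1.0))
        with pytest.raises(ValidationError):
            simulate(p, init, 10.0)

    def test_plain_callable_history_is_screened(self):
        p = ModelParameters(growth=MONOD, gamma=1.0, k2=0.1, tau=2.0)
        decreasing = lambda t: 0.2 - 0.05 * t  # rises into the past: invalid
        with pytest.raises(ValidationError):
            simulate(p, InitialData(s0=5.0, history=decreasing), 10.0)


class TestConservation:
    def test_mortality_free_model_conserves_gamma_s_plus_x(self, scenarios):
        sc = scenarios["classical"]
        traj = simulate(sc.params, sc.init, sc.horizon)
        tot = total_mass(sc.params, traj)
        assert np.max(np.abs(tot - tot[0])) <= 1e-6 * tot[0]

    def test_euler_oracle_is_exactly_conservative_without_mortality(self, scenarios):
        # both Euler updates share the same mu(s_i)*x_i product, so
        # gamma*s + x is conserved to roundoff when k1 = k2 = 0
        sc = scenarios["classical"]
        for h in (2e-3, 1e-3):
            tr = euler_oracle(sc.params, sc.init, 10.0, h)
            tot = total_mass(sc.params, tr)
            assert np.max(np.abs(tot - tot[0])) <= 1e-12 * tot[0]


class TestOracleAgreement:
    def test_final_state_matches_euler_oracle(self, scenarios):
        # moderate oracle step here; the acceptance suite runs h = 1e-4
        for name in ("delay-only", "combined-webb", "no-growth"):
            sc = scenarios[name]
            rk = simulate(sc.params, sc.init, sc.horizon)
            eu = euler_oracle(sc.params, sc.init, sc.horizon, 1e-3)
            T = min(rk.horizon, eu.horizon)
            s1, x1 = rk.evaluate_at(T)
            s2, x2 = eu.evaluate_at(T)
            scale = 1e-6 * (sc.params.gamma * sc.init.s0 + sc.init.x0)
            assert abs(s1 - s2) <= 1e-2 * max(abs(s2), scale)
            assert abs(x1 - x2) <= 1e-2 * max(abs(x2), scale)

    def test_euler_first_order_convergence(self, scenarios):
        sc = scenarios["delay-only"]
        ref = simulate(sc.params, sc.init, 20.0)
        errs = []
        for h in (1e-3, 5e-4, 2.5e-4):
            eu = euler_oracle(sc.params, sc.init, 20.0, h)
            errs.append(abs(eu.evaluate_at(20.0)[1] - ref.evaluate_at(20.0)[1]))
        assert errs[0] / errs[1] == pytest.approx(2.0, rel=0.25)
        assert errs[1] / errs[2] == pytest.approx(2.0, rel=0.25)

    def test_euler_single_step_arithmetic(self):
        p = ModelParameters(growth=MONOD, gamma=2.0, k1=0.1, k2=0.2, tau=1.0)
        init = InitialData(s0=1.0, history=make_history("constant", 0.5, 1.0))
        tr = euler_oracle(p, init, 1.0, 1.0)  # h = tau: one step per delay
        # x(h) = x0 + h*(mu(s0)*x0 - k1*x0 - k2*phi(-tau))
        expected = 0.5 + 1.0 * (0.5 * 0.5 - 0.1 * 0.5 - 0.2 * 0.5)
        assert tr._x[1] == pytest.approx(expected, abs=1e-15)

    def test_euler_requires_integral_delay_ratio(self):
        p = ModelParameters(growth=MONOD, gamma=1.0, k2=0.1, tau=1.0)
        init = InitialData(s0=1.0, history=make_history("constant", 0.1, 1.0))
        with pytest.raises(UsageError):
            euler_oracle(p, init, 5.0, 0.3)


class TestReductions:
    def test_no_delayed_mortality_makes_tau_inert(self, scenarios):
        sc = scenarios["instant-only"]  # k2 = 0, tau = 2
        h = sc.params.tau / 64
        tr_tau = simulate(sc.params, sc.init, sc.horizon, SolverOptions(h=h))
        p0 = replace(sc.params, tau=0.0)
        init0 = InitialData(s0=sc.init.s0, history=make_history("constant", sc.init.x0, 0.0))
        tr_0 = simulate(p0, init0, sc.horizon, SolverOptions(h=h))
        assert np.max(np.abs(tr_tau._s - tr_0._s)) <= 1e-9
        assert np.max(np.abs(tr_tau._x - tr_0._x)) <= 1e-9

    def test_zero_delay_matches_independent_ode_solver(self):
        from scipy.integrate import solve_ivp

        scn = sample_scenario(3, tau=0.0, min_mortality_frac=0.05)
        p, init = scn.params, scn.init
        tr = simulate(p, init, scn.horizon)

        from monodde import evaluate_mu

        def f(_, y):
            s, x = max(y[0], 0.0), y[1]
            m = evaluate_mu(p.growth, s)
            return [-m * x / p.gamma, m * x - (p.k1 + p.k2) * x]

        sol = solve_ivp(f, (0.0, tr.horizon), [init.s0, init.x0],
                        rtol=1e-11, atol=1e-14, method="DOP853")
        s1, x1 = tr.evaluate_at(tr.horizon)
        # mixed tolerance: atol = rtol * (gamma*s0 + x0), rtol = 1e-6
        scale = p.gamma * init.s0 + init.x0
        assert abs(s1 - sol.y[0, -1]) <= 1e-6 * max(abs(sol.y[0, -1]), scale)
        assert abs(x1 - sol.y[1, -1]) <= 1e-6 * max(abs(sol.y[1, -1]), scale)


class TestTrajectoryContract:
    def test_history_segment_and_convention_values(self, scenarios):
        sc = scenarios["delay-only"]
        traj = simulate(sc.params, sc.init, sc.horizon)
        tau = sc.params.tau
        # node matching on the history segment
        neg = traj.times < 0
        assert np.all(traj.s_values[neg] == sc.init.s0)
        expected = np.array([sc.init.history(t) for t in traj.times[neg]])
        np.testing.assert_allclose(traj.x_values[neg], expected, rtol=1e-12)
        # dense output convention on [-tau, 0)
        s, x = evaluate_at(traj, -tau / 2)
        assert s == sc.init.s0
        assert x == pytest.approx(float(sc.init.history(-tau / 2)), rel=1e-12)

    def test_dense_output_matches_grid_nodes_exactly(self, scenarios):
        sc = scenarios["combined-webb"]
        traj = simulate(sc.params, sc.init, sc.horizon)
        for i in (0, 17, len(traj._t) - 1):
            s, x = traj.evaluate_at(float(traj._t[i]))
            assert s == traj._s[i] and x == traj._x[i]

    def test_dense_output_respects_refined_resimulation(self, scenarios):
        # interpolated values should agree with a 10x finer grid's values
        sc = scenarios["delay-only"]
        coarse = simulate(sc.params, sc.init, sc.horizon)
        fine = simulate(sc.params, sc.init, sc.horizon,
                        SolverOptions(steps_per_delay=640))
        rng = np.random.default_rng(11)
        for t in rng.uniform(0, 0.9 * sc.horizon, size=30):
            sc_, xc = coarse.evaluate_at(float(t))
            sf, xf = fine.evaluate_at(float(t))
            # bounded by the coarse run's own O(h^4) global error (absolute
            # floor because s decays through many orders of magnitude)
            assert sc_ == pytest.approx(sf, rel=2e-5, abs=2e-6)
            assert xc == pytest.approx(xf, rel=2e-5, abs=2e-6)

    def test_out_of_range_time_rejected(self, scenarios):
        sc = scenarios["classical"]
        traj = simulate(sc.params, sc.init, sc.horizon)
        with pytest.raises(DomainError):
            traj.evaluate_at(traj.horizon + 1.0)

    def test_substrate_monotone_and_states_nonnegative(self):
        for seed in range(8):
            scn = sample_scenario(seed)
            traj = simulate(scn.params, scn.init, scn.horizon)
            assert np.all(np.diff(traj._s) <= 1e-9)
            assert np.all(traj._s >= 0) and np.all(traj._x >= 0)

    def test_depletion_clamp_freezes_substrate_at_zero(self, scenarios):
        sc = scenarios["fast-depletion"]
        traj = simulate(sc.params, sc.init, sc.horizon)
        ct = traj.meta["s_clamp_time"]
        assert ct is not None and 0 < ct < sc.horizon
        post = traj._t > ct
        assert np.all(traj._s[post] == 0.0)
        # biomass strictly decays once the nutrient is gone (k1 + k2 > 0)
        xp = traj._x[post]
        alive = xp > 0
        assert np.all(np.diff(xp[alive]) < 0)

    def test_csv_round_trip_and_stability(self, scenarios, tmp_path):
        sc = scenarios["classical"]
        traj = simulate(sc.params, sc.init, sc.horizon)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        traj.to_csv(p1)
        simulate(sc.params, sc.init, sc.horizon).to_csv(p2)
        assert p1.read_bytes() == p2.read_bytes()
        data = np.loadtxt(p1, delimiter=",", skiprows=1)
        np.testing.assert_array_equal(data[:, 0], traj.times)
        np.testing.assert_array_equal(data[:, 1], traj.s_values)

    def test_step_not_dividing_tau_is_adjusted(self):
        p = ModelParameters(growth=MONOD, gamma=1.0, k2=0.1, tau=1.0)
        init = InitialData(s0=5.0, history=make_history("constant", 0.1, 1.0))
        traj = simulate(p, init, 5.0, SolverOptions(h=0.3))
        assert traj.meta["h_adjusted_to_divide_tau"]
        n = traj.meta["steps_per_delay"]
        assert n * traj.meta["h"] == pytest.approx(p.tau, rel=1e-15)
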