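"""Deterministic two-compartment core: rate equations, solver, equilibria."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cscplasticity import (
    ModelParameters,
    PopulationState,
    Trajectory,
    fraction_positive,
    ode_rhs,
    solve_deterministic,
    steady_state_fraction,
)
from oracles import expm_solution

rates = st.floats(min_value=0.0, max_value=2.0, allow_nan=False)
counts = st.floats(min_value=0.0, max_value=1e4, allow_nan=False)


def params_from(r):
    return ModelParameters(
        alpha_S=r[0], delta_S=r[1], alpha_D=r[2], delta_D=r[3], k_SD=r[4], k_DS=r[5]
    )


class TestOdeRhs:
    @pytest.mark.parametrize(
        "state, kw, expected",
        [
            ((0.0, 0.0, 0.0), {}, (0.0, 0.0)),
            ((0.0, 0.0, 100.0), {"alpha_D": 0.5}, (0.0, 50.0)),
            (
                (0.0, 10.0, 90.0),
                dict(alpha_S=0.4, delta_S=0.1, alpha_D=0.5, delta_D=0.1, k_SD=0.05, k_DS=0.01),
                (3.4, 35.6),
            ),
        ],
    )
    def test_direct_substitution(self, state, kw, expected):
        base = dict(alpha_S=0, delta_S=0, alpha_D=0, delta_D=0, k_SD=0, k_DS=0)
        base.update(kw)
        got = ode_rhs(PopulationState(*state), ModelParameters(**base))
        assert got == pytest.approx(expected)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            PopulationState(0.0, -1.0, 5.0)
        with pytest.raises(ValueError):
            ModelParameters(-0.1, 0, 0, 0, 0, 0)

    @given(
        r=st.tuples(rates, rates, rates, rates, rates, rates),
        s1=st.tuples(counts, counts),
        s2=st.tuples(counts, counts),
        lam=st.floats(min_value=0.0, max_value=10.0),
    )
    def test_linearity(self, r, s1, s2, lam):
        """The rhs is additive and homogeneous in (S, D)."""
        p = params_from(r)

        def f(S, D):
            return np.array(ode_rhs(PopulationState(1.0, S, D), p))

        left = f(s1[0] + lam * s2[0], s1[1] + lam * s2[1])
        right = f(*s1) + lam * f(*s2)
        assert np.allclose(left, right, rtol=1e-12, atol=1e-9)


class TestSolveDeterministic:
    def test_frozen_system(self):
        p = ModelParameters(0, 0, 0, 0, 0, 0)
        traj = solve_deterministic(PopulationState(0, 5, 7), p, np.linspace(0, 10, 6))
        assert np.allclose(traj.S, 5.0) and np.allclose(traj.D, 7.0)

    def test_decoupled_exponential_growth(self):
        p = ModelParameters(alpha_S=0.3, delta_S=0, alpha_D=0.7, delta_D=0, k_SD=0, k_DS=0)
        t = np.linspace(0, 5, 11)
        traj = solve_deterministic(PopulationState(0, 2.0, 3.0), p, t)
        assert np.allclose(traj.S, 2.0 * np.exp(0.3 * t), rtol=1e-9)
        assert np.allclose(traj.D, 3.0 * np.exp(0.7 * t), rtol=1e-9)

    def test_matches_matrix_exponential_with_piecewise_rates(self):
        """Numerical integration equals expm per constant-rate segment."""
        rng = np.random.default_rng(7)
        times = np.linspace(0.0, 20.0, 9)
        for _ in range(30):
            r = rng.uniform(0, 2, 6)
            p = ModelParameters(
                *r[:5], k_DS=[[0.0, r[5]], [3.0, rng.uniform(0, 2)]]
            )
            init = PopulationState(0.0, rng.uniform(0, 100), rng.uniform(0, 100))
            traj = solve_deterministic(init, p, times)
            ref = expm_solution(init, p, times)
            got = np.column_stack([traj.S, traj.D])
            rel = np.abs(got - ref) / np.maximum(np.abs(ref), 1e-30)
            assert rel.max() < 1e-8

    def test_first_state_is_initial_condition(self, generic_params):
        init = PopulationState(1.0, 3.0, 4.0)
        traj = solve_deterministic(init, generic_params, [1.0, 2.0, 5.0])
        assert traj.S[0] == init.S and traj.D[0] == init.D and traj.t[0] == init.t

    def test_output_time_validation(self, generic_params):
        init = PopulationState(0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            solve_deterministic(init, generic_params, [0.0, 2.0, 2.0])
        with pytest.raises(ValueError):
            solve_deterministic(init, generic_params, [1.0, 2.0])


class TestFractionPositive:
    def test_point_values(self):
        traj = Trajectory([0.0, 1.0], [0.0, 50.0], [100.0, 50.0])
        assert fraction_positive(traj) == pytest.approx([0.0, 0.5])

    def test_extinct_population_is_flagged(self):
        traj = Trajectory([0.0, 1.0], [0.0, 1.0], [0.0, 1.0])
        with pytest.warns(RuntimeWarning):
            f = fraction_positive(traj)
        assert np.isnan(f[0]) and f[1] == pytest.approx(0.5)

    def test_matches_recomputation_on_scenario(self, hypoxia):
        t = np.arange(0.0, 8.5, 0.5)
        traj = solve_deterministic(
            PopulationState(0, 0, 1000.0), hypoxia.params, t
        )
        f = fraction_positive(traj)
        assert np.allclose(f, traj.S / (traj.S + traj.D))
        assert np.all((f >= 0) & (f <= 1))

    def test_fraction_dynamics(self, hypoxia):
        """df/dt = k_DS(1-f) - k_SD f + dg f(1-f) (finite differences)."""
        p = hypoxia.params
        dt = 1e-4
        t = np.arange(0.0, 8.0, dt)
        traj = solve_deterministic(PopulationState(0, 0, 1000.0), p, t)
        f = fraction_positive(traj)
        dg = (p.alpha_S - p.delta_S) - (p.alpha_D - p.delta_D)
        mid = (f[1:] + f[:-1]) / 2
        t_mid = (t[1:] + t[:-1]) / 2
        k_ds = np.array([p.k_DS_at(x) for x in t_mid])
        predicted = k_ds * (1 - mid) - p.k_SD * mid + dg * mid * (1 - mid)
        observed = np.diff(f) / dt
        # exclude the switch-day step, where the derivative jumps
        keep = np.abs(t_mid - 3.0) > dt
        assert np.max(np.abs(observed[keep] - predicted[keep])) < 1e-4


class TestSteadyStateFraction:
    def test_no_influx_and_outgrown(self):
        p = ModelParameters(alpha_S=0.2, delta_S=0.1, alpha_D=0.9, delta_D=0.1, k_SD=0.05, k_DS=0.0)
        assert steady_state_fraction(p) == pytest.approx(0.0)

    def test_symmetric_interconversion(self):
        p = ModelParameters(alpha_S=0.5, delta_S=0.1, alpha_D=0.5, delta_D=0.1, k_SD=0.3, k_DS=0.3)
        assert steady_state_fraction(p) == pytest.approx(0.5)

    def test_matches_long_time_integration(self, generic_params):
        f_star = steady_state_fraction(generic_params)
        traj = solve_deterministic(
            PopulationState(0, 0, 1.0), generic_params, [0.0, 200.0]
        )
        assert fraction_positive(traj)[-1] == pytest.approx(f_star, abs=1e-8)

    def test_monotone_in_dedifferentiation_rate(self):
        sweep = np.geomspace(1e-4, 1.0, 25)
        vals = [
            steady_state_fraction(
                ModelParameters(0.8, 0.1, 0.9, 0.1, 0.1, k_DS=float(k))
            )
            for k in sweep
        ]
        assert np.all(np.diff(vals) >= 0)

    def test_piecewise_schedule_rejected(self, hypoxia):
        with pytest.raises(ValueError, match="single-segment"):
            steady_state_fraction(hypoxia.params)

    def test_fraction_rises_monotonically_from_pure_negative_start(self, normoxia):
        """With S0 = 0 and dg <= 0 the fraction climbs towards f*."""
        t = np.arange(0.0, 30.0, 0.25)
        traj = solve_deterministic(
            PopulationState(0, 0, 1000.0), normoxia.params, t
        )
        f = fraction_positive(traj)
        assert np.all(np.diff(f) >= -1e-12)
        assert f[-1] <= steady_state_fraction(normoxia.params) + 1e-9


class TestModelParameters:
    def test_schedule_normalisation_and_lookup(self):
        p = ModelParameters(0.1, 0, 0.1, 0, 0.0, k_DS=[[0.0, 0.001], [3.0, 0.01]])
        assert p.k_DS_at(2.0) == 0.001
        assert p.k_DS_at(3.0) == 0.01
        assert p.k_DS_at(10.0) == 0.01
        assert not p.k_DS_constant
        assert p.switch_times() == (3.0,)

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            ModelParameters(0.1, 0, 0.1, 0, 0, k_DS=[[1.0, 0.01]])
        with pytest.raises(ValueError):
            ModelParameters(0.1, 0, 0.1, 0, 0, k_DS=[[0.0, 0.01], [0.0, 0.02]])
        with pytest.raises(ValueError):
            ModelParameters(0.1, 0, 0.1, 0, 0, k_DS=[[0.0, -0.01]])

    def test_roundtrip_dict(self, hypoxia):
        p = hypoxia.params
        assert ModelParameters.from_dict(p.as_dict()) == p
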