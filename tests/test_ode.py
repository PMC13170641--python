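"""Two-compartment model: pools, right-hand side, simulation, steady states."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

from parosc import (
    Cue,
    FeedbackSchedule,
    InadmissibleParameters,
    OdeParams,
    classify_quadrant,
    classify_stability,
    cytoplasmic_pools,
    default_dead_zone,
    find_steady_states,
    ode_rhs,
    simulate,
)
from parosc.ode import ode_jacobian, quadrant_attractors


class TestCytoplasmicPools:
    def test_empty_membrane_returns_full_pools(self):
        p = OdeParams()
        assert cytoplasmic_pools((0, 0, 0, 0), p) == (p.rhoA, p.rhoP)

    def test_pool_exhaustion_boundary(self):
        p = OdeParams()
        tot = 2 * p.rhoA / p.psi
        acyto, _ = cytoplasmic_pools((tot / 2, tot / 2, 0, 0), p)
        assert acyto == pytest.approx(0.0, abs=1e-12)

    def test_generic_value_matches_hand_evaluation(self):
        p = OdeParams(rhoA=3.0, rhoP=1.5, psi=0.7)
        state = (0.4, 1.1, 0.2, 0.9)
        acyto, pcyto = cytoplasmic_pools(state, p)
        assert acyto == pytest.approx(3.0 - 0.7 * (0.4 + 1.1) / 2)
        assert pcyto == pytest.approx(1.5 - 0.7 * (0.2 + 0.9) / 2)

    def test_negative_pool_raises(self):
        p = OdeParams(rhoA=0.1)
        with pytest.raises(InadmissibleParameters):
            cytoplasmic_pools((1.0, 1.0, 0, 0), p)


class TestRhs:
    def test_empty_membrane_only_attachment(self):
        p = OdeParams()
        d = ode_rhs((0, 0, 0, 0), 0.0, p)
        assert d[0] == pytest.approx(p.kon * p.rhoA)
        assert d[1] == pytest.approx(p.kon * p.rhoA)
        assert d[2] == pytest.approx(p.kon * p.rhoP)
        assert d[3] == pytest.approx(p.kon * p.rhoP)

    def test_symmetric_state_exchange_vanishes(self):
        p = OdeParams(kAP=2.0, kPA=2.0)
        d = ode_rhs((0.5, 0.5, 0.3, 0.3), 0.0, p)
        assert d[0] == pytest.approx(d[1])
        assert d[2] == pytest.approx(d[3])

    def test_schedule_multiplier_halves_kap_term(self):
        p = OdeParams(kAP=4.0, kPA=1.0)
        state = (0.4, 0.6, 0.5, 0.2)
        half = FeedbackSchedule.constant(0.5)
        d_half = ode_rhs(state, 1.0, p, schedule=half)
        d_equiv = ode_rhs(state, 1.0, replace(p, kAP=2.0))
        np.testing.assert_allclose(d_half, d_equiv, rtol=1e-12)

    def test_generic_hand_evaluation(self):
        p = OdeParams(Dtilde=0.2, kon=0.8, koff=1.1, kAP=2.0, kPA=3.0,
                      alpha=2, beta=2, rhoA=2.0, rhoP=2.5, psi=0.9)
        Aa, Ap, Pa, Pp = 0.3, 0.7, 0.4, 0.1
        acyto = 2.0 - 0.9 * (0.3 + 0.7) / 2
        pcyto = 2.5 - 0.9 * (0.4 + 0.1) / 2
        expect_dAa = 0.2 * (Ap - Aa) + 0.8 * acyto - 1.1 * Aa - 2.0 * Pa**2 * Aa
        d = ode_rhs((Aa, Ap, Pa, Pp), 0.0, p)
        assert d[0] == pytest.approx(expect_dAa, rel=1e-12)

    def test_cue_conserves_total_a(self):
        p = OdeParams()
        cue = Cue(rate=0.7, t_on=0.0, t_off=10.0)
        d_on = ode_rhs((0.3, 0.5, 0.2, 0.2), 5.0, p, cue=cue)
        d_off = ode_rhs((0.3, 0.5, 0.2, 0.2), 15.0, p, cue=cue)
        assert d_on[0] + d_on[1] == pytest.approx(d_off[0] + d_off[1], rel=1e-12)
        assert d_on[0] - d_off[0] == pytest.approx(0.7 * 0.5, rel=1e-12)

    def test_jacobian_matches_finite_differences(self):
        p = OdeParams(kAP=5.0, kPA=3.0)
        y = np.array([0.3, 0.6, 0.4, 0.2])
        J = ode_jacobian(y, p, 0.8, 1.0, 0.2)
        eps = 1e-7
        from parosc.ode import _rhs_values

        for j in range(4):
            e = np.zeros(4)
            e[j] = eps
            num = (_rhs_values(y + e, p, 0.8, 1.0, 0.2)
                   - _rhs_values(y - e, p, 0.8, 1.0, 0.2)) / (2 * eps)
            np.testing.assert_allclose(J[:, j], num, rtol=1e-5, atol=1e-7)


class TestSimulate:
    def test_linear_limit_converges_to_uniform_balance(self):
        p = OdeParams(kAP=0.0, kPA=0.0)
        traj = simulate([0.1, 0.9, 0.4, 0.0], p, (0, 80))
        a_star = p.kon * p.rhoA / (p.koff + p.kon * p.psi)
        p_star = p.kon * p.rhoP / (p.koff + p.kon * p.psi)
        np.testing.assert_allclose(traj.final_state, [a_star, a_star, p_star, p_star],
                                   atol=1e-8)

    def test_polarized_state_remains_polarized_at_high_feedback(
            self, high_params, high_attractors):
        y0 = high_attractors["POLARIZED_AP"]
        traj = simulate(y0, high_params, (0, 100))
        dz = default_dead_zone(high_params)
        assert classify_quadrant(traj.final_state, dz) == "POLARIZED_AP"
        np.testing.assert_allclose(traj.final_state, y0, atol=1e-6)

    def test_mass_conservation_along_trajectory(self, high_params):
        traj = simulate([0.5, 0.2, 0.1, 0.8], high_params, (0, 50))
        pools = traj.pools()
        rhoA = high_params.psi * (traj.states[:, 0] + traj.states[:, 1]) / 2 + pools[:, 0]
        np.testing.assert_allclose(rhoA, high_params.rhoA, rtol=1e-9)

    def test_nonnegativity(self, high_params):
        traj = simulate([1.2, 0.0, 0.0, 1.2], high_params, (0, 50))
        assert traj.states.min() >= -1e-9

    def test_swap_symmetry(self, high_params):
        """Under symmetric rates, swapping (A<->P, a<->p) swaps the trajectory."""
        y0 = np.array([0.9, 0.1, 0.2, 0.7])
        swap = np.array([0.7, 0.2, 0.1, 0.9])  # (Pp, Pa, Ap, Aa)
        t1 = simulate(y0, high_params, (0, 30))
        t2 = simulate(swap, high_params, (0, 30))
        np.testing.assert_allclose(t1.states[:, [0, 1, 2, 3]],
                                   t2.states[:, [3, 2, 1, 0]], atol=1e-6)

    def test_constant_schedule_and_zero_cue_reproduce_bare_model(self, high_params):
        y0 = [0.4, 0.3, 0.2, 0.6]
        bare = simulate(y0, high_params, (0, 20))
        dressed = simulate(y0, high_params, (0, 20),
                           schedule=FeedbackSchedule.constant(1.0),
                           cue=Cue(0.0))
        np.testing.assert_allclose(bare.states, dressed.states, atol=1e-10)


class TestSteadyStates:
    def test_high_feedback_structure(self, high_params):
        """Four stable states (one per quadrant) plus a central non-stable one."""
        fps = find_steady_states(high_params)
        stable = [f for f in fps if f.is_stable]
        assert len(stable) == 4
        dz = default_dead_zone(high_params)
        labels = {classify_quadrant(f.state, dz) for f in stable}
        assert labels == {"UNIFORM_A", "UNIFORM_P", "POLARIZED_AP", "POLARIZED_PA"}
        central = [f for f in fps if not f.is_stable
                   and np.allclose(f.state, f.state[0], atol=1e-6)]
        assert len(central) == 1

    def test_low_feedback_single_uniform_a(self, low_params):
        fps = find_steady_states(low_params)
        stable = [f for f in fps if f.is_stable]
        assert len(stable) == 1
        dz = default_dead_zone(low_params)
        assert classify_quadrant(stable[0].state, dz) == "UNIFORM_A"

    def test_no_feedback_single_analytic_point(self):
        p = OdeParams(kAP=0.0, kPA=0.0)
        fps = find_steady_states(p, grid_density=3)
        assert len(fps) == 1
        assert fps[0].is_stable
        a_star = p.kon * p.rhoA / (p.koff + p.kon * p.psi)
        np.testing.assert_allclose(fps[0].state, [a_star] * 2 + [a_star] * 2, atol=1e-8)

    def test_no_feedback_eigenvalues_all_real_negative(self):
        p = OdeParams(kAP=0.0, kPA=0.0)
        a_star = p.kon * p.rhoA / (p.koff + p.kon * p.psi)
        label, re = classify_stability([a_star] * 4, p)
        assert label == "stable"
        assert np.all(re < 0)

    def test_symmetric_fixed_point_eigenvalues_swap_invariant(self, high_params):
        fps = find_steady_states(high_params)
        for fp in fps:
            swapped = fp.state[[3, 2, 1, 0]]
            _, re1 = classify_stability(fp.state, high_params)
            _, re2 = classify_stability(swapped, high_params)
            np.testing.assert_allclose(np.sort(re1), np.sort(re2), atol=1e-7)

    def test_stable_count_monotone_as_kap_lowered(self, high_params):
        counts = []
        for kap in (20.0, 12.0, 8.0, 1.0, 0.1):
            p = replace(high_params, kAP=kap)
            counts.append(sum(f.is_stable for f in find_steady_states(p)))
        assert counts[0] == 4 and counts[-1] == 1
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_root_finder_agrees_with_brute_force_integration(self, high_params):
        """Long-time integration endpoints land on enumerated fixed points."""
        fps = [f.state for f in find_steady_states(high_params) if f.is_stable]
        grid = np.linspace(0.05, 1.2, 3)
        for aa in grid:
            for pp in grid:
                traj = simulate([aa, aa / 2, pp / 2, pp], high_params, (0, 400))
                d = min(np.linalg.norm(traj.final_state - f) for f in fps)
                assert d < 1e-4


class TestQuadrant:
    def test_uniform_a(self):
        assert classify_quadrant((1, 1, 0, 0), 0.1) == "UNIFORM_A"

    def test_origin_is_undefined(self):
        assert classify_quadrant((0, 0, 0, 0), 0.1) == "UNDEFINED"

    def test_polarized_ap(self):
        assert classify_quadrant((1, 0, 0, 1), 0.1) == "POLARIZED_AP"

    @given(st.lists(st.floats(0, 3, allow_nan=False), min_size=4, max_size=4),
           st.floats(1e-6, 0.5))
    @settings(max_examples=50, deadline=None)
    def test_label_depends_only_on_difference_signs(self, state, dz):
        label = classify_quadrant(state, dz)
        da = state[0] - state[2]
        dp = state[1] - state[3]
        if abs(da) <= dz or abs(dp) <= dz:
            assert label == "UNDEFINED"
        elif da > 0 and dp > 0:
            assert label == "UNIFORM_A"
        elif da < 0 and dp < 0:
            assert label == "UNIFORM_P"


@pytest.fixture(scope="module")
def table(high_params):
    from parosc import run_state_switching_matrix

    return run_state_switching_matrix(high_params)


class TestSwitchingMatrix:
    def test_constant_high_converts_only_uniform_a(self, table):
        row = table["constant_high"]
        assert row["UNIFORM_A"] == "POLARIZED_AP"
        assert row["UNIFORM_P"] == "UNIFORM_P"
        assert row["POLARIZED_PA"] == "POLARIZED_PA"
        assert row["POLARIZED_AP"] == "POLARIZED_AP"

    def test_oscillating_converts_all_initials(self, table):
        assert all(v == "POLARIZED_AP" for v in table["oscillating"].values())

    def test_constant_low_cannot_hold_polarity(self, table):
        assert all(v == "UNIFORM_A" for v in table["constant_low"].values())
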