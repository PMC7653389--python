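"""Solver oracles, rate-constant recovery, ODE consistency, gating."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import thermoreg as tr
from thermoreg.model import ModelError, SystemState

from conftest import chain2_activity_closed_form, chain2_closed_form


class TestOdds:
    def test_unit_quotient(self):
        net, state = tr.build_network(
            [("R1", {"A": -1, "B": 1})],
            [("A", True, 1e3), ("B", False, 1e3)],
        )
        thermo = tr.ThermoSpec([2.0])
        Q, fwd, rev = tr.thermodynamic_odds(state, net, thermo)
        assert Q[0] == pytest.approx(1.0)
        assert fwd[0] == pytest.approx(2.0)
        assert rev[0] == pytest.approx(0.5)

    def test_equilibrium_has_unit_odds_and_zero_affinity(self):
        net, state = tr.build_network(
            [("R1", {"A": -1, "B": 1})],
            [("A", True, 1e3), ("B", False, 2e3)],
        )
        thermo = tr.ThermoSpec([2.0])
        _, fwd, _ = tr.thermodynamic_odds(state, net, thermo)
        assert fwd[0] == pytest.approx(1.0)
        sol = tr.solve_steady_state(net, thermo, state)
        assert sol.affinities[0] == pytest.approx(0.0, abs=1e-9)

    def test_reverse_is_exact_reciprocal(self, full_model, full_solution):
        np.testing.assert_allclose(
            full_solution.reverse_odds, 1.0 / full_solution.forward_odds, rtol=0
        )


class TestNetFlux:
    @pytest.mark.parametrize(
        "fwd, alpha, expected",
        [(2.0, 1.0, 1.5), (2.0, 0.0, 0.0), (1.0, 1.0, 0.0), (4.0, 0.5, 1.875)],
    )
    def test_values(self, fwd, alpha, expected):
        J = tr.net_flux(np.array([fwd]), np.array([1.0 / fwd]), np.array([alpha]))
        assert J[0] == pytest.approx(expected)

    def test_rejects_out_of_range_activity(self):
        with pytest.raises(ModelError):
            tr.net_flux(np.array([2.0]), np.array([0.5]), np.array([1.5]))


class TestSolveSteadyState:
    def test_canonical_chain(self, toy_chain, toy_solution):
        net, _, _ = toy_chain
        assert toy_solution.converged
        assert toy_solution.concentrations[1] == pytest.approx(2.0, abs=1e-8)
        np.testing.assert_allclose(toy_solution.forward_odds, [2.0, 2.0], atol=1e-8)
        np.testing.assert_allclose(toy_solution.net_fluxes, [1.5, 1.5], atol=1e-8)

    def test_activity_scaled_chain(self, toy_chain):
        net, state, thermo = toy_chain
        sol = tr.solve_steady_state(
            net, thermo, state.with_activities(np.array([0.25, 1.0]))
        )
        assert sol.concentrations[1] == pytest.approx(
            chain2_activity_closed_form(0.25), abs=1e-8
        )

    @given(
        K1=st.floats(0.1, 10.0),
        K2=st.floats(0.1, 10.0),
        B0=st.floats(0.5, 20.0),
        B2=st.floats(0.5, 20.0),
    )
    @settings(max_examples=30, deadline=None)
    def test_two_chain_matches_closed_form(self, K1, K2, B0, B2):
        net, state, thermo = tr.generate_toy_pathway("chain", 2, (K1, K2), (B0, B2))
        sol = tr.solve_steady_state(net, thermo, state)
        assert sol.converged
        assert sol.concentrations[1] == pytest.approx(
            chain2_closed_form(K1, K2, B0, B2), rel=1e-8
        )

    def test_three_chain_equal_odds(self):
        # with unit K the steady state equalises all odds: o^3 = B0/B3
        net, state, thermo = tr.generate_toy_pathway("chain", 3, None, (8.0, 1.0))
        sol = tr.solve_steady_state(net, thermo, state)
        np.testing.assert_allclose(sol.forward_odds, [2.0, 2.0, 2.0], atol=1e-8)
        np.testing.assert_allclose(sol.concentrations[1:3], [4.0, 2.0], atol=1e-8)

    def test_mass_balance_at_convergence(self, full_model, full_solution):
        net, _, _ = full_model
        assert full_solution.converged
        assert full_solution.mass_balance_inf_norm <= 1e-8

    def test_activity_scale_invariance(self, toy_chain):
        net, state, thermo = toy_chain
        a = tr.solve_steady_state(net, thermo, state)
        b = tr.solve_steady_state(
            net, thermo, state.with_activities(0.3 * state.activities)
        )
        np.testing.assert_allclose(b.concentrations, a.concentrations, rtol=1e-7)
        np.testing.assert_allclose(b.net_fluxes, 0.3 * a.net_fluxes, rtol=1e-7)

    def test_closed_system_relaxes_to_equilibrium(self):
        net, state = tr.build_network(
            [("R1", {"A": -1, "B": 1}), ("R2", {"B": -1, "C": 1})],
            [("A", False, 1e3), ("B", False, 1e3), ("C", False, 1e3)],
            check_determined=False,
        )
        thermo = tr.ThermoSpec([2.0, 0.5])
        sol = tr.solve_steady_state(net, thermo, state)
        np.testing.assert_allclose(sol.forward_odds, [1.0, 1.0], atol=1e-8)
        np.testing.assert_allclose(sol.net_fluxes, [0.0, 0.0], atol=1e-8)
        np.testing.assert_allclose(sol.delta_g, [0.0, 0.0], atol=1e-8)

    def test_boltzmann_distribution_at_equilibrium(self):
        # closed system with supplied potentials: n_i ∝ exp(-mu_i / R T)
        mu = np.array([1.0, -2.0, 0.5])  # kJ/mol for A, B, C
        net, state = tr.build_network(
            [("R1", {"A": -1, "B": 1}), ("R2", {"B": -1, "C": 1})],
            [("A", False, 1e3), ("B", False, 1e3), ("C", False, 1e3)],
            check_determined=False,
        )
        thermo = tr.ThermoSpec.from_potentials(net, mu)
        sol = tr.solve_steady_state(net, thermo, state)
        boltz = np.exp(-mu / thermo.rt)
        ratio = sol.concentrations / boltz
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-8)

    def test_null_direction_reported_for_untouched_species(self, toy_chain):
        net, state, thermo = toy_chain
        sol = tr.solve_steady_state(
            net, thermo, state.with_activities(np.array([0.0, 0.0]))
        )
        assert "X1" in sol.null_direction_report

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_branch_flux_stoichiometry(self, seed):
        """Lower glycolysis and the TCA cycle carry twice the upper-glycolysis
        molar flux because FBA splits one hexose into two trioses."""
        net, state = tr.build_ecoli_pathway("glycolysis_tca")
        thermo = tr.generate_synthetic_thermo(net, 260.0, seed=seed)
        sol = tr.solve_steady_state(net, thermo, state)
        assert sol.converged
        j = {r: sol.net_fluxes[i] for i, r in enumerate(net.reaction_ids)}
        assert abs(j["GAPD"]) == pytest.approx(abs(j["FBA"]) + abs(j["TPI"]), rel=1e-6)
        assert j["CSM"] == pytest.approx(j["PDH"], rel=1e-6)


class TestRateConstants:
    def test_toy_chain_back_calculation(self, toy_chain, toy_solution):
        net, _, thermo = toy_chain
        rc = tr.back_calculate_rate_constants(toy_solution, net, thermo)
        np.testing.assert_allclose(rc.forward, [0.75, 1.5], atol=1e-10)
        np.testing.assert_allclose(rc.reverse, [0.75, 1.5], atol=1e-10)

    def test_ratio_equals_equilibrium_constant(self):
        net, state, thermo = tr.generate_toy_pathway("chain", 2, (5.0, 1.0), (4.0, 1.0))
        sol = tr.solve_steady_state(net, thermo, state)
        rc = tr.back_calculate_rate_constants(sol, net, thermo)
        assert rc.forward[0] / rc.reverse[0] == pytest.approx(5.0, rel=1e-8)

    def test_mass_action_reproduces_flux(self, toy_chain, toy_solution):
        net, _, thermo = toy_chain
        rc = tr.back_calculate_rate_constants(toy_solution, net, thermo)
        n = toy_solution.concentrations
        nu_f, nu_r = net.forward_exponents, net.reverse_exponents
        J = rc.forward * np.prod(n[:, None] ** nu_f, axis=0) - rc.reverse * np.prod(
            n[:, None] ** nu_r, axis=0
        )
        np.testing.assert_allclose(J, toy_solution.net_fluxes, rtol=1e-8)

    def test_near_equilibrium_reported(self):
        net, state = tr.build_network(
            [("R1", {"A": -1, "B": 1})], [("A", True, 1e3), ("B", False, None)]
        )
        thermo = tr.ThermoSpec([1.0])
        sol = tr.solve_steady_state(net, thermo, state)  # single reaction equilibrates
        rc = tr.back_calculate_rate_constants(sol, net, thermo)
        assert rc.skipped == ("R1",)
        assert np.isnan(rc.forward[0])


class TestMassActionSimulation:
    def test_fixed_point_stays_fixed(self, toy_chain, toy_solution):
        net, state, thermo = toy_chain
        rc = tr.back_calculate_rate_constants(toy_solution, net, thermo)
        start = SystemState(toy_solution.concentrations, state.activities)
        traj = tr.simulate_mass_action(net, rc, start, duration=10.0)
        assert traj.success
        np.testing.assert_allclose(
            traj.concentrations[-1], toy_solution.concentrations, atol=1e-6
        )

    def test_perturbed_start_converges_to_optimum(self, toy_chain, toy_solution):
        net, state, thermo = toy_chain
        rc = tr.back_calculate_rate_constants(toy_solution, net, thermo)
        traj = tr.simulate_mass_action(net, rc, state, duration=50.0)
        assert traj.concentrations[-1][1] == pytest.approx(2.0, abs=1e-6)

    def test_closed_system_symmetric_equilibrium(self):
        net, state = tr.build_network(
            [("R1", {"A": -1, "B": 1})],
            [("A", False, 1.5e3), ("B", False, 0.5e3)],
            check_determined=False,
        )
        rc = tr.RateConstants(np.array([1.0]), np.array([1.0]))
        traj = tr.simulate_mass_action(net, rc, state, duration=50.0)
        np.testing.assert_allclose(traj.concentrations[-1], [1.0, 1.0], atol=1e-6)
        # total mass conserved along the trajectory
        np.testing.assert_allclose(traj.concentrations.sum(axis=1), 2.0, atol=1e-6)


class TestGatedKinetics:
    def test_gated_intermediate(self, toy_chain, toy_solution):
        net, state, thermo = toy_chain
        rc = tr.back_calculate_rate_constants(toy_solution, net, thermo)
        sol = tr.gated_steady_state(net, rc, np.array([0.5, 1.0]), state, thermo)
        assert sol.converged
        assert sol.concentrations[1] == pytest.approx(1.6, abs=1e-8)

    def test_unit_gate_recovers_ungated_state(self, toy_chain, toy_solution):
        net, state, thermo = toy_chain
        rc = tr.back_calculate_rate_constants(toy_solution, net, thermo)
        sol = tr.gated_steady_state(net, rc, np.array([1.0, 1.0]), state, thermo)
        assert sol.concentrations[1] == pytest.approx(2.0, abs=1e-8)

    def test_odds_expression_independent_of_gate(self, toy_chain, toy_solution):
        """K Q^-1 built from gated rates (g k1 nA)/(g k-1 nB) cancels g, so
        at fixed concentrations the odds never see the gating factor."""
        net, state, thermo = toy_chain
        rc = tr.back_calculate_rate_constants(toy_solution, net, thermo)
        n = toy_solution.concentrations
        nu_f, nu_r = net.forward_exponents, net.reverse_exponents
        for g in (1.0, 0.5, 0.01):
            fwd_rate = g * rc.forward * np.prod(n[:, None] ** nu_f, axis=0)
            rev_rate = g * rc.reverse * np.prod(n[:, None] ** nu_r, axis=0)
            np.testing.assert_allclose(
                fwd_rate / rev_rate, toy_solution.forward_odds, rtol=1e-10
            )
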