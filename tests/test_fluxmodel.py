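"""Stoichiometric network construction, flux solving, and ATP accounting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fermbal.balances import carbon_recovery, electron_recovery
from fermbal.fluxmodel import (
    REFERENCE_GLUCOSE_YIELDS,
    Reaction,
    Scenario,
    atp_ledger,
    build_network,
    check_network,
    compare_scenarios,
    minimum_norm_solve,
    network_from_dict,
    network_to_dict,
    solve_fluxes,
)


class TestNetworkConstruction:
    def test_hydm_scenario_excludes_hydabc(self):
        names = {r.name for r in build_network(Scenario(hydrogenase="hydm"))}
        assert "hydm" in names and "hydabc" not in names

    def test_hydabc_draws_equal_electrons_from_nadh_and_ferredoxin(self):
        network = build_network(Scenario(hydrogenase="hydabc"))
        hyd = next(r for r in network if r.name == "hydabc")
        assert hyd.coefficient("nadh") == hyd.coefficient("fdred") == -0.5

    def test_every_reaction_carbon_and_electron_balanced(self):
        for hydrogenase in ("hydm", "hydabc", "none"):
            check_network(build_network(Scenario(hydrogenase=hydrogenase)))

    def test_unbalanced_reaction_rejected(self):
        with pytest.raises(ValueError, match="unbalanced"):
            check_network([Reaction("broken", {"glucose": -1, "acetate": 1})])

    def test_invalid_scenario_rejected(self):
        with pytest.raises(ValueError):
            Scenario(hydrogenase="hydX")
        with pytest.raises(ValueError):
            Scenario(h_per_atp=0.0)

    def test_declarative_round_trip(self):
        scenario = Scenario(hydrogenase="hydabc")
        network = build_network(scenario)
        back, sc = network_from_dict(network_to_dict(network, scenario))
        assert sc == scenario
        assert [r.name for r in back] == [r.name for r in network]
        assert all(dict(a.stoichiometry) == dict(b.stoichiometry) for a, b in zip(back, network))


class TestReferenceSolutions:
    def test_homoacetogenic_four_atp_by_slp(self):
        """Complete conversion of glucose to 3 acetate yields 4 ATP/hexose
        by substrate-level phosphorylation (2 pyruvate kinase + 2 acetate
        kinase; the WLP acetate is ATP-neutral)."""
        scenario = Scenario(hydrogenase="none")
        sol = solve_fluxes(build_network(scenario), {"acetate": 3}, scenario)
        assert sol.feasible
        assert sol.atp_slp == pytest.approx(4.0, abs=1e-9)
        # the WLP runs once and is fed by PFL-derived formate
        assert sol.fluxes["wlp"] == pytest.approx(1.0, abs=1e-9)
        assert sol.fluxes["pfl"] == pytest.approx(1.0, abs=1e-9)

    def test_homolactic_two_atp_all_nodes_closed(self):
        scenario = Scenario(hydrogenase="none")
        sol = solve_fluxes(build_network(scenario), {"lactate": 2}, scenario)
        assert sol.feasible
        assert sol.atp_net == pytest.approx(2.0, abs=1e-9)
        assert sol.max_residual < 1e-9

    def test_hydm_scenario_net_atp(self):
        scenario = Scenario(hydrogenase="hydm")
        sol = solve_fluxes(build_network(scenario), REFERENCE_GLUCOSE_YIELDS, scenario)
        assert sol.feasible
        assert sol.atp_net == pytest.approx(3.05, abs=0.02)
        # ferredoxin-only H2 production leaves nothing for Rnf
        assert sol.fluxes["rnf"] == pytest.approx(0.0, abs=1e-9)

    def test_hydabc_scenario_net_atp(self):
        scenario = Scenario(hydrogenase="hydabc")
        sol = solve_fluxes(build_network(scenario), REFERENCE_GLUCOSE_YIELDS, scenario)
        assert sol.feasible
        assert sol.atp_net == pytest.approx(3.15, abs=0.02)
        assert sol.atp_chemiosmotic > 0

    def test_scenario_comparison_prefers_bifurcating_hydrogenase(self):
        sols = compare_scenarios(REFERENCE_GLUCOSE_YIELDS)
        assert sols["hydabc"].atp_net > sols["hydm"].atp_net

    def test_no_h2_makes_scenarios_identical(self):
        # electron-closed yields with zero H2: the hydrogenase carries no
        # flux, so the scenarios coincide exactly
        yields = {"acetate": 1.25, "succinate": 0.75, "lactate": 0.20,
                  "formate": 0.55, "H2": 0.0}
        sols = compare_scenarios(yields)
        assert sols["hydm"].feasible and sols["hydabc"].feasible
        assert sols["hydabc"].atp_net == pytest.approx(sols["hydm"].atp_net, abs=1e-9)
        assert sols["hydm"].fluxes["hydm"] == pytest.approx(0.0, abs=1e-9)

    def test_scenario_gap_proportional_to_h2_yield(self):
        # two electron-closed yield sets differing only in how much of the
        # reduced ferredoxin leaves as H2 (0.4 vs 0.8 per glucose)
        base = compare_scenarios(REFERENCE_GLUCOSE_YIELDS)
        high_h2 = compare_scenarios(
            {"acetate": 1.15, "succinate": 0.90, "lactate": 0.05,
             "formate": 0.0, "H2": 0.80}
        )
        gap1 = base["hydabc"].atp_net - base["hydm"].atp_net
        gap2 = high_h2["hydabc"].atp_net - high_h2["hydm"].atp_net
        assert gap1 == pytest.approx(0.40 / 2 * 2.0 / 3.6, abs=1e-9)
        assert gap2 == pytest.approx(2.0 * gap1, abs=1e-9)


class TestAtpLedger:
    def test_chemiosmotic_from_rnf_flux(self):
        slp, chemi, net = atp_ledger({"rnf": 1.8})
        assert chemi == pytest.approx(1.0)
        assert net == pytest.approx(slp + chemi)

    def test_zero_rnf_zero_chemiosmotic(self):
        assert atp_ledger({"rnf": 0.0})[1] == 0.0

    def test_unit_ferredoxin_through_rnf(self):
        assert atp_ledger({"rnf": 1.0})[1] == pytest.approx(2.0 / 3.6)

    def test_slp_sums_kinase_fluxes(self):
        slp, _, _ = atp_ledger(
            {"pyruvate_kinase": 1.1, "pep_carboxykinase": 0.9, "acetate_kinase": 1.05}
        )
        assert slp == pytest.approx(3.05)

    def test_ledger_invariant_under_zero_weight_cycle(self):
        """Adding a flux cycle that carries no ATP-forming reaction and no
        translocation leaves the ledger unchanged."""
        scenario = Scenario(hydrogenase="hydm")
        sol = solve_fluxes(build_network(scenario), REFERENCE_GLUCOSE_YIELDS, scenario)
        perturbed = dict(sol.fluxes)
        for name in ("malate_dehydrogenase", "fumarase"):  # interior chain only
            perturbed[name] += 0.37
        assert atp_ledger(perturbed, scenario) == atp_ledger(sol.fluxes, scenario)


class TestSolverProperties:
    def test_all_nodes_balance_to_1e9(self):
        for hydrogenase in ("hydm", "hydabc"):
            scenario = Scenario(hydrogenase=hydrogenase)
            sol = solve_fluxes(build_network(scenario), REFERENCE_GLUCOSE_YIELDS, scenario)
            assert sol.max_residual < 1e-9

    def test_irreversible_fluxes_nonnegative(self):
        scenario = Scenario(hydrogenase="hydm")
        network = build_network(scenario)
        sol = solve_fluxes(network, REFERENCE_GLUCOSE_YIELDS, scenario)
        reversible = {r.name for r in network if r.reversible}
        for name, v in sol.fluxes.items():
            if name not in reversible and name not in ("ex_co2", "ex_h2o"):
                assert v >= -1e-9, name

    def test_exchange_fluxes_rebalance_through_recovery_functions(self):
        """Solver output closes carbon and electrons exactly when CO2 and
        water flows are put back on their sides of the balance."""
        scenario = Scenario(hydrogenase="hydm")
        sol = solve_fluxes(build_network(scenario), REFERENCE_GLUCOSE_YIELDS, scenario)
        co2_net = sol.fluxes["ex_co2"]  # positive = net CO2 output
        consumed = {"glucose": 1.0}
        formed = {k if k != "H2" else "H2": v for k, v in REFERENCE_GLUCOSE_YIELDS.items()}
        if co2_net >= 0:
            formed["CO2"] = co2_net
        else:
            consumed["CO2"] = -co2_net
        assert carbon_recovery(consumed, formed, include_co2=True) == pytest.approx(100.0, abs=1e-6)
        assert electron_recovery(consumed, formed, include_co2=True) == pytest.approx(100.0, abs=1e-6)

    def test_increasing_lactate_never_increases_net_atp(self):
        """Along an electron-closed family that diverts pyruvate from the
        acetate routes to lactate, net ATP falls monotonically (each
        lactate forfeits one acetate-kinase ATP): atp_net = 3.1 - y_lac."""
        nets = []
        for lac in (0.0, 0.05, 0.10, 0.20):
            w = (0.2 - lac) / 1.5  # WLP flux that closes NADH at this lactate
            yields = {
                "acetate": 1.1 - lac + w,
                "succinate": 0.90,
                "lactate": lac,
                "formate": 0.5 - w,
                "H2": 0.40,
            }
            scenario = Scenario(hydrogenase="hydm")
            sol = solve_fluxes(build_network(scenario), yields, scenario)
            assert sol.feasible
            nets.append(sol.atp_net)
            assert sol.atp_net == pytest.approx(3.1 - lac, abs=1e-9)
        assert all(a > b for a, b in zip(nets, nets[1:]))

    def test_infeasible_measurements_flagged_with_node_residuals(self):
        # H2 reported but no hydrogenase in the scenario
        scenario = Scenario(hydrogenase="none")
        sol = solve_fluxes(build_network(scenario), {"acetate": 2.0, "H2": 1.0}, scenario)
        assert not sol.feasible
        assert abs(sol.residuals["h2"]) > 0.1

    def test_unknown_product_rejected(self):
        scenario = Scenario()
        with pytest.raises(ValueError, match="butyrate"):
            solve_fluxes(build_network(scenario), {"butyrate": 1.0}, scenario)

    @given(st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_minimum_norm_matches_pseudoinverse_oracle(self, seed):
        """On small unconstrained systems (<= 8 reactions) the solver must
        return the SVD pseudoinverse minimum-norm solution."""
        rng = np.random.default_rng(seed)
        m, n = rng.integers(2, 7), rng.integers(2, 9)
        A = rng.standard_normal((m, n))
        b = A @ rng.standard_normal(n)  # consistent system
        lb = np.full(n, -np.inf)
        v, residual = minimum_norm_solve(A, b, lb)
        oracle = np.linalg.pinv(A) @ b
        np.testing.assert_allclose(v, oracle, atol=1e-9)
        assert np.max(np.abs(residual)) < 1e-9

    def test_bounded_solve_respects_nonnegativity(self):
        # unconstrained optimum has a negative component; bounded must not
        A = np.array([[1.0, 1.0]])
        b = np.array([1.0])
        v, residual = minimum_norm_solve(A, b, np.array([0.4, 0.4]))
        assert np.all(v >= 0.4 - 1e-12)
        assert np.max(np.abs(residual)) < 1e-7

    def test_max_atp_objective_at_least_min_norm(self):
        scenario = Scenario(hydrogenase="hydabc")
        network = build_network(scenario)
        a = solve_fluxes(network, REFERENCE_GLUCOSE_YIELDS, scenario)
        b = solve_fluxes(network, REFERENCE_GLUCOSE_YIELDS, scenario, objective="max_atp")
        assert b.atp_net >= a.atp_net - 1e-6
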