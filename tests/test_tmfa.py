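"""FBA, the thermodynamic MILP, and flux variability."""

import itertools
import math

import numpy as np
import pytest

from oracle import EnumOracle
from thermoflux.model_io import Metabolite, MetabolicNetwork, Reaction, ThermoTable
from thermoflux.synthetic_data import FixtureSpec, make_network_fixture, random_fixture
from thermoflux.thermo import ThermoConfig, assemble_reaction_thermo, build_lumped_reactions
from thermoflux.tmfa import (
    build_tmfa,
    flux_variability,
    mass_balance_residual,
    second_law_violations,
    solve_fba,
    solve_tmfa,
)

CFG = ThermoConfig()


def chain_network(uptake=5.0):
    mets = [Metabolite("A"), Metabolite("B")]
    rxns = [
        Reaction("EX_A", {"A": 1.0}, 0.0, uptake),
        Reaction("R1", {"A": -1.0, "B": 1.0}, 0.0, 100.0),
        Reaction("EX_B", {"B": -1.0}, 0.0, 100.0, objective_coeff=1.0),
    ]
    return MetabolicNetwork(mets, rxns)


def build_problem(net, table, config=CFG, **kwargs):
    thermo = assemble_reaction_thermo(net, table, config)
    lumps, _ = build_lumped_reactions(net, thermo, table, config)
    return build_tmfa(net, thermo, lumps, config, **kwargs)


class TestFba:
    def test_chain_objective_equals_uptake_bound(self):
        sol = solve_fba(chain_network(5.0), "EX_B")
        assert sol.status == "optimal"
        assert sol.objective == pytest.approx(5.0)
        assert mass_balance_residual(chain_network(5.0), sol.fluxes) < 1e-6

    def test_zero_uptake_gives_zero_objective(self):
        sol = solve_fba(chain_network(0.0), "EX_B")
        assert sol.objective == pytest.approx(0.0)

    def test_matches_cobra_on_mini_core(self, mini_core):
        cobra = pytest.importorskip("cobra")
        net, _, _ = mini_core
        ours = solve_fba(net)
        model = cobra.Model("mini")
        cmet = {m.id: cobra.Metabolite(m.id, compartment=m.compartment)
                for m in net.metabolites}
        for r in net.reactions:
            rx = cobra.Reaction(r.id)
            model.add_reactions([rx])
            rx.add_metabolites({cmet[m]: c for m, c in r.stoichiometry.items()})
            rx.bounds = (r.lower_bound, r.upper_bound)
        model.objective = "BIO"
        ref = model.optimize()
        assert ours.objective == pytest.approx(ref.objective_value, abs=1e-6)


class TestTmfaConstruction:
    def test_without_thermo_equals_fba(self):
        net = chain_network()
        problem = build_problem(net, ThermoTable({}))
        fba = solve_fba(net, "EX_B")
        tmfa = solve_tmfa(problem, "EX_B")
        assert tmfa.objective == pytest.approx(fba.objective)

    def test_objective_never_exceeds_fba(self, mini_core):
        net, table, _ = mini_core
        fba = solve_fba(net)
        tmfa = solve_tmfa(build_problem(net, table))
        assert tmfa.objective <= fba.objective + 1e-6

    def test_benign_pathway_unaffected(self):
        # strongly downhill chain: thermodynamics non-binding
        net = chain_network()
        table = ThermoTable({"A": (0.0, 0.0), "B": (-20.0, 0.0)})
        tmfa = solve_tmfa(build_problem(net, table), "EX_B")
        assert tmfa.objective == pytest.approx(5.0)

    def test_collapsed_activities_force_infeasibility(self):
        # pin activities so the only pathway reaction has drG' > 0
        net = MetabolicNetwork(
            [Metabolite("A"), Metabolite("B")],
            [Reaction("EX_A", {"A": 1.0}, 1.0, 5.0),  # forced uptake
             Reaction("R1", {"A": -1.0, "B": 1.0}, 0.0, 100.0),
             Reaction("EX_B", {"B": -1.0}, 0.0, 100.0, objective_coeff=1.0)],
        )
        table = ThermoTable({"A": (0.0, 0.0), "B": (2.0, 0.0)})  # uphill
        problem = build_problem(net, table,
                                ln_bounds={"A": (-5.0, -5.0), "B": (-5.0, -5.0)})
        sol = solve_tmfa(problem, "EX_B")
        assert sol.status == "infeasible"

    def test_three_reaction_cycle_never_fully_active(self):
        """Enumerating all 8 binary patterns: no feasible one carries
        strictly positive flux all the way around a zero-sum cycle."""
        mets = [Metabolite(m) for m in "ABC"]
        rxns = [
            Reaction("C1", {"A": -1.0, "B": 1.0}, 0, 10),
            Reaction("C2", {"B": -1.0, "C": 1.0}, 0, 10),
            Reaction("C3", {"C": -1.0, "A": 1.0}, 0, 10),
        ]
        net = MetabolicNetwork(mets, rxns)
        table = ThermoTable({"A": (-5.0, 0.0), "B": (-6.0, 0.0), "C": (-5.5, 0.0)})
        oracle = EnumOracle(net, {t.reaction_id: t.drG0 for t in
                                  assemble_reaction_thermo(net, table, CFG)}, config=CFG)
        best = oracle.max_objective({"C1": 1.0})
        assert best == pytest.approx(0.0, abs=1e-9)
        problem = build_problem(net, table)
        sol = solve_tmfa(problem, {"C1": 1.0})
        assert sol.objective == pytest.approx(0.0, abs=1e-9)


class TestFutileCycle:
    def test_fba_allows_cycle_up_to_bound_tmfa_confines_it(self, futile_cycle):
        net, table, gt = futile_cycle
        cyc = gt.pathway_reaction  # the pathway-carrying cycle member
        fva_fba = flux_variability(net, "EX_D", reactions=["R2", "R3"])
        assert fva_fba["R2"][1] == pytest.approx(net.reaction("R2").upper_bound)
        problem = build_problem(net, table)
        fva_tmfa = flux_variability(problem, "EX_D", reactions=["R2", "R3"])
        assert fva_tmfa["R2"][1] == pytest.approx(gt.pathway_flux, abs=1e-6)
        assert fva_tmfa["R3"] == pytest.approx((0.0, 0.0), abs=1e-6)

    def test_blocked_reaction_has_zero_range(self):
        net = MetabolicNetwork(
            [Metabolite("A"), Metabolite("B"), Metabolite("Z")],
            [Reaction("EX_A", {"A": 1.0}, 0, 5),
             Reaction("R1", {"A": -1.0, "B": 1.0}, 0, 100),
             Reaction("DEAD", {"Z": -1.0, "B": 1.0}, 0, 100),  # Z unproducible
             Reaction("EX_B", {"B": -1.0}, 0, 100, objective_coeff=1.0)],
        )
        fva = flux_variability(net, "EX_B", reactions=["DEAD"])
        assert fva["DEAD"] == pytest.approx((0.0, 0.0))

    def test_relaxed_objective_recovers_bound_propagation(self, futile_cycle):
        net, _, _ = futile_cycle
        fva = flux_variability(net, "EX_D", fix_objective_at=0.0, fraction=False,
                               reactions=["EX_A"])
        assert fva["EX_A"] == pytest.approx((0.0, 5.0))


class TestSecondLaw:
    def test_no_active_reaction_with_nonnegative_drg(self, mini_core):
        net, table, _ = mini_core
        problem = build_problem(net, table)
        sol = solve_tmfa(problem)
        assert sol.status == "optimal"
        assert second_law_violations(problem, sol) == []

    def test_audit_across_fixture_kinds(self):
        for kind in ("linear_chain", "branched", "futile_cycle"):
            net, table, gt = make_network_fixture(FixtureSpec(kind=kind, seed=3,
                                                              n_reactions=5))
            problem = build_problem(net, table)
            sol = solve_tmfa(problem)
            assert sol.status == "optimal", kind
            assert second_law_violations(problem, sol) == [], kind
            assert mass_balance_residual(net, sol.fluxes) < 1e-6


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_optimum_matches_enumeration(self, seed):
        net, table, gt = random_fixture(seed)
        thermo = assemble_reaction_thermo(net, table, CFG)
        problem = build_tmfa(net, thermo, [], CFG)
        sol = solve_tmfa(problem)
        drg0 = {t.reaction_id: t.drG0 for t in thermo if t.known and t.constrained}
        oracle = EnumOracle(net, drg0, config=CFG)
        objective = {r.id: r.objective_coeff for r in net.reactions if r.objective_coeff}
        best = oracle.max_objective(objective)
        if sol.status == "infeasible":
            assert best == -math.inf
        else:
            assert sol.objective == pytest.approx(best, abs=1e-6)


class TestMonotonicity:
    def test_tightening_activity_bounds_never_helps(self, mini_core):
        net, table, _ = mini_core
        wide = solve_tmfa(build_problem(net, table))
        tight_cfg = ThermoConfig(ln_activity_min=math.log(1e-4),
                                 ln_activity_max=math.log(0.01))
        tight = solve_tmfa(build_problem(net, table, config=tight_cfg))
        if tight.status == "optimal":
            assert tight.objective <= wide.objective + 1e-6
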