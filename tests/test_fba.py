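"""Two-stage FBA: biomass LP, L1 minimization, and the simulate pipeline."""

import numpy as np
import pytest

from protflux import (
    BoundSet,
    FluxDistribution,
    MetabolicModel,
    Metabolite,
    ProteomeSpec,
    Reaction,
    SolverStatus,
    Stage,
    ToyModelSpec,
    knockout,
    make_proteome,
    make_toy_model,
    minimize_total_flux,
    simulate,
    solve_fba,
)
from protflux.fba import FBAError
from protflux.synthetic_data import make_random_model

from conftest import build_cobra_model


def chain_model(cap=10.0):
    mets = [Metabolite("A"), Metabolite("B")]
    rxns = [
        Reaction("EX_A", {"A": 1.0}, upper_bound=cap),
        Reaction("AtoB", {"A": -1.0, "B": 1.0}),
        Reaction("BIO", {"B": -1.0}, objective_coefficient=1.0),
    ]
    return MetabolicModel(mets, rxns, "BIO")


class TestSolveFBA:
    def test_hand_solved_chain(self):
        # every reaction capped at 10 -> Z = 10, all fluxes 10
        sol = solve_fba(chain_model(10.0))
        assert sol.status is SolverStatus.OPTIMAL
        assert sol.objective_value == pytest.approx(10.0)
        assert sol.fluxes == pytest.approx({"EX_A": 10.0, "AtoB": 10.0, "BIO": 10.0})

    def test_closed_system_is_zero(self):
        model = chain_model()
        bounds = BoundSet.from_model(model)
        bounds.bounds["EX_A"] = (0.0, 0.0)
        sol = solve_fba(model, bounds)
        assert sol.objective_value == pytest.approx(0.0)
        assert all(abs(v) < 1e-9 for v in sol.fluxes.values())

    def test_forced_consumption_without_source_infeasible(self):
        model = chain_model()
        bounds = BoundSet.from_model(model)
        bounds.bounds["EX_A"] = (0.0, 0.0)
        bounds.bounds["BIO"] = (5.0, 1000.0)  # demand biomass with no input
        sol = solve_fba(model, bounds)
        assert sol.status is SolverStatus.INFEASIBLE

    def test_mass_balance_at_optimum(self, toy_model):
        sol = solve_fba(toy_model)
        S = toy_model.stoichiometric_matrix()
        v = sol.vector(toy_model.reaction_ids())
        assert np.abs(S @ v).max() < 1e-6

    def test_oracle_equivalence_random_models(self):
        """Objective matches an independent cobrapy solve on 100 models."""
        rng = np.random.default_rng(2024)
        checked = 0
        for _ in range(100):
            model = make_random_model(rng)
            mine = solve_fba(model)
            cm = build_cobra_model(model)
            ref = cm.optimize()
            if mine.status is SolverStatus.OPTIMAL and ref.status == "optimal":
                scale = max(1.0, abs(ref.objective_value))
                assert abs(mine.objective_value - ref.objective_value) / scale < 1e-6
                checked += 1
            else:
                assert (mine.status is not SolverStatus.OPTIMAL) == (
                    ref.status != "optimal"
                )
        assert checked >= 80  # construction makes most models solvable


class TestMinimizeTotalFlux:
    def test_parallel_paths_take_direct_route(self, toy):
        model, z_opt, min_l1 = toy
        bounds = BoundSet.from_model(model)
        fba = solve_fba(model, bounds)
        sol = minimize_total_flux(model, bounds, fba.objective_value)
        # direct chain carries everything; the 2-reaction detour is idle
        assert sol.fluxes["CHAIN1"] == pytest.approx(z_opt, rel=1e-6)
        assert sol.fluxes["PAR1a"] == pytest.approx(0.0, abs=1e-9)
        assert sol.total_absolute_flux() == pytest.approx(min_l1, rel=1e-6)

    def test_biomass_preserved(self, toy):
        model, z_opt, _ = toy
        bounds = BoundSet.from_model(model)
        sol = minimize_total_flux(model, bounds, z_opt)
        assert sol.objective_value >= z_opt - 1e-6

    def test_futile_cycle_driven_to_zero(self, toy_model):
        bounds = BoundSet.from_model(toy_model)
        fba = solve_fba(toy_model, bounds)
        sol = minimize_total_flux(toy_model, bounds, fba.objective_value)
        for rid in ("CYC1a", "CYC1b", "CYC1c"):
            assert sol.fluxes[rid] == pytest.approx(0.0, abs=1e-9)

    def test_unique_optimum_unchanged(self):
        model = chain_model(7.5)
        bounds = BoundSet.from_model(model)
        fba = solve_fba(model, bounds)
        pfba = minimize_total_flux(model, bounds, fba.objective_value)
        for rid in model.reaction_ids():
            assert pfba.fluxes[rid] == pytest.approx(fba.fluxes[rid], abs=1e-6)

    def test_l1_never_exceeds_fba_l1(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            model = make_random_model(rng)
            bounds = BoundSet.from_model(model)
            fba = solve_fba(model, bounds)
            if fba.status is not SolverStatus.OPTIMAL:
                continue
            pfba = minimize_total_flux(model, bounds, fba.objective_value)
            assert pfba.status is SolverStatus.OPTIMAL
            assert pfba.total_absolute_flux() <= fba.total_absolute_flux() + 1e-6
            c = np.array([r.objective_coefficient for r in model.reactions])
            v = pfba.vector(model.reaction_ids())
            assert c @ v >= fba.objective_value - 1e-6

    def test_gamma_out_of_range_rejected(self, toy_model):
        with pytest.raises(ValueError, match="gamma"):
            minimize_total_flux(toy_model, BoundSet.from_model(toy_model), 1.0, gamma=0.0)

    def test_exclude_removes_reactions_from_objective(self, toy_model):
        bounds = BoundSet.from_model(toy_model)
        fba = solve_fba(toy_model, bounds)
        full = minimize_total_flux(toy_model, bounds, fba.objective_value)
        excl = minimize_total_flux(
            toy_model, bounds, fba.objective_value, exclude={"EX_M0", "BIOMASS"}
        )
        weight = lambda fd, skip: sum(
            abs(v) for r, v in fd.fluxes.items() if r not in skip
        )
        assert weight(excl, {"EX_M0", "BIOMASS"}) <= weight(full, {"EX_M0", "BIOMASS"}) + 1e-6


class TestKnockoutMonotonicity:
    def test_every_single_knockout_lowers_or_keeps_z(self, toy_model):
        wt = solve_fba(toy_model).objective_value
        base = BoundSet.from_model(toy_model)
        for rid in toy_model.reaction_ids():
            sol = solve_fba(toy_model, knockout(base, [rid]))
            assert sol.status is SolverStatus.OPTIMAL
            assert sol.objective_value <= wt + 1e-9


class TestSimulate:
    def test_wild_type_hits_known_optimum(self, toy):
        model, z_opt, min_l1 = toy
        spec = ProteomeSpec(n_proteins=20, de_fraction=0.0, seed=3)
        table, _ = make_proteome(spec, sorted(model.genes))
        levels = {g: 50.0 for g in model.genes}  # all above the uptake cap
        dist, bounds = simulate(model, levels=levels)
        assert dist.stage is Stage.PFBA
        assert dist.objective_value == pytest.approx(z_opt, rel=1e-6)
        assert dist.total_absolute_flux() == pytest.approx(min_l1, rel=1e-6)

    def test_biomass_path_knockout_zeroes_growth(self, toy_model):
        dist, _ = simulate(toy_model, knockouts=["CHAIN3"])
        assert dist.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_overexpression_factor_one_is_wild_type(self, toy_model):
        wt, _ = simulate(toy_model)
        oe, _ = simulate(toy_model, overexpressions=[("CHAIN1", 1.0)])
        assert oe.fluxes == pytest.approx(wt.fluxes, abs=1e-9)

    def test_infeasible_raises_with_stage(self):
        model = chain_model()
        model.reactions[2].lower_bound = 5.0  # forced biomass
        model.reactions[0].upper_bound = 0.0  # no source
        with pytest.raises(FBAError, match="fba"):
            simulate(model)
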