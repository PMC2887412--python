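"""LP core: FBA, regulated FBA, strong-duality block, production envelopes."""

import numpy as np
import pytest

from optorf.fba import (FEAS_TOL, MILP, add_flux_system, add_inner_optimality,
                        effective_bounds, extract_dual_solution,
                        production_envelope, solve_fba, solve_regulated_fba,
                        theoretical_max_product, vname)
from optorf.logic import PerturbationVars, reaction_feasibility, compile_gpr
from optorf.model import random_toy_model


class TestSolveFBA:
    def test_wildtype_prefers_high_yield_branch(self, example_model, env1):
        res = solve_fba(example_model, env1)
        assert res.optimal
        assert res.objective == pytest.approx(0.12, abs=1e-9)
        assert res.flux["EX_P2"] == pytest.approx(1.0, abs=1e-6)

    def test_forced_onto_low_yield_branch(self, example_model, env1):
        res = solve_fba(example_model, env1, d={"R3": False, "R4": False})
        assert res.objective == pytest.approx(0.08, abs=1e-9)
        assert res.flux["EX_P1"] == pytest.approx(1.0, abs=1e-6)

    def test_all_internal_off(self, example_model, env1):
        d = {j: False for j, r in example_model.reactions.items()
             if not r.is_exchange}
        res = solve_fba(example_model, env1, d=d)
        assert res.optimal and res.objective == pytest.approx(0.0, abs=1e-9)

    def test_infeasible_reported(self, example_model, env1):
        res = solve_fba(example_model, env1, min_growth=0.5,
                        d={j: False for j in ("R2", "R5")})
        assert res.status == "infeasible"

    def test_scaling_with_uptake(self, example_model, env10):
        res = solve_fba(example_model, env10)
        assert res.objective == pytest.approx(1.2, abs=1e-8)


class TestRegulatedFBA:
    def test_wildtype_r1_repressed(self, example_model, env1):
        res = solve_regulated_fba(example_model, env1)
        assert res.optimal
        assert res.growth == pytest.approx(0.12, abs=1e-8)
        assert res.flux["R1"] == pytest.approx(0.0, abs=1e-6)
        assert res.flux["EX_P2"] == pytest.approx(1.0, abs=1e-6)
        assert res.state.y["TF1"] and not res.state.y["G1A"]

    def test_tf1_g4_double_deletion_couples_p1(self, example_model, env1):
        p = PerturbationVars.from_sets(["TF1", "G4"])
        res = solve_regulated_fba(example_model, env1, p)
        assert res.growth == pytest.approx(0.08, abs=1e-8)
        assert res.flux["EX_P1"] == pytest.approx(1.0, abs=1e-6)

    def test_isozyme_pair_deletion_lethal(self, example_model, env10):
        p = PerturbationVars.from_sets(["G5", "G6"])
        res = solve_regulated_fba(example_model, env10, p, min_growth=0.1)
        assert res.status == "infeasible" and res.lethal

    def test_state_is_consistent_with_fluxes(self, example_model, env1,
                                             example_indices):
        from optorf.logic import evaluate_state

        res = solve_regulated_fba(example_model, env1)
        gpr, reg = example_indices
        st = evaluate_state(reg, gpr, env1, res.flux,
                            reaction_ids=example_model.reactions)
        assert st.y == res.state.y
        assert st.d == res.state.d

    @pytest.mark.parametrize("seed", range(6))
    def test_regulation_never_raises_growth(self, seed):
        model, env = random_toy_model(8, 8, 2, seed=seed)
        unreg = solve_fba(model, env)
        reg = solve_regulated_fba(model, env)
        assert reg.optimal
        assert reg.growth <= unreg.objective + FEAS_TOL


class TestStrongDuality:
    def _solve_with_block(self, model, env, d_const, h_bound=None):
        bounds = effective_bounds(model, env)
        lp = MILP()
        add_flux_system(lp, model, bounds)
        add_inner_optimality(lp, model, bounds, d_const, h_bound=h_bound,
                             link_primal=True)
        lp.set_objective({vname(model.biomass_reaction_id): 1.0})
        res = lp.solve()
        return res, bounds

    def test_block_attains_plain_fba_optimum(self, example_model, env1):
        d = {j: 1.0 for j, r in example_model.reactions.items()
             if not r.is_exchange}
        res, bounds = self._solve_with_block(example_model, env1, d)
        assert res.optimal
        assert res.objective == pytest.approx(0.12, abs=1e-8)

    def test_primal_equals_dual(self, example_model, env1):
        d = {j: 1.0 for j, r in example_model.reactions.items()
             if not r.is_exchange}
        res, bounds = self._solve_with_block(example_model, env1, d)
        dual = extract_dual_solution(example_model, res, bounds)
        primal = res.values[vname(example_model.biomass_reaction_id)]
        assert abs(primal - dual.objective) <= 1e-6

    def test_forces_inner_optimality_under_deletion(self, example_model, env1):
        d = {j: 1.0 for j, r in example_model.reactions.items()
             if not r.is_exchange}
        d["R5"] = 0.0
        res, _ = self._solve_with_block(example_model, env1, d)
        assert res.objective == pytest.approx(0.08, abs=1e-8)
        assert abs(res.values[vname("R5")]) <= 1e-6

    def test_h_bounds_honored(self, example_model, env1):
        d = {j: 1.0 for j, r in example_model.reactions.items()
             if not r.is_exchange}
        d["R5"] = 0.0
        d["R3"] = 0.0
        res, bounds = self._solve_with_block(example_model, env1, d, h_bound=1.0)
        dual = extract_dual_solution(example_model, res, bounds)
        for j, h in dual.h.items():
            assert -1.0 - 1e-9 <= h <= 1.0 + 1e-9

    @pytest.mark.parametrize("seed", range(5))
    def test_block_matches_plain_fba_on_random_models(self, seed):
        model, env = random_toy_model(8, 8, 2, seed=seed)
        d = {j: 1.0 for j, r in model.reactions.items() if not r.is_exchange}
        res, bounds = self._solve_with_block(model, env, d)
        plain = solve_fba(model, env)
        assert res.objective == pytest.approx(plain.objective, abs=1e-6)
        dual = extract_dual_solution(model, res, bounds)
        assert abs(res.objective - dual.objective) <= 1e-6


class TestEnvelope:
    def test_wildtype_p1_uncoupled(self, example_model, env1):
        df = production_envelope(example_model, env1, "EX_P1", 5)
        top = df.iloc[-1]
        assert top["growth"] == pytest.approx(0.12, abs=1e-8)
        assert top["product_max"] == pytest.approx(0.0, abs=1e-6)

    def test_coupled_mutant_min_product_positive(self, example_model, env1):
        p = PerturbationVars.from_sets(["TF1", "G4"])
        df = production_envelope(example_model, env1, "EX_P1", 5,
                                 regulated=True, perturb=p)
        top = df.iloc[-1]
        assert top["growth"] == pytest.approx(0.08, abs=1e-4)
        assert top["product_min"] > 0.5

    @pytest.mark.parametrize("seed", range(4))
    def test_min_leq_max_everywhere(self, seed):
        model, env = random_toy_model(8, 8, 2, seed=seed)
        df = production_envelope(model, env, "EX_P1", 6)
        valid = df.dropna()
        assert (valid["product_min"] <= valid["product_max"] + 1e-6).all()

    def test_regulated_contained_in_unregulated(self, example_model, env1,
                                                example_indices):
        """At every growth level of the regulated envelope, the unregulated
        min/max bracket the regulated ones (same interventions)."""
        gpr, _ = example_indices
        p = PerturbationVars.from_sets(["TF1", "G4"])
        reg_df = production_envelope(example_model, env1, "EX_P1", 5,
                                     regulated=True, perturb=p)
        y_hat = {g: g not in p.z for g in example_model.genes}
        d = reaction_feasibility(gpr, y_hat, example_model.reactions)
        for _, row in reg_df.dropna().iterrows():
            lo = solve_fba(example_model, env1, d=d, objective="EX_P1",
                           maximize=False,
                           fixed={"EX_B": row["growth"]})
            hi = solve_fba(example_model, env1, d=d, objective="EX_P1",
                           fixed={"EX_B": row["growth"]})
            # the regulated sub-solves take a +-1e-6 growth window, worth
            # ~1e-5 of product here; compare with that slack
            assert lo.objective <= row["product_min"] + 1e-4
            assert hi.objective >= row["product_max"] - 1e-4

    def test_zero_growth_single_row(self, example_model):
        from optorf.model import Environment

        env0 = Environment(uptake_bounds={"EX_S": 0.0})
        df = production_envelope(example_model, env0, "EX_P1", 5)
        assert len(df) == 1 and df.iloc[0]["growth"] == 0.0


def test_theoretical_max_product(example_model, env1):
    # all substrate routed through R1/R2 when gene logic is ignored
    assert theoretical_max_product(example_model, env1, "EX_P1") == \
        pytest.approx(1.0, abs=1e-8)
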