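"""Logic compiler: DNF expansion, effector typing, perturbation algebra,
Boolean state evaluation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from optorf.logic import (Condition, ConsistencyError, Effector,
                          PerturbationError, PerturbationVars,
                          apply_perturbations, compile_gpr, compile_regulation,
                          evaluate_state, reaction_feasibility, to_dnf)
from optorf.model import (And, Environment, Gene, IntegratedModel, Metabolite,
                          Not, Or, Reaction, Ref, RegulatoryRule, eval_expr,
                          parse_rule, random_toy_model)


def tiny_model(gprs: dict[str, str], rules: dict[str, str] = (),
               tfs: set[str] = frozenset()):
    """One-metabolite scaffold carrying arbitrary GPRs/rules for logic tests."""
    rules = dict(rules or {})
    genes = set()
    reactions = {}
    for j, text in gprs.items():
        gpr = parse_rule(text) if text else None
        reactions[j] = Reaction(j, {"A": 1.0}, 0, 10, gpr=gpr)
        if gpr is not None:
            stack = [gpr]
            while stack:
                e = stack.pop()
                if isinstance(e, Ref):
                    genes.add(e.name)
                elif isinstance(e, (And, Or)):
                    stack.extend(e.children)
                elif isinstance(e, Not):
                    stack.append(e.child)
    reactions["EX_A"] = Reaction("EX_A", {"A": -1.0}, 0, 10, is_exchange=True)
    genes |= set(rules)
    gene_objs = {g: Gene(g, "transcription_factor" if g in tfs else "metabolic")
                 for g in genes}
    rule_objs = {t: RegulatoryRule(t, parse_rule(x), x) for t, x in rules.items()}
    return IntegratedModel({"A": Metabolite("A")}, reactions, gene_objs,
                           rule_objs, "EX_A").validate()


class TestCompileGPR:
    def test_isozymes(self):
        idx = compile_gpr(tiny_model({"TKT1": "tktA or tktB"}))
        assert set(idx.complexes["TKT1"]) == {frozenset({"tktA"}),
                                              frozenset({"tktB"})}

    def test_complex(self):
        idx = compile_gpr(tiny_model({"R1": "G1A and G1B"}))
        assert idx.complexes["R1"] == (frozenset({"G1A", "G1B"}),)

    def test_no_gpr_excluded(self):
        idx = compile_gpr(tiny_model({"R9": ""}))
        assert "R9" not in idx

    def test_absorption(self):
        # (a) or (a and b) collapses to the single-gene isozyme
        idx = compile_gpr(tiny_model({"R": "a or (a and b)"}))
        assert idx.complexes["R"] == (frozenset({"a"}),)

    def test_mixed_nesting(self):
        idx = compile_gpr(tiny_model({"R": "(a and b) or (c and (d or e))"}))
        assert set(idx.complexes["R"]) == {frozenset({"a", "b"}),
                                           frozenset({"c", "d"}),
                                           frozenset({"c", "e"})}


class TestCompileRegulation:
    def test_uptake_sensing_tf(self, example_model):
        reg = compile_regulation(example_model)
        (cond,) = reg.conditions["TF1"]
        assert cond.activators == (Effector("NF", "EX_S"),)
        assert cond.repressors == ()

    def test_repressor(self, example_model):
        reg = compile_regulation(example_model)
        (cond,) = reg.conditions["G1A"]
        assert cond.activators == ()
        assert cond.repressors == (Effector("TF", "TF1"),)

    def test_constitutive_gene_single_empty_condition(self, example_model):
        reg = compile_regulation(example_model)
        assert reg.conditions["G2"] == (Condition((), ()),)

    def test_epsilon_default(self, example_model):
        assert compile_regulation(example_model).epsilon == pytest.approx(1e-3)

    def test_stimulus_effector(self):
        m = tiny_model({"R": "g1"}, {"g1": "STRESS or not tf", "tf": ""},
                       tfs={"tf"})
        reg = compile_regulation(m)
        conds = reg.conditions["g1"]
        assert Condition((Effector("ES", "STRESS"),), ()) in conds
        assert Condition((), (Effector("TF", "tf"),)) in conds


def random_expr(rng, names, depth=3):
    if depth == 0 or rng.uniform() < 0.3:
        return Ref(str(rng.choice(names)))
    op = rng.uniform()
    if op < 0.2:
        return Not(random_expr(rng, names, depth - 1))
    children = tuple(random_expr(rng, names, depth - 1)
                     for _ in range(int(rng.integers(2, 4))))
    return And(children) if op < 0.6 else Or(children)


class TestDnfEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_dnf_matches_tree_on_random_assignments(self, seed):
        rng = np.random.default_rng(seed)
        names = ["a", "b", "c", "d", "e"]
        expr = random_expr(rng, names)
        terms = to_dnf(expr)
        for _ in range(200):
            bits = {n: bool(rng.integers(0, 2)) for n in names}
            direct = eval_expr(expr, lambda lit: bits[lit.name])
            via_dnf = any(all(bits[l.name] for l in pos)
                          and not any(bits[l.name] for l in neg)
                          for pos, neg in terms)
            assert direct == via_dnf

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_dnf_matches_tree_exhaustively(self, seed):
        rng = np.random.default_rng(seed)
        names = ["a", "b", "c", "d"]
        expr = random_expr(rng, names, depth=2)
        terms = to_dnf(expr)
        for values in itertools.product([False, True], repeat=len(names)):
            bits = dict(zip(names, values))
            direct = eval_expr(expr, lambda lit: bits[lit.name])
            via_dnf = any(all(bits[l.name] for l in pos)
                          and not any(bits[l.name] for l in neg)
                          for pos, neg in terms)
            assert direct == via_dnf


class TestApplyPerturbations:
    @pytest.mark.parametrize("y,z,w,expected", [
        (True, True, False, False),   # expressed gene deleted
        (False, False, True, True),   # repressed gene overexpressed
        (True, False, False, True),   # identity
        (False, False, False, False), # identity
    ])
    def test_cases(self, y, z, w, expected):
        assert apply_perturbations(y, z, w) is expected

    @pytest.mark.parametrize("y,z,w", [
        (False, True, False),   # deleting an unexpressed gene
        (True, False, True),    # overexpressing an expressed gene
        (True, True, True),     # both at once
    ])
    def test_contract_violations(self, y, z, w):
        with pytest.raises(PerturbationError):
            apply_perturbations(y, z, w)

    def test_unique_boolean_function(self):
        # the only valid combinations fully determine y_hat = (y & ~z) | (~y & w)
        for y, z, w in itertools.product([False, True], repeat=3):
            valid = not (z and w) and not (z and not y) and not (w and y)
            if valid:
                assert apply_perturbations(y, z, w) == ((y and not z) or
                                                        (not y and w))


class TestReactionFeasibility:
    def test_isozyme_one_of_two(self, example_model, example_indices):
        gpr, _ = example_indices
        y_hat = {g: True for g in example_model.genes}
        y_hat["G5"] = False
        d = reaction_feasibility(gpr, y_hat)
        assert d["R5"] is True

    def test_complex_missing_subunit(self, example_model, example_indices):
        gpr, _ = example_indices
        y_hat = {g: True for g in example_model.genes}
        y_hat["G1A"] = False
        assert reaction_feasibility(gpr, y_hat)["R1"] is False

    def test_all_off(self, example_model, example_indices):
        gpr, _ = example_indices
        y_hat = {g: False for g in example_model.genes}
        d = reaction_feasibility(gpr, y_hat, example_model.reactions)
        for j in gpr.complexes:
            assert d[j] is False
        for j in example_model.exchanges:
            assert d[j] is True

    @pytest.mark.parametrize("seed", range(5))
    def test_truth_table_brute_force(self, seed):
        """Index-based evaluation equals direct GPR tree evaluation for every
        gene assignment (models kept <= 12 genes)."""
        model, _ = random_toy_model(8, 8, 2, seed=seed)
        gpr = compile_gpr(model)
        genes = sorted(model.genes)
        assert len(genes) <= 12
        for values in itertools.product([False, True], repeat=len(genes)):
            y_hat = dict(zip(genes, values))
            d = reaction_feasibility(gpr, y_hat)
            for j, rxn in model.reactions.items():
                if rxn.gpr is None:
                    continue
                assert d[j] == eval_expr(rxn.gpr, lambda l: y_hat[l.name])


class TestEvaluateState:
    def test_wildtype_uptake_active(self, example_model, example_indices, env1):
        gpr, reg = example_indices
        flux = {j: 0.0 for j in example_model.reactions}
        flux["EX_S"] = -1.0
        st_ = evaluate_state(reg, gpr, env1, flux)
        assert st_.y["TF1"] and not st_.y["G1A"]
        assert st_.y["G3"] and st_.y["G5"]
        assert st_.d["R1"] is False

    def test_tf_deletion_cascade(self, example_model, example_indices, env1):
        gpr, reg = example_indices
        flux = {j: 0.0 for j in example_model.reactions}
        flux["EX_S"] = -1.0
        st_ = evaluate_state(reg, gpr, env1, flux,
                             PerturbationVars.from_sets(["TF1"]))
        assert not st_.y_hat["TF1"]
        assert not st_.y_hat["G3"] and not st_.y_hat["G5"]
        assert st_.y_hat["G1A"]

    def test_no_uptake(self, example_model, example_indices, env1):
        gpr, reg = example_indices
        flux = {j: 0.0 for j in example_model.reactions}
        st_ = evaluate_state(reg, gpr, env1, flux)
        assert not st_.y["TF1"]
        assert st_.y["G1A"]

    def test_contradictory_cycle_reported(self):
        m = tiny_model({"R": "g"}, {"tf": "not tf", "g": "tf"}, tfs={"tf"})
        gpr, reg = compile_gpr(m), compile_regulation(m)
        flux = {j: 0.0 for j in m.reactions}
        with pytest.raises(ConsistencyError, match="tf"):
            evaluate_state(reg, gpr, Environment(), flux)

    def test_bistable_cycle_prefers_expression(self):
        # tf self-activates: both on and off are fixed points; the evaluator
        # deterministically reports the expressed one
        m = tiny_model({"R": "g"}, {"tf": "tf", "g": "tf"}, tfs={"tf"})
        gpr, reg = compile_gpr(m), compile_regulation(m)
        flux = {j: 0.0 for j in m.reactions}
        st_ = evaluate_state(reg, gpr, Environment(), flux)
        assert st_.y["tf"] is True


class TestPerturbationVars:
    def test_overlap_rejected(self):
        with pytest.raises(PerturbationError):
            PerturbationVars.from_sets(["g1"], ["g1"])

    def test_tf_overexpression_rejected(self, example_model):
        with pytest.raises(PerturbationError, match="TF1"):
            PerturbationVars.from_sets((), ["TF1"]).validate_against(example_model)

    def test_caps(self):
        with pytest.raises(PerturbationError):
            PerturbationVars.from_sets(["a", "b"], (), k1=1)
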