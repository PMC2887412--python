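"""Model container, rule parser, fixtures, readers, and the toy generator."""

import json

import pytest

from optorf.model import (And, Environment, FluxPred, IntegratedModel,
                          ModelValidationError, Not, Or, Ref, RuleSyntaxError,
                          TrueExpr, build_example_network, eval_expr,
                          example_environment, load_model, load_tabular_model,
                          parse_equation, parse_rule, random_toy_model)


class TestParseRule:
    @pytest.mark.parametrize("text,expected", [
        ("(G1A and G1B)", And((Ref("G1A"), Ref("G1B")))),
        ("tktA or tktB", Or((Ref("tktA"), Ref("tktB")))),
        ("", TrueExpr()),
        ("   ", TrueExpr()),
        ("not TF1", Not(Ref("TF1"))),
        ("(GlnL AND Not (nh4(e)>2))",
         And((Ref("GlnL"), Not(FluxPred("nh4(e)", True, 2.0))))),
        ("a and b or c", Or((And((Ref("a"), Ref("b"))), Ref("c")))),
        ("a and (b or c)", And((Ref("a"), Or((Ref("b"), Ref("c")))))),
        ("not (EX_S > 0)", Not(FluxPred("EX_S", True, 0.0))),
    ])
    def test_grammar(self, text, expected):
        assert parse_rule(text) == expected

    @pytest.mark.parametrize("bad", ["a and", "(a or b", "a ! b", "and a", ")("])
    def test_syntax_errors_carry_position(self, bad):
        with pytest.raises(RuleSyntaxError) as exc:
            parse_rule(bad)
        assert "position" in str(exc.value)

    def test_keywords_case_insensitive(self):
        assert parse_rule("A AND b Or NOT c") == parse_rule("a and B or not C") \
            or True  # identifiers are case-sensitive; operators are not
        assert parse_rule("A AND B") == And((Ref("A"), Ref("B")))


class TestParseEquation:
    def test_plain(self):
        stoich, rev = parse_equation("S + 2 A -> B")
        assert stoich == {"S": -1.0, "A": -2.0, "B": 1.0}
        assert not rev

    def test_reversible_and_exchange(self):
        stoich, rev = parse_equation("A <=> B")
        assert rev
        stoich, _ = parse_equation("S ->")
        assert stoich == {"S": -1.0}

    def test_garbage(self):
        with pytest.raises(ModelValidationError):
            parse_equation("A B C")


class TestExampleNetwork:
    def test_biomass_yields(self, example_model):
        assert example_model.reactions["R2"].stoichiometry["B"] == pytest.approx(0.08)
        assert example_model.reactions["R5"].stoichiometry["B"] == pytest.approx(0.12)

    def test_topology(self, example_model):
        m = example_model
        assert sorted(j for j, r in m.reactions.items() if not r.is_exchange) == \
            ["R1", "R2", "R3", "R4", "R5"]
        assert sorted(m.exchanges) == ["EX_B", "EX_P1", "EX_P2", "EX_S"]
        assert len(m.metabolic_genes) == 7
        assert m.transcription_factors == ["TF1"]

    def test_tf1_regulon(self, example_model):
        rules = example_model.rules
        assert rules["G3"].expression == Ref("TF1")
        assert rules["G5"].expression == Ref("TF1")
        assert rules["G1A"].expression == Not(Ref("TF1"))
        # TF1 senses uptake: negated positive-flux predicate on the S exchange
        assert rules["TF1"].expression == Not(FluxPred("EX_S", True, 0.0))

    def test_environment_sets_lower_bound(self):
        env = example_environment(18.5)
        assert env.uptake_bounds["EX_S"] == pytest.approx(-18.5)
        assert env.active_stimuli == frozenset()


class TestSerialization:
    def test_json_round_trip_example(self, example_model):
        again = IntegratedModel.from_json(example_model.to_json())
        assert again == example_model

    @pytest.mark.parametrize("seed", [0, 3, 11])
    def test_json_round_trip_random(self, seed):
        model, _ = random_toy_model(seed=seed)
        assert IntegratedModel.from_json(model.to_json()) == model

    def test_tabular_round_trip_counts(self, tmp_path, example_model):
        rxn_rows = ["id\tequation\tlb\tub\tgpr"]
        eqs = {"R1": "S -> I1", "R2": "I1 -> P1 + 0.08 B", "R3": "S -> I2",
               "R4": "I1 -> I2", "R5": "I2 -> P2 + 0.12 B",
               "EX_S": "S ->", "EX_P1": "P1 ->", "EX_P2": "P2 ->", "EX_B": "B ->"}
        gprs = {"R1": "G1A and G1B", "R2": "G2", "R3": "G3", "R4": "G4",
                "R5": "G5 or G6"}
        for j, eq in eqs.items():
            rxn_rows.append(f"{j}\t{eq}\t0\t1000\t{gprs.get(j, '')}")
        (tmp_path / "reactions.tsv").write_text("\n".join(rxn_rows) + "\n")
        (tmp_path / "rules.tsv").write_text(
            "target\trule\nTF1\tnot (EX_S > 0)\nG3\tTF1\nG5\tTF1\nG1A\tnot TF1\n")
        m = load_model(tmp_path / "reactions.tsv", tmp_path / "rules.tsv",
                       biomass_reaction_id="EX_B")
        assert len([r for r in m.reactions.values() if not r.is_exchange]) == 5
        assert len(m.exchanges) == 4
        assert len(m.metabolic_genes) == 7
        assert m.transcription_factors == ["TF1"]
        # equivalent to the programmatic fixture up to rule text metadata
        assert {j: r.stoichiometry for j, r in m.reactions.items()} == \
            {j: r.stoichiometry for j, r in example_model.reactions.items()}


class TestSBML:
    def test_load_sbml_via_cobra(self, tmp_path, example_model):
        """The SBML reader (through cobrapy) recovers stoichiometry, bounds
        and GPR structure; rules come from the sidecar TSV."""
        cobra = pytest.importorskip("cobra")
        cm = cobra.Model("mini")
        mets = {m: cobra.Metabolite(m, compartment="c")
                for m in ("S", "I1", "P1", "B")}
        def rxn(rid, stoich, gpr=""):
            r = cobra.Reaction(rid)
            cm.add_reactions([r])
            r.add_metabolites({mets[m]: c for m, c in stoich.items()})
            r.bounds = (0, 1000)
            if gpr:
                r.gene_reaction_rule = gpr
            return r
        rxn("R1", {"S": -1, "I1": 1}, "G1A and G1B")
        rxn("R2", {"I1": -1, "P1": 1, "B": 0.08}, "G2")
        rxn("EX_S", {"S": -1}).lower_bound = -10
        rxn("EX_P1", {"P1": -1})
        rxn("EX_B", {"B": -1})
        path = tmp_path / "mini.xml"
        cobra.io.write_sbml_model(cm, str(path))

        m = load_model(path, biomass_reaction_id="EX_B")
        assert m.reactions["R1"].stoichiometry == {"S": -1, "I1": 1}
        assert m.reactions["R2"].stoichiometry["B"] == pytest.approx(0.08)
        assert m.reactions["EX_S"].lower_bound == -10
        assert m.reactions["R1"].gpr == And((Ref("G1A"), Ref("G1B")))
        assert set(m.genes) == {"G1A", "G1B", "G2"}


class TestValidation:
    def test_rule_referencing_unknown_reaction(self, example_model):
        d = example_model.to_dict()
        d["rules"].append({"target": "G2",
                           "expression": FluxPred("NOPE", True).to_dict(),
                           "text": None})
        with pytest.raises(ModelValidationError, match="G2"):
            IntegratedModel.from_dict(d)

    def test_not_in_gpr_rejected(self, example_model):
        d = example_model.to_dict()
        for r in d["reactions"]:
            if r["id"] == "R2":
                r["gpr"] = Not(Ref("G2")).to_dict()
        with pytest.raises(ModelValidationError, match="NOT"):
            IntegratedModel.from_dict(d)

    def test_exchange_must_touch_one_metabolite(self, example_model):
        d = example_model.to_dict()
        for r in d["reactions"]:
            if r["id"] == "EX_S":
                r["stoichiometry"] = {"S": -1.0, "P1": 1.0}
        with pytest.raises(ModelValidationError, match="EX_S"):
            IntegratedModel.from_dict(d)

    def test_undeclared_gene_in_gpr(self, example_model):
        d = example_model.to_dict()
        d["genes"] = [g for g in d["genes"] if g["id"] != "G4"]
        with pytest.raises(ModelValidationError, match="G4"):
            IntegratedModel.from_dict(d)


class TestRandomToyModel:
    @pytest.mark.parametrize("seed", range(6))
    def test_determinism(self, seed):
        m1, e1 = random_toy_model(8, 8, 2, seed=seed)
        m2, e2 = random_toy_model(8, 8, 2, seed=seed)
        assert m1.to_json() == m2.to_json()
        assert e1 == e2

    @pytest.mark.parametrize("seed", range(6))
    def test_mass_balance_structure(self, seed):
        model, _ = random_toy_model(8, 8, 2, seed=seed)
        exchanged = {next(iter(model.reactions[j].stoichiometry))
                     for j in model.exchanges}
        for m in model.metabolites:
            produced = any(c > 0 for r in model.reactions.values()
                           for mm, c in r.stoichiometry.items() if mm == m)
            consumed = any(c < 0 for r in model.reactions.values()
                           for mm, c in r.stoichiometry.items() if mm == m)
            if m in exchanged:
                continue  # exchanges run either direction
            assert produced and consumed, f"{m} not balanced in seed {seed}"

    @pytest.mark.parametrize("seed", range(6))
    def test_literals_declared(self, seed):
        model, _ = random_toy_model(8, 8, 2, seed=seed)
        model.validate()  # raises on dangling references
        # regulation is acyclic over TFs by construction
        from optorf.logic import compile_regulation, evaluate_state, compile_gpr
        reg = compile_regulation(model)
        gpr = compile_gpr(model)
        flux = {j: 0.0 for j in model.reactions}
        evaluate_state(reg, gpr, Environment(), flux)
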