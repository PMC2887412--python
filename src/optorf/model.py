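"""Integrated metabolic/regulatory model: domain types, rule parsing, I/O, fixtures.

The central container is :class:`IntegratedModel`: a stoichiometric network whose
reactions carry Boolean gene-protein-reaction (GPR) expressions, plus a table of
Boolean regulatory rules over genes, transcription factors (TFs), flux predicates
and environmental stimuli.  Exchange fluxes follow the standard constraint-based
convention: uptake is a negative flux, secretion positive, and an
:class:`Environment` constrains exchange *lower* bounds (a glucose uptake rate of
18.5 mmol/gDW/hr becomes a lower bound of -18.5 on the glucose exchange).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "BoolExpr",
    "TrueExpr",
    "FalseExpr",
    "Ref",
    "FluxPred",
    "Not",
    "And",
    "Or",
    "RuleSyntaxError",
    "ModelValidationError",
    "parse_rule",
    "Metabolite",
    "Reaction",
    "Gene",
    "RegulatoryRule",
    "IntegratedModel",
    "Environment",
    "parse_equation",
    "load_model",
    "load_tabular_model",
    "build_example_network",
    "example_environment",
    "random_toy_model",
]


# ---------------------------------------------------------------------------
# Boolean expressions
# ---------------------------------------------------------------------------

class BoolExpr:
    """Base class for Boolean expression trees used by GPRs and rules."""

    def to_dict(self) -> dict:
        raise NotImplementedError

    @staticmethod
    def from_dict(d: dict) -> "BoolExpr":
        op = d["op"]
        if op == "true":
            return TrueExpr()
        if op == "false":
            return FalseExpr()
        if op == "ref":
            return Ref(d["name"])
        if op == "flux":
            return FluxPred(d["ref"], bool(d["positive"]), d.get("threshold"))
        if op == "not":
            return Not(BoolExpr.from_dict(d["child"]))
        if op in ("and", "or"):
            children = tuple(BoolExpr.from_dict(c) for c in d["children"])
            return And(children) if op == "and" else Or(children)
        raise ValueError(f"unknown expression op {op!r}")


@dataclass(frozen=True)
class TrueExpr(BoolExpr):
    """The always-true expression (empty rule, constitutive target)."""

    def to_dict(self) -> dict:
        return {"op": "true"}


@dataclass(frozen=True)
class FalseExpr(BoolExpr):
    def to_dict(self) -> dict:
        return {"op": "false"}


@dataclass(frozen=True)
class Ref(BoolExpr):
    """A named literal: gene, TF, or (if unresolvable) environmental stimulus."""

    name: str

    def to_dict(self) -> dict:
        return {"op": "ref", "name": self.name}


@dataclass(frozen=True)
class FluxPred(BoolExpr):
    """Flux predicate literal.

    ``positive=True`` means "flux through `ref` is positive" (v >= epsilon once
    compiled); ``positive=False`` the negative-flux counterpart (v <= -epsilon).
    The printed threshold of the source rule (e.g. the ``2`` in ``nh4(e)>2``) is
    kept as metadata only; the compiled indicator always uses the model-wide
    epsilon.
    """

    ref: str
    positive: bool = True
    threshold: float | None = None

    def to_dict(self) -> dict:
        return {"op": "flux", "ref": self.ref, "positive": self.positive,
                "threshold": self.threshold}


@dataclass(frozen=True)
class Not(BoolExpr):
    child: BoolExpr

    def to_dict(self) -> dict:
        return {"op": "not", "child": self.child.to_dict()}


@dataclass(frozen=True)
class And(BoolExpr):
    children: tuple[BoolExpr, ...]

    def to_dict(self) -> dict:
        return {"op": "and", "children": [c.to_dict() for c in self.children]}


@dataclass(frozen=True)
class Or(BoolExpr):
    children: tuple[BoolExpr, ...]

    def to_dict(self) -> dict:
        return {"op": "or", "children": [c.to_dict() for c in self.children]}


def expr_literals(expr: BoolExpr) -> list[BoolExpr]:
    """All Ref/FluxPred leaves of an expression tree."""
    if isinstance(expr, (Ref, FluxPred)):
        return [expr]
    if isinstance(expr, Not):
        return expr_literals(expr.child)
    if isinstance(expr, (And, Or)):
        out: list[BoolExpr] = []
        for c in expr.children:
            out.extend(expr_literals(c))
        return out
    return []


def eval_expr(expr: BoolExpr, assign) -> bool:
    """Evaluate a tree against ``assign``, a callable mapping literal -> bool."""
    if isinstance(expr, TrueExpr):
        return True
    if isinstance(expr, FalseExpr):
        return False
    if isinstance(expr, (Ref, FluxPred)):
        return bool(assign(expr))
    if isinstance(expr, Not):
        return not eval_expr(expr.child, assign)
    if isinstance(expr, And):
        return all(eval_expr(c, assign) for c in expr.children)
    if isinstance(expr, Or):
        return any(eval_expr(c, assign) for c in expr.children)
    raise TypeError(f"not an expression: {expr!r}")


# ---------------------------------------------------------------------------
# Rule parser
# ---------------------------------------------------------------------------

class RuleSyntaxError(ValueError):
    """Raised on malformed rule text; carries the offending position."""

    def __init__(self, message: str, text: str, pos: int):
        super().__init__(f"{message} at position {pos} in {text!r}")
        self.text = text
        self.pos = pos


_PRED_RE = re.compile(
    r"(?P<ref>[A-Za-z0-9_.\[\]-]+(?:\(e\))?)\s*>\s*(?P<thr>-?\d+(?:\.\d+)?)"
)
_IDENT_RE = re.compile(r"[A-Za-z0-9_.\[\]-]+")
_WS_RE = re.compile(r"\s+")


def _tokenize(text: str) -> list[tuple[str, object, int]]:
    tokens: list[tuple[str, object, int]] = []
    i, n = 0, len(text)
    while i < n:
        m = _WS_RE.match(text, i)
        if m:
            i = m.end()
            continue
        m = _PRED_RE.match(text, i)
        if m:
            ref = m.group("ref")
            tokens.append(("PRED", (ref, float(m.group("thr"))), i))
            i = m.end()
            continue
        m = _IDENT_RE.match(text, i)
        if m:
            word = m.group(0)
            low = word.lower()
            if low in ("and", "or", "not"):
                tokens.append((low.upper(), word, i))
            else:
                tokens.append(("IDENT", word, i))
            i = m.end()
            continue
        ch = text[i]
        if ch == "(":
            tokens.append(("LP", ch, i))
        elif ch == ")":
            tokens.append(("RP", ch, i))
        else:
            raise RuleSyntaxError(f"unexpected character {ch!r}", text, i)
        i += 1
    tokens.append(("EOF", None, n))
    return tokens


class _RuleParser:
    """Recursive-descent parser: OR < AND < NOT precedence, parentheses."""

    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos]

    def take(self, kind: str):
        tok = self.tokens[self.pos]
        if tok[0] != kind:
            raise RuleSyntaxError(f"expected {kind}, found {tok[0]}", self.text, tok[2])
        self.pos += 1
        return tok

    def parse(self) -> BoolExpr:
        expr = self.or_expr()
        tok = self.peek()
        if tok[0] != "EOF":
            raise RuleSyntaxError(f"trailing token {tok[0]}", self.text, tok[2])
        return expr

    def or_expr(self) -> BoolExpr:
        terms = [self.and_expr()]
        while self.peek()[0] == "OR":
            self.take("OR")
            terms.append(self.and_expr())
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def and_expr(self) -> BoolExpr:
        factors = [self.unary()]
        while self.peek()[0] == "AND":
            self.take("AND")
            factors.append(self.unary())
        return factors[0] if len(factors) == 1 else And(tuple(factors))

    def unary(self) -> BoolExpr:
        tok = self.peek()
        if tok[0] == "NOT":
            self.take("NOT")
            return Not(self.unary())
        if tok[0] == "LP":
            self.take("LP")
            expr = self.or_expr()
            self.take("RP")
            return expr
        if tok[0] == "PRED":
            self.take("PRED")
            ref, thr = tok[1]
            return FluxPred(ref, positive=True, threshold=thr)
        if tok[0] == "IDENT":
            self.take("IDENT")
            return Ref(tok[1])
        raise RuleSyntaxError(f"unexpected token {tok[0]}", self.text, tok[2])


def parse_rule(text: str) -> BoolExpr:
    """Parse a Boolean rule string into an expression tree.

    Grammar: identifiers, ``AND``/``OR``/``NOT`` (case-insensitive),
    parentheses, and flux predicates of the form ``rxn>0`` or ``met(e)>2``.
    Empty or whitespace-only text yields the always-true expression
    (constitutive target).  Unknown identifiers are resolved later during model
    validation; syntax errors raise :class:`RuleSyntaxError` with a position.
    """
    if text is None or not text.strip():
        return TrueExpr()
    return _RuleParser(text).parse()


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    is_extracellular: bool = False


@dataclass(frozen=True)
class Reaction:
    """A reaction with signed stoichiometry and flux bounds (mmol/gDW/hr).

    ``gpr`` is an AND/OR tree over gene literals, or None when the reaction has
    no known gene association (such reactions are never switched off by gene
    logic).  ``deletable`` marks candidates for reaction-level knockout
    designers.
    """

    id: str
    stoichiometry: Mapping[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    is_exchange: bool = False
    gpr: BoolExpr | None = None
    deletable: bool = True


@dataclass(frozen=True)
class Gene:
    id: str
    kind: str = "metabolic"  # "metabolic" | "transcription_factor"

    @property
    def is_tf(self) -> bool:
        return self.kind == "transcription_factor"


@dataclass(frozen=True)
class RegulatoryRule:
    """Boolean condition for the expression (gene) or activity (TF) of ``target``.

    Targets without a rule are constitutively expressed/active.
    """

    target: str
    expression: BoolExpr
    text: str | None = None


@dataclass(frozen=True)
class Environment:
    """Simulation condition: exchange lower bounds and active stimuli.

    ``uptake_bounds`` maps exchange reaction ids to *lower* bounds (uptake is
    negative, so a maximum uptake of 18.5 is the lower bound -18.5).  Stimuli
    not listed in ``active_stimuli`` are absent (their indicator is 0).
    """

    uptake_bounds: Mapping[str, float] = field(default_factory=dict)
    active_stimuli: frozenset[str] = frozenset()


class ModelValidationError(ValueError):
    pass


@dataclass
class IntegratedModel:
    """Metabolic network plus Boolean regulatory rules.

    Invariants (checked by :meth:`validate`): unique ids; every stoichiometric,
    GPR and rule literal references a declared object; GPRs contain no NOT;
    exchanges touch exactly one metabolite; the biomass reaction exists.
    """

    metabolites: dict[str, Metabolite]
    reactions: dict[str, Reaction]
    genes: dict[str, Gene]
    rules: dict[str, RegulatoryRule]
    biomass_reaction_id: str
    id: str = "model"

    # -- convenience views ---------------------------------------------------

    @property
    def metabolic_genes(self) -> list[str]:
        return [g for g, gene in self.genes.items() if not gene.is_tf]

    @property
    def transcription_factors(self) -> list[str]:
        return [g for g, gene in self.genes.items() if gene.is_tf]

    @property
    def exchanges(self) -> list[str]:
        return [j for j, r in self.reactions.items() if r.is_exchange]

    def stimuli(self) -> set[str]:
        """Identifiers used in rules that are neither genes nor TFs (ES literals)."""
        out: set[str] = set()
        for rule in self.rules.values():
            for lit in expr_literals(rule.expression):
                if isinstance(lit, Ref) and lit.name not in self.genes:
                    out.add(lit.name)
        return out

    def resolve_flux_ref(self, ref: str) -> str:
        """Map a flux-predicate reference to a reaction id.

        Accepts a reaction id directly, or an extracellular metabolite
        (``glc`` or ``glc(e)`` style), which resolves to its exchange reaction.
        """
        if ref in self.reactions:
            return ref
        met = ref[:-3] if ref.endswith("(e)") else ref
        candidates = [met, met + "_e", met + "(e)", met + "[e]"]
        for mid in candidates:
            if mid in self.metabolites and self.metabolites[mid].is_extracellular:
                for j, rxn in self.reactions.items():
                    if rxn.is_exchange and mid in rxn.stoichiometry:
                        return j
        raise ModelValidationError(
            f"flux predicate reference {ref!r} matches no reaction or "
            f"extracellular metabolite with an exchange"
        )

    # -- linear algebra ------------------------------------------------------

    def stoichiometric_matrix(self):
        """Dense S matrix with row/column index mappings (mets x reactions)."""
        mets = list(self.metabolites)
        rxns = list(self.reactions)
        mi = {m: i for i, m in enumerate(mets)}
        S = np.zeros((len(mets), len(rxns)))
        for j, rid in enumerate(rxns):
            for m, coef in self.reactions[rid].stoichiometry.items():
                S[mi[m], j] = coef
        return S, mets, rxns

    # -- validation ----------------------------------------------------------

    def validate(self) -> "IntegratedModel":
        for j, rxn in self.reactions.items():
            if not rxn.stoichiometry:
                raise ModelValidationError(f"reaction {j} has empty stoichiometry")
            if rxn.lower_bound > rxn.upper_bound:
                raise ModelValidationError(f"reaction {j}: lower bound exceeds upper")
            for m in rxn.stoichiometry:
                if m not in self.metabolites:
                    raise ModelValidationError(
                        f"reaction {j} references undeclared metabolite {m!r}")
            if rxn.is_exchange and len(rxn.stoichiometry) != 1:
                raise ModelValidationError(
                    f"exchange reaction {j} must touch exactly one metabolite")
            if rxn.gpr is not None:
                self._check_gpr(j, rxn.gpr)
        if self.biomass_reaction_id not in self.reactions:
            raise ModelValidationError(
                f"biomass reaction {self.biomass_reaction_id!r} not in model")
        seen_targets = set()
        for target, rule in self.rules.items():
            if rule.target != target:
                raise ModelValidationError(f"rule key/target mismatch for {target}")
            if target in seen_targets:
                raise ModelValidationError(f"duplicate rule for target {target}")
            seen_targets.add(target)
            if target not in self.genes:
                raise ModelValidationError(f"rule target {target!r} is not a declared gene/TF")
            for lit in expr_literals(rule.expression):
                if isinstance(lit, FluxPred):
                    try:
                        self.resolve_flux_ref(lit.ref)
                    except ModelValidationError as exc:
                        raise ModelValidationError(
                            f"rule for {target!r}: {exc}") from None
        return self

    def _check_gpr(self, rxn_id: str, expr: BoolExpr) -> None:
        if isinstance(expr, Not):
            raise ModelValidationError(f"GPR of {rxn_id} contains NOT")
        if isinstance(expr, FluxPred):
            raise ModelValidationError(f"GPR of {rxn_id} contains a flux predicate")
        if isinstance(expr, Ref):
            if expr.name not in self.genes:
                raise ModelValidationError(
                    f"GPR of {rxn_id} references undeclared gene {expr.name!r}")
            return
        if isinstance(expr, (And, Or)):
            for c in expr.children:
                self._check_gpr(rxn_id, c)
            return
        if isinstance(expr, (TrueExpr, FalseExpr)):
            return
        raise ModelValidationError(f"GPR of {rxn_id}: bad node {expr!r}")

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "biomass_reaction_id": self.biomass_reaction_id,
            "metabolites": [
                {"id": m.id, "name": m.name, "compartment": m.compartment,
                 "is_extracellular": m.is_extracellular}
                for m in self.metabolites.values()
            ],
            "reactions": [
                {"id": r.id, "stoichiometry": dict(r.stoichiometry),
                 "lower_bound": r.lower_bound, "upper_bound": r.upper_bound,
                 "is_exchange": r.is_exchange, "deletable": r.deletable,
                 "gpr": None if r.gpr is None else r.gpr.to_dict()}
                for r in self.reactions.values()
            ],
            "genes": [{"id": g.id, "kind": g.kind} for g in self.genes.values()],
            "rules": [
                {"target": ru.target, "expression": ru.expression.to_dict(),
                 "text": ru.text}
                for ru in self.rules.values()
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IntegratedModel":
        model = cls(
            metabolites={m["id"]: Metabolite(**m) for m in d["metabolites"]},
            reactions={
                r["id"]: Reaction(
                    id=r["id"], stoichiometry=dict(r["stoichiometry"]),
                    lower_bound=r["lower_bound"], upper_bound=r["upper_bound"],
                    is_exchange=r["is_exchange"], deletable=r["deletable"],
                    gpr=None if r["gpr"] is None else BoolExpr.from_dict(r["gpr"]))
                for r in d["reactions"]
            },
            genes={g["id"]: Gene(**g) for g in d["genes"]},
            rules={
                ru["target"]: RegulatoryRule(
                    ru["target"], BoolExpr.from_dict(ru["expression"]),
                    ru.get("text"))
                for ru in d["rules"]
            },
            biomass_reaction_id=d["biomass_reaction_id"],
            id=d.get("id", "model"),
        )
        return model.validate()

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "IntegratedModel":
        text = str(source)
        if "{" not in text:  # a path, not serialized content
            text = Path(source).read_text()
        return cls.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# Tabular / SBML readers
# ---------------------------------------------------------------------------

_ARROWS = ("<=>", "<->", "-->", "->", "=>")


def parse_equation(eq: str) -> tuple[dict[str, float], bool]:
    """Parse ``"A + 2 B -> C"`` into a stoichiometry dict; returns (stoich, reversible).

    A missing right side (``"A ->"``) defines an exchange/sink style reaction.
    """
    arrow = None
    for a in _ARROWS:
        if a in eq:
            arrow = a
            break
    if arrow is None:
        raise ModelValidationError(f"no arrow in reaction equation {eq!r}")
    left, right = eq.split(arrow, 1)
    reversible = arrow in ("<=>", "<->")
    stoich: dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for part in side.split("+"):
            part = part.strip()
            if not part:
                continue
            bits = part.split()
            if len(bits) == 2:
                coef, met = float(bits[0]), bits[1]
            elif len(bits) == 1:
                coef, met = 1.0, bits[0]
            else:
                raise ModelValidationError(f"malformed term {part!r} in {eq!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coef

    add_side(left, -1.0)
    add_side(right, +1.0)
    stoich = {m: c for m, c in stoich.items() if c != 0.0}
    if not stoich:
        raise ModelValidationError(f"equation {eq!r} cancels to nothing")
    return stoich, reversible


def _read_tsv(path: Path) -> list[dict[str, str]]:
    import csv

    with open(path, newline="") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def load_tabular_model(reactions_tsv: str | Path,
                       rules_tsv: str | Path | None = None,
                       metabolites_tsv: str | Path | None = None,
                       biomass_reaction_id: str | None = None,
                       model_id: str = "model") -> IntegratedModel:
    """Read the plain-text dialect.

    ``reactions.tsv`` columns: id, equation, lb, ub, gpr (gpr optional/empty).
    ``rules.tsv`` columns: target, rule.  ``metabolites.tsv`` (optional)
    columns: id, name, compartment.  Metabolites absent from the sidecar are
    inferred from equations; ids ending in ``_e``, ``(e)`` or ``[e]`` are
    extracellular.  Metabolites that appear in exactly one reaction and that
    reaction only get an implicit classification as exchange species.
    """
    reactions_tsv = Path(reactions_tsv)
    rows = _read_tsv(reactions_tsv)
    declared: dict[str, Metabolite] = {}
    if metabolites_tsv is not None:
        for m in _read_tsv(Path(metabolites_tsv)):
            ext = m.get("compartment", "c") == "e" or m.get(
                "is_extracellular", "").lower() in ("1", "true", "yes")
            declared[m["id"]] = Metabolite(
                m["id"], m.get("name", ""), m.get("compartment", "c"), ext)

    reactions: dict[str, Reaction] = {}
    mets: dict[str, Metabolite] = dict(declared)
    for row in rows:
        rid = row["id"].strip()
        if rid in reactions:
            raise ModelValidationError(f"duplicate reaction id {rid!r}")
        try:
            stoich, reversible = parse_equation(row["equation"])
        except ModelValidationError as exc:
            raise ModelValidationError(f"reaction {rid!r}: {exc}") from None
        lb = float(row.get("lb") or (-1000.0 if reversible else 0.0))
        ub = float(row.get("ub") or 1000.0)
        gpr_text = (row.get("gpr") or "").strip()
        gpr = parse_rule(gpr_text) if gpr_text else None
        if isinstance(gpr, TrueExpr):
            gpr = None
        is_exchange = len(stoich) == 1
        for m in stoich:
            if m not in mets:
                ext = m.endswith(("_e", "(e)", "[e]"))
                mets[m] = Metabolite(m, compartment="e" if ext else "c",
                                     is_extracellular=ext)
        reactions[rid] = Reaction(rid, stoich, lb, ub, is_exchange, gpr,
                                  deletable=not is_exchange)

    gpr_genes: set[str] = set()
    for rxn in reactions.values():
        if rxn.gpr is not None:
            for lit in expr_literals(rxn.gpr):
                if isinstance(lit, Ref):
                    gpr_genes.add(lit.name)

    rules: dict[str, RegulatoryRule] = {}
    if rules_tsv is not None:
        for row in _read_tsv(Path(rules_tsv)):
            target = row["target"].strip()
            if target in rules:
                raise ModelValidationError(f"duplicate rule for {target!r}")
            rules[target] = RegulatoryRule(target, parse_rule(row.get("rule") or ""),
                                           row.get("rule"))

    # Gene kinds: GPR genes are metabolic; rule targets never used in a GPR
    # are transcription factors.
    genes: dict[str, Gene] = {g: Gene(g, "metabolic") for g in sorted(gpr_genes)}
    for target in rules:
        if target not in genes:
            genes[target] = Gene(target, "transcription_factor")
    # rule effectors that are rule targets or GPR genes stay as-is; anything
    # else is an environmental stimulus and needs no declaration.

    if biomass_reaction_id is None:
        cands = [j for j in reactions if "biomass" in j.lower()]
        if len(cands) != 1:
            raise ModelValidationError(
                "biomass reaction not given and not uniquely inferable")
        biomass_reaction_id = cands[0]

    model = IntegratedModel(mets, reactions, genes, rules,
                            biomass_reaction_id, id=model_id)
    return model.validate()


def load_model(metabolic_source: str | Path,
               rules_source: str | Path | None = None,
               biomass_reaction_id: str | None = None) -> IntegratedModel:
    """Load an integrated model from SBML or the tabular/JSON dialect.

    ``metabolic_source`` may be an SBML file (``.xml``/``.sbml``, read through
    cobrapy), a serialized model (``.json``), or a ``reactions.tsv``;
    ``rules_source`` is a two-column TSV (target, rule).
    """
    src = Path(metabolic_source)
    if src.suffix in (".xml", ".sbml"):
        return _load_sbml(src, rules_source, biomass_reaction_id)
    if src.suffix == ".json":
        model = IntegratedModel.from_json(src)
        if rules_source is not None:
            raise ModelValidationError("JSON models already embed their rules")
        return model
    return load_tabular_model(src, rules_source,
                              biomass_reaction_id=biomass_reaction_id)


def _load_sbml(path: Path, rules_source, biomass_reaction_id) -> IntegratedModel:
    import cobra

    cm = cobra.io.read_sbml_model(str(path))
    mets = {
        m.id: Metabolite(m.id, m.name or "", m.compartment or "c",
                         is_extracellular=(m.compartment or "").lower().startswith("e"))
        for m in cm.metabolites
    }
    reactions: dict[str, Reaction] = {}
    for r in cm.reactions:
        gpr_text = r.gene_reaction_rule
        gpr = parse_rule(gpr_text) if gpr_text else None
        if isinstance(gpr, TrueExpr):
            gpr = None
        is_ex = len(r.metabolites) == 1
        reactions[r.id] = Reaction(
            r.id, {m.id: c for m, c in r.metabolites.items()},
            float(r.lower_bound), float(r.upper_bound), is_ex, gpr,
            deletable=not is_ex)
    genes = {g.id: Gene(g.id, "metabolic") for g in cm.genes}
    rules: dict[str, RegulatoryRule] = {}
    if rules_source is not None:
        for row in _read_tsv(Path(rules_source)):
            t = row["target"].strip()
            rules[t] = RegulatoryRule(t, parse_rule(row.get("rule") or ""),
                                      row.get("rule"))
            if t not in genes:
                genes[t] = Gene(t, "transcription_factor")
    if biomass_reaction_id is None:
        if cm.objective is not None:
            obj = [r.id for r in cm.reactions
                   if r.objective_coefficient not in (0, None)]
            if len(obj) == 1:
                biomass_reaction_id = obj[0]
    if biomass_reaction_id is None:
        cands = [j for j in reactions if "biomass" in j.lower()]
        if len(cands) != 1:
            raise ModelValidationError("cannot infer biomass reaction from SBML")
        biomass_reaction_id = cands[0]
    return IntegratedModel(mets, reactions, genes, rules,
                           biomass_reaction_id, id=cm.id or "sbml").validate()


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

def build_example_network() -> IntegratedModel:
    """Small didactic network with one transcription factor.

    A substrate S can reach biomass B via two branches: R1 (enzyme of two
    subunits G1A+G1B) feeds I1, converted by R2 into by-product P1 plus 0.08 B;
    R3 (G3) and R4 (G4) feed I2, converted by R5 (isozymes G5 or G6) into
    by-product P2 plus 0.12 B.  TF1 is active whenever S is taken up, activates
    G3 and G5 and represses G1A; every other gene is constitutive.  Maximizing
    growth therefore prefers the P2 branch, and P1 production is uncoupled
    until the network is re-engineered.
    """
    mets = {
        "S": Metabolite("S", "substrate"),
        "I1": Metabolite("I1", "intermediate 1"),
        "I2": Metabolite("I2", "intermediate 2"),
        "P1": Metabolite("P1", "by-product 1"),
        "P2": Metabolite("P2", "by-product 2"),
        "B": Metabolite("B", "biomass"),
    }
    rxns = {
        "R1": Reaction("R1", {"S": -1, "I1": 1}, 0, 1000, gpr=parse_rule("G1A and G1B")),
        "R2": Reaction("R2", {"I1": -1, "P1": 1, "B": 0.08}, 0, 1000,
                       gpr=parse_rule("G2")),
        "R3": Reaction("R3", {"S": -1, "I2": 1}, 0, 1000, gpr=parse_rule("G3")),
        "R4": Reaction("R4", {"I1": -1, "I2": 1}, 0, 1000, gpr=parse_rule("G4")),
        "R5": Reaction("R5", {"I2": -1, "P2": 1, "B": 0.12}, 0, 1000,
                       gpr=parse_rule("G5 or G6")),
        "EX_S": Reaction("EX_S", {"S": -1}, 0, 1000, is_exchange=True, deletable=False),
        "EX_P1": Reaction("EX_P1", {"P1": -1}, 0, 1000, is_exchange=True, deletable=False),
        "EX_P2": Reaction("EX_P2", {"P2": -1}, 0, 1000, is_exchange=True, deletable=False),
        "EX_B": Reaction("EX_B", {"B": -1}, 0, 1000, is_exchange=True, deletable=False),
    }
    genes = {g: Gene(g) for g in ("G1A", "G1B", "G2", "G3", "G4", "G5", "G6")}
    genes["TF1"] = Gene("TF1", "transcription_factor")
    rules = {
        # TF1 senses substrate uptake: negative flux through the S exchange.
        "TF1": RegulatoryRule("TF1", parse_rule("not (EX_S > 0)"), "not (EX_S > 0)"),
        "G3": RegulatoryRule("G3", parse_rule("TF1"), "TF1"),
        "G5": RegulatoryRule("G5", parse_rule("TF1"), "TF1"),
        "G1A": RegulatoryRule("G1A", parse_rule("not TF1"), "not TF1"),
    }
    return IntegratedModel(mets, rxns, genes, rules, "EX_B", id="example").validate()


def example_environment(uptake: float = 10.0) -> Environment:
    """Environment for the example network: substrate uptake up to ``uptake``."""
    return Environment(uptake_bounds={"EX_S": -float(uptake)})


# ---------------------------------------------------------------------------
# Random toy generator
# ---------------------------------------------------------------------------

def random_toy_model(n_reactions: int = 8, n_genes: int = 8, n_tfs: int = 2,
                     seed: int = 0) -> tuple[IntegratedModel, Environment]:
    """Seeded random small network for oracle testing.

    Construction guarantees: a substrate-to-biomass path always exists; every
    internal metabolite is produced and consumed by at least one reaction; two
    secreted by-products with exchanges (``EX_P1`` is the natural design
    product); GPRs mix single genes, isozyme pairs and two-subunit complexes
    (some reactions have none); regulatory rules use TF and stimulus effectors
    only, with an acyclic TF dependency structure, so that Boolean states can
    be enumerated exactly by a brute-force oracle.  Identical seeds give
    identical models.
    """
    if n_reactions > 15:
        raise ValueError("random_toy_model is meant for small networks (<= 15 reactions)")
    rng = np.random.default_rng(seed)
    n_mid = max(2, n_reactions // 2)
    met_ids = ["S"] + [f"M{i}" for i in range(1, n_mid + 1)]
    mets = {m: Metabolite(m) for m in met_ids}
    for extra in ("P1", "P2", "B"):
        mets[extra] = Metabolite(extra)

    reactions: dict[str, Reaction] = {}
    consumed: set[str] = set()
    k = 0

    # backbone chain S -> M1 -> ... -> Mn so a route to biomass always exists
    chain = ["S"] + [f"M{i}" for i in range(1, n_mid + 1)]
    for a, b in zip(chain, chain[1:]):
        k += 1
        reactions[f"R{k}"] = Reaction(f"R{k}", {a: -1.0, b: 1.0}, 0, 1000)
        consumed.add(a)
    # extra cross edges between earlier and later internal metabolites
    while k < n_reactions - 2:
        k += 1
        i = int(rng.integers(0, len(chain) - 1))
        j = int(rng.integers(i + 1, len(chain)))
        coef = float(rng.choice([1.0, 1.0, 2.0]))
        reactions[f"R{k}"] = Reaction(f"R{k}", {chain[i]: -1.0, chain[j]: coef},
                                      0, 1000)
        consumed.add(chain[i])
    # two terminal reactions draining the chain end into biomass + by-products
    end = chain[-1]
    y1 = float(np.round(rng.uniform(0.05, 0.15), 3))
    y2 = float(np.round(rng.uniform(0.1, 0.3), 3))
    k += 1
    reactions[f"R{k}"] = Reaction(f"R{k}", {end: -1.0, "P1": 1.0, "B": y1}, 0, 1000)
    k += 1
    reactions[f"R{k}"] = Reaction(f"R{k}", {end: -1.0, "P2": 1.0, "B": y2}, 0, 1000)
    consumed.add(end)
    internal = list(reactions)

    for ex, met in (("EX_S", "S"), ("EX_P1", "P1"), ("EX_P2", "P2"), ("EX_B", "B")):
        reactions[ex] = Reaction(ex, {met: -1.0}, 0, 1000, is_exchange=True,
                                 deletable=False)

    gene_ids = [f"g{i}" for i in range(n_genes)]
    tf_ids = [f"tf{i}" for i in range(n_tfs)]
    genes = {g: Gene(g) for g in gene_ids}
    genes.update({t: Gene(t, "transcription_factor") for t in tf_ids})

    def random_gpr() -> BoolExpr | None:
        u = rng.uniform()
        if u < 0.1:
            return None
        if u < 0.55:
            return Ref(str(rng.choice(gene_ids)))
        a, b = rng.choice(gene_ids, size=2, replace=False)
        if u < 0.8:
            return Or((Ref(str(a)), Ref(str(b))))
        return And((Ref(str(a)), Ref(str(b))))

    rxns2: dict[str, Reaction] = {}
    for j, rxn in reactions.items():
        gpr = random_gpr() if j in internal else None
        rxns2[j] = replace(rxn, gpr=gpr)
    reactions = rxns2

    rules: dict[str, RegulatoryRule] = {}
    # tf0 constitutively active; later TFs depend on earlier TFs or a stimulus
    for i, t in enumerate(tf_ids):
        if i == 0:
            text = ""
        else:
            u = rng.uniform()
            if u < 0.3:
                text = "STRESS"
            elif u < 0.65:
                text = str(rng.choice(tf_ids[:i]))
            else:
                text = f"not {rng.choice(tf_ids[:i])}"
        rules[t] = RegulatoryRule(t, parse_rule(text), text)
    for g in gene_ids:
        if rng.uniform() < 0.35 and tf_ids:
            t = str(rng.choice(tf_ids))
            text = t if rng.uniform() < 0.5 else f"not {t}"
            rules[g] = RegulatoryRule(g, parse_rule(text), text)

    model = IntegratedModel(mets, reactions, genes, rules, "EX_B",
                            id=f"toy-{seed}").validate()
    env = Environment(uptake_bounds={"EX_S": -10.0})
    return model, env
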