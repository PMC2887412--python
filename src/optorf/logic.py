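"""Compile GPR and regulatory Boolean structures to indexed DNF form.

The designers need every Boolean relationship in a linearizable shape:

* a GPR becomes an OR of enzyme complexes, each complex an AND over its
  subunit genes (:class:`GPRIndex`);
* a regulatory rule becomes an OR of conditions, each condition an AND over
  activator effectors (which must be on) and repressor effectors (which must
  be off) (:class:`RegulatoryIndex`).  Effectors are TF/gene states, positive
  or negative flux indicators (threshold epsilon, default 1e-3), or
  environmental stimuli.

This module also evaluates Boolean states directly (no solver), which serves
both simulation readout and independent consistency checking of MILP output.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .model import (And, BoolExpr, Environment, FalseExpr, FluxPred,
                    IntegratedModel, Not, Or, Ref, TrueExpr)

__all__ = [
    "GPRIndex",
    "RegulatoryIndex",
    "Effector",
    "Condition",
    "PerturbationVars",
    "BooleanState",
    "DnfBlowupError",
    "ConsistencyError",
    "PerturbationError",
    "compile_gpr",
    "compile_regulation",
    "apply_perturbations",
    "reaction_feasibility",
    "evaluate_state",
]

DEFAULT_EPSILON = 1e-3


class DnfBlowupError(ValueError):
    pass


class ConsistencyError(ValueError):
    """No consistent Boolean assignment exists (contradictory regulatory cycle)."""


class PerturbationError(ValueError):
    """Deletion of an unexpressed gene or overexpression of an expressed one."""


# ---------------------------------------------------------------------------
# DNF machinery
# ---------------------------------------------------------------------------

# a DNF term: (positive literals, negative literals); literals are Ref or
# FluxPred nodes.  Negation parity on a flux predicate flips its direction and
# keeps it positive, so negative literals are always plain Refs.
Term = tuple[frozenset, frozenset]


def _nnf(expr: BoolExpr, negate: bool = False) -> BoolExpr:
    """Push NOT down to literals, folding predicate negation into direction."""
    if isinstance(expr, TrueExpr):
        return FalseExpr() if negate else expr
    if isinstance(expr, FalseExpr):
        return TrueExpr() if negate else expr
    if isinstance(expr, Ref):
        return Not(expr) if negate else expr
    if isinstance(expr, FluxPred):
        if negate:
            return FluxPred(expr.ref, not expr.positive, expr.threshold)
        return expr
    if isinstance(expr, Not):
        return _nnf(expr.child, not negate)
    if isinstance(expr, And):
        children = tuple(_nnf(c, negate) for c in expr.children)
        return Or(children) if negate else And(children)
    if isinstance(expr, Or):
        children = tuple(_nnf(c, negate) for c in expr.children)
        return And(children) if negate else Or(children)
    raise TypeError(f"not an expression: {expr!r}")


def _dnf_terms(expr: BoolExpr, cap: int) -> list[Term] | None:
    """DNF as a list of terms; None encodes FALSE, [(empty, empty)] TRUE."""
    if isinstance(expr, TrueExpr):
        return [(frozenset(), frozenset())]
    if isinstance(expr, FalseExpr):
        return []
    if isinstance(expr, (Ref, FluxPred)):
        return [(frozenset([expr]), frozenset())]
    if isinstance(expr, Not):  # after NNF the child is a Ref
        return [(frozenset(), frozenset([expr.child]))]
    if isinstance(expr, Or):
        out: list[Term] = []
        for c in expr.children:
            out.extend(_dnf_terms(c, cap))
            if len(out) > cap:
                raise DnfBlowupError("DNF term cap exceeded")
        return out
    if isinstance(expr, And):
        out = [(frozenset(), frozenset())]
        for c in expr.children:
            child_terms = _dnf_terms(c, cap)
            nxt: list[Term] = []
            for (p1, n1), (p2, n2) in itertools.product(out, child_terms):
                pos, neg = p1 | p2, n1 | n2
                if pos & neg:
                    continue  # contradictory term: x AND NOT x
                nxt.append((pos, neg))
                if len(nxt) > cap:
                    raise DnfBlowupError("DNF term cap exceeded")
            out = nxt
        return out
    raise TypeError(f"not an expression: {expr!r}")


def _absorb(terms: list[Term]) -> list[Term]:
    """Drop duplicate terms and terms subsumed by a smaller term."""
    uniq = list(dict.fromkeys(terms))
    keep: list[Term] = []
    for t in sorted(uniq, key=lambda t: (len(t[0]) + len(t[1]))):
        p, n = t
        if any(p2 <= p and n2 <= n for p2, n2 in keep):
            continue
        keep.append(t)
    return keep


def to_dnf(expr: BoolExpr, cap: int = 256) -> list[Term]:
    """Disjunctive normal form with absorption pruning.

    Returns a list of (positive, negative) literal sets; an empty list means
    the expression is unsatisfiable, a single empty term means it is a
    tautology.
    """
    terms = _dnf_terms(_nnf(expr), cap)
    return _absorb(terms)


# ---------------------------------------------------------------------------
# Indices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Effector:
    """One regulatory input: kind TF (gene/TF state), PF/NF (flux), or ES."""

    kind: str  # "TF" | "PF" | "NF" | "ES"
    ref: str


@dataclass(frozen=True)
class Condition:
    """One DNF condition: all activators on and all repressors off."""

    activators: tuple[Effector, ...]
    repressors: tuple[Effector, ...]


@dataclass
class GPRIndex:
    """Per reaction in J_GPR: list of enzyme complexes, each a gene set."""

    complexes: dict[str, tuple[frozenset[str], ...]]

    @property
    def reactions(self) -> list[str]:
        return list(self.complexes)

    def __contains__(self, rxn_id: str) -> bool:
        return rxn_id in self.complexes

    def genes(self) -> set[str]:
        out: set[str] = set()
        for cxs in self.complexes.values():
            for cx in cxs:
                out |= cx
        return out

    def to_triples(self) -> list[tuple[str, int, str]]:
        """(reaction, complex index, gene) triples, the array form of the index."""
        return [(j, n, g)
                for j, cxs in self.complexes.items()
                for n, cx in enumerate(cxs)
                for g in sorted(cx)]


@dataclass
class RegulatoryIndex:
    """Per target: DNF condition list; plus the flux-indicator threshold.

    Every declared gene/TF appears as a target.  Targets without a rule get a
    single empty condition (constitutively on); targets whose rule reduces to
    FALSE get no conditions (never on).
    """

    conditions: dict[str, tuple[Condition, ...]]
    epsilon: float = DEFAULT_EPSILON

    def effectors(self) -> list[Effector]:
        seen: dict[Effector, None] = {}
        for conds in self.conditions.values():
            for cond in conds:
                for e in cond.activators + cond.repressors:
                    seen[e] = None
        return list(seen)

    def flux_effectors(self) -> list[Effector]:
        return [e for e in self.effectors() if e.kind in ("PF", "NF")]

    def to_triples(self) -> list[tuple[str, int, str, str, str]]:
        """(target, condition index, effector ref, kind, role) tuples."""
        out = []
        for g, conds in self.conditions.items():
            for m, cond in enumerate(conds):
                for e in cond.activators:
                    out.append((g, m, e.ref, e.kind, "activator"))
                for e in cond.repressors:
                    out.append((g, m, e.ref, e.kind, "repressor"))
        return out


def compile_gpr(model: IntegratedModel, term_cap: int = 256) -> GPRIndex:
    """DNF-expand every GPR into isozyme complexes.

    Reactions without a GPR are absent from the index and are never
    flux-constrained by gene logic.
    """
    complexes: dict[str, tuple[frozenset[str], ...]] = {}
    for j, rxn in model.reactions.items():
        if rxn.gpr is None:
            continue
        try:
            terms = to_dnf(rxn.gpr, term_cap)
        except DnfBlowupError:
            raise DnfBlowupError(f"GPR of reaction {j} exceeds {term_cap} DNF terms")
        cxs = []
        for pos, neg in terms:
            if neg:
                raise ValueError(f"GPR of reaction {j} contains NOT")
            genes = frozenset(lit.name for lit in pos)
            if not genes:
                # tautological GPR: treat as no association
                cxs = None
                break
            cxs.append(genes)
        if cxs:
            complexes[j] = tuple(cxs)
    return GPRIndex(complexes)


def _literal_to_effector(model: IntegratedModel, lit, negated: bool) -> Effector:
    if isinstance(lit, FluxPred):
        rxn = model.resolve_flux_ref(lit.ref)
        kind = "PF" if lit.positive else "NF"
        return Effector(kind, rxn)
    name = lit.name
    if name in model.genes:
        return Effector("TF", name)
    return Effector("ES", name)


def compile_regulation(model: IntegratedModel, epsilon: float = DEFAULT_EPSILON,
                       term_cap: int = 256) -> RegulatoryIndex:
    """Compile every rule to DNF conditions over typed effectors.

    Positive literals become activators; negated gene/stimulus literals become
    repressors; negated flux predicates flip direction (NOT "v positive"
    compiles to a negative-flux activator, matching how uptake sensing is
    written in rules).
    """
    conditions: dict[str, tuple[Condition, ...]] = {}
    for g in model.genes:
        rule = model.rules.get(g)
        if rule is None:
            conditions[g] = (Condition((), ()),)
            continue
        try:
            terms = to_dnf(rule.expression, term_cap)
        except DnfBlowupError:
            raise DnfBlowupError(f"rule for {g} exceeds {term_cap} DNF terms")
        conds = []
        for pos, neg in terms:
            acts = tuple(sorted((_literal_to_effector(model, l, False) for l in pos),
                                key=lambda e: (e.kind, e.ref)))
            reps = tuple(sorted((_literal_to_effector(model, l, True) for l in neg),
                                key=lambda e: (e.kind, e.ref)))
            conds.append(Condition(acts, reps))
        conditions[g] = tuple(conds)
    return RegulatoryIndex(conditions, epsilon)


# ---------------------------------------------------------------------------
# Perturbations and state evaluation
# ---------------------------------------------------------------------------

@dataclass
class PerturbationVars:
    """Gene deletions (z), metabolic-gene overexpressions (w) and caps."""

    z: dict[str, bool] = field(default_factory=dict)
    w: dict[str, bool] = field(default_factory=dict)
    k1: int | None = None
    k2: int | None = None

    def __post_init__(self):
        self.z = {g: bool(v) for g, v in self.z.items() if v}
        self.w = {g: bool(v) for g, v in self.w.items() if v}
        both = set(self.z) & set(self.w)
        if both:
            raise PerturbationError(
                f"genes cannot be deleted and overexpressed at once: {sorted(both)}")
        if self.k1 is not None and len(self.z) > self.k1:
            raise PerturbationError("deletion cap K1 exceeded")
        if self.k2 is not None and len(self.w) > self.k2:
            raise PerturbationError("overexpression cap K2 exceeded")

    def validate_against(self, model: IntegratedModel) -> "PerturbationVars":
        for g in list(self.z) + list(self.w):
            if g not in model.genes:
                raise PerturbationError(f"unknown gene {g!r}")
        tfs = {g for g in self.w if model.genes[g].is_tf}
        if tfs:
            raise PerturbationError(
                f"transcription factors cannot be overexpressed: {sorted(tfs)}")
        return self

    @classmethod
    def from_sets(cls, deletions: Iterable[str] = (), overexpressions: Iterable[str] = (),
                  k1: int | None = None, k2: int | None = None) -> "PerturbationVars":
        return cls({g: True for g in deletions}, {g: True for g in overexpressions},
                   k1, k2)


def apply_perturbations(y: bool, z: bool, w: bool) -> bool:
    """Surrogate expression of one gene given deletion/overexpression flags.

    Deletion is only defined for an expressed gene, overexpression only for a
    repressed one; violating either is a contract error, not a no-op.
    """
    if z and w:
        raise PerturbationError("a gene cannot be deleted and overexpressed")
    if z and not y:
        raise PerturbationError("deletion of an unexpressed gene is not allowed")
    if w and y:
        raise PerturbationError("overexpression of an expressed gene is not allowed")
    return (y and not z) or (not y and w)


def _forced_expression(y: bool, z: bool, w: bool) -> bool:
    """Forcing semantics used for fixed-design audits: z wins, then w, then y."""
    if z:
        return False
    if w:
        return True
    return y


def reaction_feasibility(index: GPRIndex, y_hat: Mapping[str, bool],
                         reaction_ids: Iterable[str] | None = None) -> dict[str, bool]:
    """Reaction feasibility d from surrogate expression: OR over complexes of
    AND over subunits; reactions outside the index are always feasible."""
    d: dict[str, bool] = {}
    if reaction_ids is not None:
        for j in reaction_ids:
            d[j] = True
    for j, cxs in index.complexes.items():
        d[j] = any(all(y_hat[g] for g in cx) for cx in cxs)
    return d


@dataclass
class BooleanState:
    """A consistent assignment of all Boolean variables of the logic system."""

    y: dict[str, bool]                       # gene expression / TF activity
    y_hat: dict[str, bool]                   # surrogate (after z/w)
    a: dict[tuple[str, int], bool]           # condition satisfaction
    x: dict[Effector, bool]                  # effector status
    b: dict[tuple[str, int], bool]           # enzyme-complex presence
    d: dict[str, bool]                       # reaction feasibility


def _condition_value(cond: Condition, x: Mapping[Effector, bool]) -> bool:
    return (all(x[e] for e in cond.activators)
            and not any(x[e] for e in cond.repressors))


def evaluate_state(reg: RegulatoryIndex, gpr: GPRIndex, env: Environment,
                   flux: Mapping[str, float],
                   perturb: PerturbationVars | None = None,
                   reaction_ids: Iterable[str] | None = None,
                   max_cycle: int = 16) -> BooleanState:
    """Evaluate the Boolean system at fixed fluxes and stimuli.

    Flux indicators are read off ``flux`` with the index threshold; stimuli
    absent from the environment are inactive.  TF-over-TF dependencies are
    resolved along the condensation of the dependency graph; inside a
    nontrivial strongly connected component every assignment is enumerated and
    the first consistent one in a deterministic most-expressed-first order is
    returned.  A contradictory cycle raises :class:`ConsistencyError` naming
    its members.
    """
    perturb = perturb or PerturbationVars()
    eps = reg.epsilon
    x: dict[Effector, bool] = {}
    for e in reg.effectors():
        if e.kind == "PF":
            x[e] = flux[e.ref] >= eps
        elif e.kind == "NF":
            x[e] = flux[e.ref] <= -eps
        elif e.kind == "ES":
            x[e] = e.ref in env.active_stimuli

    # dependency graph over targets via gene-state effectors
    graph = nx.DiGraph()
    graph.add_nodes_from(reg.conditions)
    for g, conds in reg.conditions.items():
        for cond in conds:
            for e in cond.activators + cond.repressors:
                if e.kind == "TF" and e.ref in reg.conditions:
                    graph.add_edge(e.ref, g)

    y: dict[str, bool] = {}
    y_hat: dict[str, bool] = {}

    def settle(g: str) -> None:
        yv = any(_condition_value(c, x) for c in reg.conditions[g])
        y[g] = yv
        y_hat[g] = _forced_expression(yv, g in perturb.z, g in perturb.w)
        x[Effector("TF", g)] = y_hat[g]

    condensation = nx.condensation(graph)
    for comp_id in nx.topological_sort(condensation):
        members = sorted(condensation.nodes[comp_id]["members"])
        if len(members) == 1 and not graph.has_edge(members[0], members[0]):
            settle(members[0])
            continue
        if len(members) > max_cycle:
            raise ConsistencyError(f"regulatory cycle too large: {members}")
        found = False
        # most-expressed-first: deterministic tie-break among fixed points
        for bits in sorted(itertools.product((True, False), repeat=len(members)),
                           key=lambda t: (-sum(t), t)):
            trial = dict(zip(members, bits))
            for g, v in trial.items():
                x[Effector("TF", g)] = _forced_expression(
                    v, g in perturb.z, g in perturb.w)
            ok = all(
                any(_condition_value(c, x) for c in reg.conditions[g]) == trial[g]
                for g in members)
            if ok:
                for g in members:
                    y[g] = trial[g]
                    y_hat[g] = _forced_expression(
                        trial[g], g in perturb.z, g in perturb.w)
                    x[Effector("TF", g)] = y_hat[g]
                found = True
                break
        if not found:
            raise ConsistencyError(
                f"no consistent assignment for regulatory cycle {members}")

    a = {(g, m): _condition_value(cond, x)
         for g, conds in reg.conditions.items()
         for m, cond in enumerate(conds)}
    b = {(j, n): all(y_hat[g] for g in cx)
         for j, cxs in gpr.complexes.items()
         for n, cx in enumerate(cxs)}
    d = reaction_feasibility(gpr, y_hat, reaction_ids)
    return BooleanState(y, y_hat, a, x, b, d)
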