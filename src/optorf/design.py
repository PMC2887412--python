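"""Bi-level gene-oriented strain design (OptORF).

The designer searches over gene deletions ``z`` (metabolic genes and
transcription factors) and metabolic-gene overexpressions ``w`` for the
combination that maximizes secretion of a target product at the *inner
optimum* of cellular growth, subject to GPR associations and transcriptional
regulation.  The inner growth LP is replaced by its strong-duality optimality
certificate, giving a single-level MILP with outer objective

    maximize  c.v  -  alpha * sum(z)  -  beta * sum(w)

whose tiny penalties (default 1e-6) strip interventions that do not improve
production.  Alternative strategies are enumerated with integer cuts that
require at least ``delta`` intervention differences from every previous
solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .fba import (BIG_M, FEAS_TOL, add_flux_system, add_inner_optimality,
                  add_logic_system, effective_bounds, extract_dual_solution,
                  solve_regulated_fba, theoretical_max_product, vname)
from .logic import (BooleanState, GPRIndex, PerturbationVars, RegulatoryIndex,
                    compile_gpr, compile_regulation)
from .milp import MILP, LinVal
from .model import Environment, IntegratedModel

__all__ = [
    "DesignSpec",
    "DesignSolution",
    "EvaluatedDesign",
    "VerificationReport",
    "optorf",
    "enumerate_designs",
    "evaluate_design",
    "verify",
]


@dataclass(frozen=True)
class DesignSpec:
    """Design problem parameters.

    ``k1``/``k2`` cap deletions and overexpressions; ``alpha``/``beta`` are
    the per-intervention penalties; ``delta`` the minimum intervention
    distance between enumerated strategies; ``min_growth`` the enforced
    minimal growth rate (1/hr) of the inner problem; ``h_bound`` optionally
    tightens the conditional duals (the classic speed heuristic is 1.0);
    ``excluded_genes`` can neither be deleted nor overexpressed.
    """

    product: str
    k1: int = 5
    k2: int = 0
    alpha: float = 1e-6
    beta: float = 1e-6
    delta: int = 1
    min_growth: float = 0.1
    excluded_genes: frozenset[str] = frozenset()
    regulation: bool = True
    epsilon: float = 1e-3
    h_bound: float | None = None
    big_m: float = BIG_M

    def __post_init__(self):
        if self.k1 < 0 or self.k2 < 0:
            raise ValueError("caps must be non-negative")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("penalties must be non-negative")
        if self.delta < 1:
            raise ValueError("delta must be >= 1")


@dataclass
class DesignSolution:
    """One strain design: interventions plus the optimistic phenotype."""

    deletions: frozenset[str]
    overexpressions: frozenset[str]
    growth: float
    product: float
    yield_pct: float
    objective: float
    flux: dict[str, float]
    state: BooleanState | None
    status: str = "optimal"
    mip_gap: float | None = None
    primal_dual_gap: float | None = None

    def interventions(self) -> frozenset[tuple[str, str]]:
        return frozenset({("del", g) for g in self.deletions}
                         | {("oe", g) for g in self.overexpressions})

    def __repr__(self):
        dels = ",".join(sorted(self.deletions)) or "-"
        oes = ",".join(sorted(self.overexpressions)) or "-"
        return (f"DesignSolution(del=[{dels}] oe=[{oes}] growth={self.growth:.4g} "
                f"product={self.product:.4g})")


def _indices(model, spec, indices):
    if indices is not None:
        return indices
    return compile_gpr(model), compile_regulation(model, spec.epsilon)


def _intervention_cut(lp: MILP, names, model, deletions, overexpressions,
                      delta: int) -> None:
    """Require >= delta intervention flips relative to one previous solution."""
    terms: list[tuple[LinVal, float]] = []
    for g in model.genes:
        zv = names.z[g]
        if g in deletions:
            terms.append((1.0, 1.0))
            terms.append((zv, -1.0))
        else:
            terms.append((zv, 1.0))
        wv = names.w[g]
        if g in overexpressions:
            terms.append((1.0, 1.0))
            terms.append((wv, -1.0))
        else:
            terms.append((wv, 1.0))
    lp.add_constr(terms, lo=float(delta))


def optorf(model: IntegratedModel, env: Environment, spec: DesignSpec,
           *,
           indices: tuple[GPRIndex, RegulatoryIndex] | None = None,
           cuts: Sequence[tuple[frozenset, frozenset]] = (),
           time_limit: float | None = None) -> DesignSolution | None:
    """Solve the single-level design MILP; None when no allowed intervention
    set satisfies the minimum-growth requirement.

    ``cuts`` lists previous (deletions, overexpressions) pairs to exclude up
    to the spec's delta.  On a solver time limit the best incumbent is
    returned with its optimality gap in ``mip_gap``.
    """
    if spec.product not in model.reactions:
        raise ValueError(f"product reaction {spec.product!r} not in model")
    gpr, reg = _indices(model, spec, indices)
    bounds = effective_bounds(model, env, spec.big_m, spec.min_growth)
    lp = MILP("optorf")
    add_flux_system(lp, model, bounds)
    names = add_logic_system(lp, model, gpr, reg, env, bounds,
                             decision="zw", k1=spec.k1, k2=spec.k2,
                             excluded=spec.excluded_genes,
                             regulation=spec.regulation, big_m=spec.big_m)
    add_inner_optimality(lp, model, bounds, names.d, h_bound=spec.h_bound,
                         big_m=spec.big_m, link_primal=False)
    for dels, oes in cuts:
        _intervention_cut(lp, names, model, dels, oes, spec.delta)

    obj: dict[LinVal, float] = {vname(spec.product): 1.0}
    for g in model.genes:
        zv, wv = names.z[g], names.w[g]
        if isinstance(zv, str):
            obj[zv] = obj.get(zv, 0.0) - spec.alpha
        if isinstance(wv, str):
            obj[wv] = obj.get(wv, 0.0) - spec.beta
    lp.set_objective(obj, maximize=True)
    res = lp.solve(time_limit=time_limit)
    if res.status in ("infeasible", "unbounded"):
        return None
    if not res.values:
        return None
    dels = frozenset(g for g in model.genes if res.binary(names.z[g]))
    oes = frozenset(g for g in model.genes if res.binary(names.w[g]))
    flux = {j: res.values[vname(j)] for j in model.reactions}
    growth = flux[model.biomass_reaction_id]
    product = flux[spec.product]
    dual = extract_dual_solution(model, res, bounds)
    theo = theoretical_max_product(model, env, spec.product)
    ypct = 100.0 * product / theo if theo and theo > FEAS_TOL else np.nan
    return DesignSolution(
        deletions=dels, overexpressions=oes, growth=growth, product=product,
        yield_pct=ypct, objective=res.objective, flux=flux,
        state=names.state(res), status=res.status, mip_gap=res.mip_gap,
        primal_dual_gap=abs(growth - dual.objective))


# ---------------------------------------------------------------------------
# Fixed-design evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvaluatedDesign:
    status: str          # optimal | infeasible | ...
    growth: float | None
    product: float | None
    flux: dict[str, float]
    state: BooleanState | None

    @property
    def viable(self) -> bool:
        return self.status == "optimal"


def evaluate_design(model: IntegratedModel, env: Environment,
                    deletions: Iterable[str] = (),
                    overexpressions: Iterable[str] = (),
                    product: str | None = None,
                    *,
                    regulation: bool = True,
                    min_growth: float = 0.0,
                    sense: str = "max",
                    indices: tuple[GPRIndex, RegulatoryIndex] | None = None,
                    epsilon: float = 1e-3) -> EvaluatedDesign:
    """Phenotype of a fixed intervention set under bi-level optimism.

    Stage 1 maximizes growth with the interventions forced; stage 2 pins
    growth to that optimum and maximizes (``sense="max"``) or minimizes
    (``"min"``, the coupling-robustness direction) the product flux.  The
    minimum-growth bound belongs to the inner problem, so falling below it is
    an infeasibility (reported as non-viable).
    """
    perturb = PerturbationVars.from_sets(deletions, overexpressions)
    if indices is None:
        indices = (compile_gpr(model), compile_regulation(model, epsilon))
    stage1 = solve_regulated_fba(model, env, perturb, min_growth=min_growth,
                                 regulation=regulation, indices=indices)
    if not stage1.optimal:
        return EvaluatedDesign(stage1.status, None, None, {}, None)
    if product is None:
        return EvaluatedDesign("optimal", stage1.growth, None, stage1.flux,
                               stage1.state)
    stage2 = solve_regulated_fba(model, env, perturb, min_growth=min_growth,
                                 regulation=regulation, indices=indices,
                                 objective=product, maximize=(sense == "max"),
                                 fixed_growth=stage1.growth)
    if not stage2.optimal:   # numerically possible only at tolerance edges
        return EvaluatedDesign("optimal", stage1.growth,
                               stage1.flux.get(product), stage1.flux,
                               stage1.state)
    return EvaluatedDesign("optimal", stage1.growth, stage2.flux[product],
                           stage2.flux, stage2.state)


def _prune(model, env, spec, deletions: frozenset, overexpressions: frozenset,
           indices) -> tuple[frozenset, frozenset, EvaluatedDesign]:
    """Leave-one-out reduction: drop interventions whose removal does not
    lower the optimistic product flux."""
    dels, oes = set(deletions), set(overexpressions)
    base = evaluate_design(model, env, dels, oes, spec.product,
                           regulation=spec.regulation,
                           min_growth=spec.min_growth, indices=indices,
                           epsilon=spec.epsilon)
    changed = True
    while changed and base.viable:
        changed = False
        for kind, g in sorted([("del", g) for g in dels] + [("oe", g) for g in oes]):
            trial_d = dels - {g} if kind == "del" else dels
            trial_o = oes - {g} if kind == "oe" else oes
            ev = evaluate_design(model, env, trial_d, trial_o, spec.product,
                                 regulation=spec.regulation,
                                 min_growth=spec.min_growth, indices=indices,
                                 epsilon=spec.epsilon)
            if ev.viable and ev.product is not None \
                    and ev.product >= (base.product or 0.0) - 1e-9:
                dels, oes, base = set(trial_d), set(trial_o), ev
                changed = True
                break
    return frozenset(dels), frozenset(oes), base


def _as_solution(model, env, spec, dels, oes, ev: EvaluatedDesign) -> DesignSolution:
    theo = theoretical_max_product(model, env, spec.product)
    product = ev.product or 0.0
    ypct = 100.0 * product / theo if theo and theo > FEAS_TOL else np.nan
    objective = product - spec.alpha * len(dels) - spec.beta * len(oes)
    return DesignSolution(dels, oes, ev.growth or 0.0, product, ypct,
                          objective, ev.flux, ev.state)


def enumerate_designs(model: IntegratedModel, env: Environment,
                      spec: DesignSpec, n_solutions: int,
                      *,
                      indices: tuple[GPRIndex, RegulatoryIndex] | None = None,
                      time_limit: float | None = None) -> list[DesignSolution]:
    """Enumerate up to ``n_solutions`` strategies with delta integer cuts.

    With ``delta=1`` every incumbent is pruned to a minimal strategy before
    being emitted (penalized ties can otherwise surface a useless extra
    intervention riding along on a previously-cut optimum); raw and pruned
    intervention sets both receive cuts.  With ``delta>1`` incumbents are
    emitted as returned so successive strategies honour the diversity
    distance.  Objectives are non-increasing; exhaustion yields a shorter
    list.
    """
    if n_solutions < 1:
        raise ValueError("n_solutions must be >= 1")
    gpr_reg = _indices(model, spec, indices)
    cuts: list[tuple[frozenset, frozenset]] = []
    emitted: set[frozenset] = set()
    out: list[DesignSolution] = []
    while len(out) < n_solutions:
        sol = optorf(model, env, spec, indices=gpr_reg, cuts=cuts,
                     time_limit=time_limit)
        if sol is None:
            break
        raw = (sol.deletions, sol.overexpressions)
        cuts.append(raw)
        if spec.delta == 1:
            dels, oes, ev = _prune(model, env, spec, *raw, gpr_reg)
            if (dels, oes) != raw:
                cuts.append((dels, oes))
                sol = _as_solution(model, env, spec, dels, oes, ev)
        key = sol.interventions()
        if key in emitted:
            continue
        emitted.add(key)
        out.append(sol)
    return out


# ---------------------------------------------------------------------------
# Verification
# ---------------------------------------------------------------------------

@dataclass
class VerificationReport:
    """Re-derivation of a design's phenotype by plain regulated FBA.

    Guards against big-M or dual-bound artifacts in the single-level MILP:
    ``growth_delta``/``product_delta`` compare the claim against a fresh
    two-stage solve, and ``robust_min_product`` is the pessimistic product
    flux at the growth optimum (coupling robustness; > 0 means every inner
    optimum secretes product).
    """

    ok: bool
    status: str
    growth_delta: float | None
    product_delta: float | None
    robust_min_product: float | None


def verify(model: IntegratedModel, env: Environment, solution: DesignSolution,
           spec: DesignSpec, *, tol: float = 1e-6,
           indices: tuple[GPRIndex, RegulatoryIndex] | None = None
           ) -> VerificationReport:
    gpr_reg = _indices(model, spec, indices)
    ev = evaluate_design(model, env, solution.deletions,
                         solution.overexpressions, spec.product,
                         regulation=spec.regulation,
                         min_growth=spec.min_growth, indices=gpr_reg,
                         epsilon=spec.epsilon)
    if not ev.viable:
        return VerificationReport(False, ev.status, None, None, None)
    robust = evaluate_design(model, env, solution.deletions,
                             solution.overexpressions, spec.product,
                             regulation=spec.regulation, sense="min",
                             min_growth=spec.min_growth, indices=gpr_reg,
                             epsilon=spec.epsilon)
    gd = abs(ev.growth - solution.growth)
    pdelta = abs((ev.product or 0.0) - solution.product)
    ok = gd <= tol and pdelta <= tol
    return VerificationReport(ok, "optimal", gd, pdelta,
                              robust.product if robust.viable else None)
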