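"""Reaction-deletion bi-level designer (the OptKnock-style baseline).

Searches over binary reaction removals for growth-coupled product secretion,
with the inner growth LP replaced by its strong-duality certificate.  GPR and
regulatory logic are deliberately NOT applied: reactions are deleted
individually even when they share genes with other reactions, and reactions
without any gene association remain deletable.  That is exactly the semantics
gene-oriented design criticizes — audits of these designs under gene/
regulatory semantics live in :mod:`optorf.analysis`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .fba import (BIG_M, FEAS_TOL, add_flux_system, add_inner_optimality,
                  effective_bounds, solve_fba, theoretical_max_product, vname)
from .milp import MILP
from .model import Environment, IntegratedModel

__all__ = ["ReactionDesign", "optknock", "enumerate_optknock",
           "evaluate_reaction_design"]

_TIE_PENALTY = 1e-6   # same scale as the gene designer's alpha


@dataclass
class ReactionDesign:
    deletions: frozenset[str]
    growth: float
    product: float
    yield_pct: float
    objective: float          # product flux (penalty not included)
    flux: dict[str, float]
    status: str = "optimal"

    def __repr__(self):
        dels = ",".join(sorted(self.deletions)) or "-"
        return (f"ReactionDesign(del=[{dels}] growth={self.growth:.4g} "
                f"product={self.product:.4g})")


def evaluate_reaction_design(model: IntegratedModel, env: Environment,
                             deletions: Iterable[str], product: str,
                             min_growth: float = 0.1
                             ) -> tuple[str, float | None, float | None, dict]:
    """(status, growth, product, flux) for fixed reaction removals: max growth,
    then max product at that growth (bi-level optimism)."""
    d = {j: False for j in deletions}
    s1 = solve_fba(model, env, d=d, min_growth=min_growth)
    if not s1.optimal:
        return s1.status, None, None, {}
    s2 = solve_fba(model, env, d=d, objective=product, min_growth=min_growth,
                   fixed={model.biomass_reaction_id: s1.objective})
    if not s2.optimal:
        return "optimal", s1.objective, s1.flux.get(product), s1.flux
    return "optimal", s1.objective, s2.objective, s2.flux


def _candidates(model: IntegratedModel, product: str,
                excluded: Iterable[str]) -> list[str]:
    excluded = set(excluded) | {model.biomass_reaction_id, product}
    return [j for j, rxn in model.reactions.items()
            if rxn.deletable and j not in excluded]


def optknock(model: IntegratedModel, env: Environment, product: str,
             max_deletions: int,
             *,
             excluded: Iterable[str] = (),
             min_growth: float = 0.1,
             h_bound: float | None = None,
             big_m: float = BIG_M,
             _cuts: Sequence[frozenset] = (),
             prune: bool = True) -> ReactionDesign:
    """Best reaction-deletion design within the cap.

    The MILP objective carries a 1e-6 per-deletion tie-break penalty so that
    among equally productive deletion sets the smallest is returned; reported
    objectives are raw product fluxes.  If no deletion set couples production
    the wild-type design is returned (possibly with product 0); if even the
    wild type cannot reach ``min_growth`` the status is ``infeasible``.
    """
    if product not in model.reactions:
        raise ValueError(f"product reaction {product!r} not in model")
    cands = _candidates(model, product, excluded)
    bounds = effective_bounds(model, env, big_m, min_growth)
    lp = MILP("optknock")
    add_flux_system(lp, model, bounds)
    d = {j: lp.add_binary(f"d[{j}]") for j in cands}
    if cands:
        lp.add_constr([(dv, 1.0) for dv in d.values()],
                      lo=float(len(cands) - max_deletions))
    for cut in _cuts:
        # exclude previous solutions and all their supersets
        terms = [(d[j], 1.0) for j in cut if j in d]
        if terms:
            lp.add_constr(terms, lo=1.0)
        else:
            lp.add_constr([(1.0, 1.0)], lo=2.0)  # unsatisfiable: exhausted
    add_inner_optimality(lp, model, bounds, d, h_bound=h_bound, big_m=big_m,
                         link_primal=True)
    obj = {vname(product): 1.0}
    for dv in d.values():
        obj[dv] = _TIE_PENALTY
    lp.set_objective(obj, maximize=True)
    res = lp.solve()
    if not res.optimal:
        return ReactionDesign(frozenset(), 0.0, 0.0, np.nan, 0.0, {},
                              status=res.status)
    deleted = frozenset(j for j, dv in d.items() if not res.binary(dv))
    if prune:
        deleted = _prune_reactions(model, env, deleted, product, min_growth)
    status, growth, prod, flux = evaluate_reaction_design(
        model, env, deleted, product, min_growth)
    if prod is None or prod <= FEAS_TOL:
        # no coupling achieved: report the wild type
        status, growth, prod, flux = evaluate_reaction_design(
            model, env, (), product, min_growth)
        deleted = frozenset()
    theo = theoretical_max_product(model, env, product)
    ypct = 100.0 * prod / theo if theo and theo > FEAS_TOL else np.nan
    return ReactionDesign(deleted, growth, prod, ypct, prod, flux, status)


def _prune_reactions(model, env, deletions: frozenset, product, min_growth):
    dels = set(deletions)
    _, _, base, _ = evaluate_reaction_design(model, env, dels, product, min_growth)
    if base is None:
        return frozenset(dels)
    changed = True
    while changed:
        changed = False
        for j in sorted(dels):
            _, _, p, _ = evaluate_reaction_design(model, env, dels - {j},
                                                  product, min_growth)
            if p is not None and p >= base - 1e-9:
                dels.remove(j)
                base = p
                changed = True
                break
    return frozenset(dels)


def enumerate_optknock(model: IntegratedModel, env: Environment, product: str,
                       cap: int, n_solutions: int,
                       *,
                       excluded: Iterable[str] = (),
                       min_growth: float = 0.1,
                       h_bound: float | None = None) -> list[ReactionDesign]:
    """Successively better-to-worse designs via superset-excluding integer
    cuts; stops when designs no longer couple production (product ~ 0)."""
    if n_solutions < 1:
        raise ValueError("n_solutions must be >= 1")
    cuts: list[frozenset] = []
    seen: set[frozenset] = set()
    out: list[ReactionDesign] = []
    while len(out) < n_solutions:
        des = optknock(model, env, product, cap, excluded=excluded,
                       min_growth=min_growth, h_bound=h_bound, _cuts=cuts)
        if des.status != "optimal" or des.product <= FEAS_TOL \
                or not des.deletions:
            break
        cuts.append(des.deletions)
        if des.deletions in seen:
            continue
        seen.add(des.deletions)
        out.append(des)
    return out
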