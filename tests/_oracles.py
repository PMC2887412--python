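"""Independent brute-force oracles for the design MILPs.

Deliberately avoids the package's MILP builder and logic compiler: Boolean
rules are evaluated directly on their expression trees, and inner LPs are
solved with scipy.optimize.linprog.  Used to certify that the single-level
strong-duality reformulations return true bi-level optima on small models.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog

from optorf.model import (And, FluxPred, IntegratedModel, Not, Or, Ref,
                          TrueExpr, FalseExpr, eval_expr)

BIG = 1000.0


def _bounds(model, env, min_growth=0.0):
    out = {}
    for j, rxn in model.reactions.items():
        lb = max(rxn.lower_bound, -BIG)
        ub = min(rxn.upper_bound, BIG)
        if j in env.uptake_bounds:
            lb = max(env.uptake_bounds[j], -BIG)
        if j == model.biomass_reaction_id:
            lb = max(lb, min_growth)
        out[j] = (lb, ub)
    return out


def _lp(model, env, d, objective, maximize, min_growth=0.0,
        fixed_growth=None, pred_assign=None, eps=1e-3):
    """One inner LP with fixed reaction states and optional flux-indicator
    consistency constraints (pred_assign maps (rxn, positive) -> bool)."""
    rxns = list(model.reactions)
    idx = {j: i for i, j in enumerate(rxns)}
    S, mets, _ = model.stoichiometric_matrix()
    bnds = _bounds(model, env, min_growth)
    lo = []
    for j in rxns:
        lb, ub = bnds[j]
        if d is not None and not d.get(j, True):
            lb, ub = 0.0, 0.0
        lo.append((lb, ub))
    A_ub, b_ub = [], []
    if fixed_growth is not None:
        row = np.zeros(len(rxns))
        row[idx[model.biomass_reaction_id]] = -1.0
        A_ub.append(row)
        b_ub.append(-(fixed_growth - 1e-9))
    if pred_assign:
        for (j, positive), val in pred_assign.items():
            row = np.zeros(len(rxns))
            row[idx[j]] = 1.0
            if positive:
                if val:      # v >= eps
                    A_ub.append(-row)
                    b_ub.append(-eps)
                else:        # v <= eps
                    A_ub.append(row)
                    b_ub.append(eps)
            else:
                if val:      # v <= -eps
                    A_ub.append(row)
                    b_ub.append(-eps)
                else:        # v >= -eps
                    A_ub.append(-row)
                    b_ub.append(eps)
    c = np.zeros(len(rxns))
    c[idx[objective]] = -1.0 if maximize else 1.0
    res = linprog(c, A_ub=np.array(A_ub) if A_ub else None,
                  b_ub=np.array(b_ub) if b_ub else None,
                  A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=lo,
                  method="highs")
    if res.status != 0:
        return None
    return -res.fun if maximize else res.fun


def _flux_predicates(model):
    preds = set()
    for rule in model.rules.values():
        stack = [rule.expression]
        while stack:
            e = stack.pop()
            if isinstance(e, FluxPred):
                preds.add((model.resolve_flux_ref(e.ref), e.positive))
            elif isinstance(e, Not):
                stack.append(e.child)
            elif isinstance(e, (And, Or)):
                stack.extend(e.children)
    return sorted(preds)


def boolean_state(model, env, z, w, pred_assign, compat=True):
    """Direct rule evaluation in topological order.

    Returns (y, y_hat) or None when the (z, w) set is incompatible with the
    regulatory state (deleting an unexpressed gene / overexpressing an
    expressed one) and ``compat`` is demanded.  Assumes acyclic TF
    dependencies (guaranteed by the toy generator).
    """
    y, y_hat = {}, {}

    def assign(lit):
        if isinstance(lit, FluxPred):
            return pred_assign[(model.resolve_flux_ref(lit.ref), lit.positive)]
        if lit.name in model.genes:
            return get_yhat(lit.name)
        return lit.name in env.active_stimuli

    def get_yhat(g):
        if g not in y_hat:
            rule = model.rules.get(g)
            yv = True if rule is None else eval_expr(rule.expression, assign)
            y[g] = yv
            if compat:
                y_hat[g] = (yv and g not in z) or (not yv and g in w)
            else:
                y_hat[g] = False if g in z else (True if g in w else yv)
        return y_hat[g]

    for g in model.genes:
        get_yhat(g)
    if compat:
        for g in z:
            if not y[g]:
                return None
        for g in w:
            if y[g]:
                return None
    return y, y_hat


def reaction_states(model, y_hat):
    d = {}
    for j, rxn in model.reactions.items():
        if rxn.gpr is None:
            d[j] = True
        else:
            d[j] = eval_expr(rxn.gpr, lambda lit: y_hat[lit.name])
    return d


def eval_gene_design(model, env, z, w, product, *, regulation=True,
                     min_growth=0.0, eps=1e-3, compat=True):
    """Optimistic (growth, product) of a fixed gene design, enumerating every
    flux-indicator assignment; None when no consistent state is viable."""
    z, w = set(z), set(w)
    preds = _flux_predicates(model) if regulation else []
    best = None
    for bits in itertools.product([False, True], repeat=len(preds)):
        pa = dict(zip(preds, bits))
        if regulation:
            st = boolean_state(model, env, z, w, pa, compat=compat)
            if st is None:
                continue
            _, y_hat = st
        else:
            y_hat = {g: (g not in z) for g in model.genes}
        d = reaction_states(model, y_hat)
        gmax = _lp(model, env, d, model.biomass_reaction_id, True, min_growth)
        if gmax is None:
            continue
        # outer-feasible: v inner-optimal AND consistent with the assignment
        prod = _lp(model, env, d, product, True, min_growth,
                   fixed_growth=gmax, pred_assign=pa if regulation else None,
                   eps=eps)
        if prod is None:
            continue
        if best is None or prod > best[1] + 1e-12:
            best = (gmax, prod)
    return best


def brute_force_optorf(model, env, spec):
    """Exhaustive search over intervention sets; returns (objective, sets)."""
    genes = [g for g in model.genes if g not in spec.excluded_genes]
    mets = [g for g in genes if not model.genes[g].is_tf]
    best = None
    del_sets = []
    for k in range(spec.k1 + 1):
        del_sets.extend(itertools.combinations(genes, k))
    for dels in del_sets:
        oe_sets = [()]
        for k in range(1, spec.k2 + 1):
            oe_sets.extend(c for c in itertools.combinations(mets, k)
                           if not set(c) & set(dels))
        for oes in oe_sets:
            r = eval_gene_design(model, env, dels, oes, spec.product,
                                 regulation=spec.regulation,
                                 min_growth=spec.min_growth,
                                 eps=spec.epsilon)
            if r is None:
                continue
            obj = r[1] - spec.alpha * len(dels) - spec.beta * len(oes)
            if best is None or obj > best[0] + 1e-12:
                best = (obj, frozenset(dels), frozenset(oes))
    return best


def eval_reaction_design(model, env, dels, product, min_growth=0.1):
    d = {j: False for j in dels}
    gmax = _lp(model, env, d, model.biomass_reaction_id, True, min_growth)
    if gmax is None:
        return None
    prod = _lp(model, env, d, product, True, min_growth, fixed_growth=gmax)
    return gmax, prod


def brute_force_optknock(model, env, product, cap, excluded=(),
                         min_growth=0.1):
    cands = [j for j, rxn in model.reactions.items()
             if rxn.deletable and j not in set(excluded)
             and j not in (model.biomass_reaction_id, product)]
    best = None
    for k in range(cap + 1):
        for dels in itertools.combinations(cands, k):
            r = eval_reaction_design(model, env, dels, product, min_growth)
            if r is None:
                continue
            if best is None or r[1] > best[0] + 1e-12:
                best = (r[1], frozenset(dels))
    return best
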