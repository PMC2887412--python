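"""Flux balance analysis, regulated FBA, production envelopes, strong duality.

Everything here is built from three reusable constraint blocks on a
:class:`~optorf.milp.MILP`:

``add_flux_system``
    flux variables ``v[j]`` with environment-adjusted bounds and steady-state
    mass balance ``S v = 0``.

``add_logic_system``
    the Boolean layer: gene expression from regulatory DNF conditions, flux
    and stimulus indicators, deletion/overexpression surrogates, enzyme and
    reaction feasibility from GPR complexes, and the big-M link that forces
    ``v_j = 0`` when a reaction is infeasible.

``add_inner_optimality``
    the strong-duality certificate that pins ``v`` to an optimum of the inner
    growth LP for whatever reaction states the binaries select: dual
    feasibility, the conditional duals for deleted reactions, and
    primal-objective = dual-objective.

Bi-level designers stack all three; plain and regulated FBA use the first one
or two.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .logic import (BooleanState, Condition, Effector, GPRIndex,
                    PerturbationVars, RegulatoryIndex, compile_gpr,
                    compile_regulation)
from .milp import MILP, LinVal, SolveResult
from .model import Environment, IntegratedModel

__all__ = [
    "BIG_M",
    "FEAS_TOL",
    "LETHAL_TOL",
    "FBAResult",
    "RegulatedFBAResult",
    "LogicNames",
    "DualSolution",
    "effective_bounds",
    "add_flux_system",
    "add_logic_system",
    "add_inner_optimality",
    "solve_fba",
    "solve_regulated_fba",
    "production_envelope",
    "extract_dual_solution",
]

BIG_M = 1000.0          # global flux bound, mmol/gDW/hr
FEAS_TOL = 1e-6         # LP/MILP feasibility checks
LETHAL_TOL = 1e-6       # growth below this counts as no growth


def effective_bounds(model: IntegratedModel, env: Environment,
                     big_m: float = BIG_M,
                     min_growth: float = 0.0) -> dict[str, tuple[float, float]]:
    """Reaction bounds clipped to +-big_m, with environment uptake overrides
    and an optional minimum-growth lower bound on the biomass reaction."""
    bounds: dict[str, tuple[float, float]] = {}
    for j, rxn in model.reactions.items():
        lb = max(rxn.lower_bound, -big_m)
        ub = min(rxn.upper_bound, big_m)
        if j in env.uptake_bounds:
            lb = max(float(env.uptake_bounds[j]), -big_m)
        if j == model.biomass_reaction_id and min_growth > 0:
            lb = max(lb, float(min_growth))
        bounds[j] = (lb, ub)
    return bounds


def vname(j: str) -> str:
    return f"v[{j}]"


def add_flux_system(lp: MILP, model: IntegratedModel,
                    bounds: Mapping[str, tuple[float, float]]) -> None:
    """Flux variables and S v = 0."""
    for j in model.reactions:
        lb, ub = bounds[j]
        lp.add_var(vname(j), lb, ub)
    by_met: dict[str, list[tuple[str, float]]] = {m: [] for m in model.metabolites}
    for j, rxn in model.reactions.items():
        for m, coef in rxn.stoichiometry.items():
            by_met[m].append((vname(j), coef))
    for m, terms in by_met.items():
        if terms:
            lp.add_eq(terms, 0.0)


# ---------------------------------------------------------------------------
# Boolean logic block
# ---------------------------------------------------------------------------

@dataclass
class LogicNames:
    """LinVal handles (variable names or constants) for every logic quantity."""

    y: dict[str, LinVal] = field(default_factory=dict)
    y_hat: dict[str, LinVal] = field(default_factory=dict)
    z: dict[str, LinVal] = field(default_factory=dict)
    w: dict[str, LinVal] = field(default_factory=dict)
    a: dict[tuple[str, int], LinVal] = field(default_factory=dict)
    x: dict[Effector, LinVal] = field(default_factory=dict)
    b: dict[tuple[str, int], LinVal] = field(default_factory=dict)
    d: dict[str, LinVal] = field(default_factory=dict)

    def deletable(self) -> dict[str, LinVal]:
        """Reactions whose feasibility indicator is not constantly 1."""
        return {j: dv for j, dv in self.d.items()
                if isinstance(dv, str) or dv < 0.5}

    def state(self, res: SolveResult) -> BooleanState:
        bit = res.binary
        return BooleanState(
            y={g: bit(v) for g, v in self.y.items()},
            y_hat={g: bit(v) for g, v in self.y_hat.items()},
            a={k: bit(v) for k, v in self.a.items()},
            x={e: bit(v) for e, v in self.x.items()},
            b={k: bit(v) for k, v in self.b.items()},
            d={j: bit(v) for j, v in self.d.items()},
        )


def add_logic_system(lp: MILP, model: IntegratedModel, gpr: GPRIndex,
                     reg: RegulatoryIndex, env: Environment,
                     bounds: Mapping[str, tuple[float, float]],
                     *,
                     perturb: PerturbationVars | None = None,
                     decision: str = "none",
                     k1: int = 0, k2: int = 0,
                     excluded: Iterable[str] = (),
                     regulation: bool = True,
                     big_m: float = BIG_M) -> LogicNames:
    """Add the GPR + regulation + perturbation layer.

    ``decision`` picks how interventions enter:

    * ``"none"`` — ``perturb`` supplies fixed interventions with forcing
      semantics (a deleted gene is off regardless of its regulatory state),
      which is what fixed-design audits need;
    * ``"zw"`` — deletions ``z[g]`` and overexpressions ``w[g]`` are binary
      decision variables under caps ``k1``/``k2`` and the compatibility
      constraints (delete only expressed genes, overexpress only repressed
      ones);
    * ``"w"`` — deletions are fixed from ``perturb`` (forcing), while
      overexpressions remain free decisions under ``k2`` (used by the minimal
      overexpression-rescue analysis).

    With ``regulation=False`` every gene is constitutively expressed and only
    the GPR layer remains active.
    """
    if decision not in ("none", "zw", "w"):
        raise ValueError(f"bad decision mode {decision!r}")
    names = LogicNames()
    excluded = set(excluded)
    perturb = perturb or PerturbationVars()
    eps = reg.epsilon

    # --- gene layer: y, z, w, y_hat ---------------------------------------
    for g, gene in model.genes.items():
        conds = reg.conditions[g]
        if not regulation:
            yval: LinVal = 1.0
        elif len(conds) == 0:
            yval = 0.0
        elif any(len(c.activators) + len(c.repressors) == 0 for c in conds):
            yval = 1.0  # some condition is empty: constitutively on
        else:
            yval = lp.add_binary(f"y[{g}]")
        names.y[g] = yval

        if decision == "zw":
            can_del = g not in excluded and k1 > 0
            can_oe = (not gene.is_tf) and g not in excluded and k2 > 0
            zval: LinVal = lp.add_binary(f"z[{g}]") if can_del else 0.0
            wval: LinVal = lp.add_binary(f"w[{g}]") if can_oe else 0.0
            names.z[g], names.w[g] = zval, wval
            if isinstance(zval, str) or isinstance(wval, str) or isinstance(yval, str):
                yh = lp.add_binary(f"yhat[{g}]")
                lp.add_eq([(yh, 1.0), (yval, -1.0), (zval, 1.0), (wval, -1.0)], 0.0)
                # z only on expressed genes, w only on repressed ones
                lp.add_constr([(zval, 1.0), (yval, -1.0)], hi=0.0)
                lp.add_constr([(wval, 1.0), (yval, 1.0)], hi=1.0)
            else:
                yh = yval
            names.y_hat[g] = yh
        elif decision == "w":
            z = g in perturb.z
            names.z[g] = float(z)
            can_oe = (not gene.is_tf) and g not in excluded and not z and k2 > 0
            wval = lp.add_binary(f"w[{g}]") if can_oe else 0.0
            names.w[g] = wval
            if z:
                names.y_hat[g] = 0.0
            elif isinstance(wval, str):
                yh = lp.add_binary(f"yhat[{g}]")
                lp.add_eq([(yh, 1.0), (yval, -1.0), (wval, -1.0)], 0.0)
                lp.add_constr([(wval, 1.0), (yval, 1.0)], hi=1.0)
                names.y_hat[g] = yh
            else:
                names.y_hat[g] = yval
        else:
            z = g in perturb.z
            w = g in perturb.w
            names.z[g], names.w[g] = float(z), float(w)
            if z:
                names.y_hat[g] = 0.0
            elif w:
                names.y_hat[g] = 1.0
            else:
                names.y_hat[g] = yval

    if decision != "none":
        zvars = [(v, 1.0) for v in names.z.values() if isinstance(v, str)]
        if zvars:
            lp.add_constr(zvars, hi=float(k1))
        wvars = [(v, 1.0) for v in names.w.values() if isinstance(v, str)]
        if wvars and k2 < len(wvars):
            lp.add_constr(wvars, hi=float(k2))

    # --- effector indicators ------------------------------------------------
    if regulation:
        for e in reg.effectors():
            if e.kind == "TF":
                names.x[e] = names.y_hat[e.ref]
            elif e.kind == "ES":
                names.x[e] = float(e.ref in env.active_stimuli)
            else:  # PF / NF flux indicators
                xv = lp.add_binary(f"x[{e.kind}:{e.ref}]")
                names.x[e] = xv
                lb, ub = bounds[e.ref]
                span = max(abs(lb), abs(ub), 1.0) + eps
                v = vname(e.ref)
                if e.kind == "PF":
                    # x=1 => v >= eps ; x=0 => v <= eps
                    lp.add_constr([(v, 1.0), (xv, -span)], lo=eps - span, hi=eps)
                else:
                    # x=1 => v <= -eps ; x=0 => v >= -eps
                    lp.add_constr([(v, 1.0), (xv, span)], lo=-eps, hi=-eps + span)

        # --- conditions and expression -------------------------------------
        for g in model.genes:
            yval = names.y[g]
            conds = reg.conditions[g]
            if not isinstance(yval, str):
                # y constant: conditions only recorded when themselves constant
                for m, cond in enumerate(conds):
                    av = _const_condition(names, cond)
                    if av is not None:
                        names.a[(g, m)] = av
                continue
            avals: list[LinVal] = []
            for m, cond in enumerate(conds):
                if len(conds) == 1:
                    av: LinVal = yval  # single condition: y doubles as a
                else:
                    av = lp.add_binary(f"a[{g},{m}]")
                names.a[(g, m)] = av
                acts = [names.x[e] for e in cond.activators]
                reps = [names.x[e] for e in cond.repressors]
                for xv in acts:
                    lp.add_constr([(av, 1.0), (xv, -1.0)], hi=0.0)
                for xv in reps:
                    lp.add_constr([(av, 1.0), (xv, 1.0)], hi=1.0)
                terms = [(xv, 1.0) for xv in acts] + [(xv, -1.0) for xv in reps]
                terms.append((av, -1.0))
                lp.add_constr(terms, hi=float(len(acts) - 1))
                avals.append(av)
            if len(conds) > 1:
                lp.add_constr([(yval, 1.0)] + [(av, -1.0) for av in avals], hi=0.0)
                for av in avals:
                    lp.add_constr([(yval, 1.0), (av, -1.0)], lo=0.0)

    # --- GPR layer ----------------------------------------------------------
    for j in model.reactions:
        names.d[j] = 1.0
    for j, cxs in gpr.complexes.items():
        bvals: list[LinVal] = []
        for n, cx in enumerate(cxs):
            members = [names.y_hat[g] for g in sorted(cx)]
            if len(members) == 1:
                bv: LinVal = members[0]
            elif all(not isinstance(v, str) for v in members):
                bv = float(all(v > 0.5 for v in members))
            else:
                bv = lp.add_binary(f"b[{j},{n}]")
                for yh in members:
                    lp.add_constr([(bv, 1.0), (yh, -1.0)], hi=0.0)
                terms = [(yh, 1.0) for yh in members] + [(bv, -1.0)]
                lp.add_constr(terms, hi=float(len(members) - 1))
            names.b[(j, n)] = bv
            bvals.append(bv)
        if len(bvals) == 1:
            dv: LinVal = bvals[0]
        elif all(not isinstance(v, str) for v in bvals):
            dv = float(any(v > 0.5 for v in bvals))
        else:
            dv = lp.add_binary(f"d[{j}]")
            lp.add_constr([(dv, 1.0)] + [(bv, -1.0) for bv in bvals], hi=0.0)
            for bv in bvals:
                lp.add_constr([(dv, 1.0), (bv, -1.0)], lo=0.0)
        names.d[j] = dv

        # reaction off => zero flux
        lb, ub = bounds[j]
        span = max(abs(lb), abs(ub), 1.0)
        v = vname(j)
        if isinstance(dv, str):
            lp.add_constr([(v, 1.0), (dv, -span)], hi=0.0)
            lp.add_constr([(v, 1.0), (dv, span)], lo=0.0)
        elif dv < 0.5:
            lp.set_bounds(v, 0.0, 0.0)
    return names


def _const_condition(names: LogicNames, cond: Condition) -> LinVal | None:
    """Condition value if every effector is a constant, else None."""
    vals = [names.x.get(e) for e in cond.activators + cond.repressors]
    if any(v is None or isinstance(v, str) for v in vals):
        return None
    on = (all(names.x[e] > 0.5 for e in cond.activators)
          and not any(names.x[e] > 0.5 for e in cond.repressors))
    return 1.0 if on else 0.0


# ---------------------------------------------------------------------------
# Strong duality block
# ---------------------------------------------------------------------------

@dataclass
class DualSolution:
    """Dual certificate of inner-LP optimality: u (mass balance), lambda/mu
    (lower/upper bound rows), h (conditional duals of deleted reactions)."""

    u: dict[str, float]
    lam: dict[str, float]
    mu: dict[str, float]
    h: dict[str, float]
    objective: float


def add_inner_optimality(lp: MILP, model: IntegratedModel,
                         bounds: Mapping[str, tuple[float, float]],
                         d: Mapping[str, LinVal],
                         *,
                         objective_rxn: str | None = None,
                         h_bound: float | None = None,
                         big_m: float = BIG_M,
                         link_primal: bool = False) -> None:
    """Constrain ``v`` to an optimum of ``max p.v`` s.t. mass balance, bounds
    and ``v_j = 0`` where ``d_j = 0``.

    ``d`` maps reaction ids to feasibility indicators (binary variable names
    or constants); only reactions present in ``d`` with a non-constant or zero
    indicator receive a conditional dual ``h``, bounded to +-``h_bound``
    (default: the global big-M; the tighter [-1, 1] range is a speed heuristic
    that can exclude genuine optima and must be opted into).  With
    ``link_primal`` the block also emits the big-M rows forcing ``v_j = 0``
    when ``d_j = 0`` — designers whose logic block already links fluxes leave
    it off.
    """
    if objective_rxn is None:
        objective_rxn = model.biomass_reaction_id
    hb = big_m if h_bound is None else float(h_bound)

    for m in model.metabolites:
        lp.add_var(f"u[{m}]", -np.inf, np.inf)
    for j in model.reactions:
        lp.add_var(f"lam[{j}]", 0.0, np.inf)
        lp.add_var(f"mu[{j}]", 0.0, np.inf)

    hvars: dict[str, str] = {}
    for j, dv in d.items():
        if not isinstance(dv, str) and dv > 0.5:
            continue
        ht = lp.add_var(f"h[{j}]", -hb, hb)
        hvars[j] = ht
        if isinstance(dv, str):
            # |h_j| <= hb (1 - d_j)
            lp.add_constr([(ht, 1.0), (dv, hb)], hi=hb)
            lp.add_constr([(ht, 1.0), (dv, -hb)], lo=-hb)
        if link_primal:
            lb, ub = bounds[j]
            span = max(abs(lb), abs(ub), 1.0)
            v = vname(j)
            if isinstance(dv, str):
                lp.add_constr([(v, 1.0), (dv, -span)], hi=0.0)
                lp.add_constr([(v, 1.0), (dv, span)], lo=0.0)
            else:
                lp.set_bounds(v, 0.0, 0.0)

    # dual feasibility: S^T u - lambda + mu + h = p
    for j, rxn in model.reactions.items():
        terms: list[tuple[LinVal, float]] = [
            (f"u[{m}]", coef) for m, coef in rxn.stoichiometry.items()]
        terms.append((f"lam[{j}]", -1.0))
        terms.append((f"mu[{j}]", 1.0))
        if j in hvars:
            terms.append((hvars[j], 1.0))
        p = 1.0 if j == objective_rxn else 0.0
        lp.add_eq(terms, p)

    # strong duality: p.v = sum(ub mu) - sum(lb lam)
    eq_terms: list[tuple[LinVal, float]] = [(vname(objective_rxn), 1.0)]
    for j in model.reactions:
        lb, ub = bounds[j]
        eq_terms.append((f"mu[{j}]", -ub))
        eq_terms.append((f"lam[{j}]", lb))
    lp.add_eq(eq_terms, 0.0)


def extract_dual_solution(model: IntegratedModel, res: SolveResult,
                          bounds: Mapping[str, tuple[float, float]]) -> DualSolution:
    u = {m: res.values[f"u[{m}]"] for m in model.metabolites}
    lam = {j: res.values[f"lam[{j}]"] for j in model.reactions}
    mu = {j: res.values[f"mu[{j}]"] for j in model.reactions}
    h = {j[2:-1]: val for j, val in res.values.items() if j.startswith("h[")}
    obj = sum(mu[j] * bounds[j][1] - lam[j] * bounds[j][0] for j in model.reactions)
    return DualSolution(u, lam, mu, h, obj)


# ---------------------------------------------------------------------------
# FBA entry points
# ---------------------------------------------------------------------------

@dataclass
class FBAResult:
    status: str           # optimal | infeasible | unbounded | error
    flux: dict[str, float]
    objective: float | None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def solve_fba(model: IntegratedModel, env: Environment,
              d: Mapping[str, bool | float] | None = None,
              objective: str | Mapping[str, float] | None = None,
              *,
              maximize: bool = True,
              min_growth: float = 0.0,
              fixed: Mapping[str, float] | None = None,
              big_m: float = BIG_M) -> FBAResult:
    """Plain FBA: optimize a flux objective under mass balance and bounds.

    ``d`` fixes reaction feasibilities (0 forces zero flux); ``fixed`` pins
    individual fluxes to values (used by envelope sweeps).  Infeasible and
    unbounded outcomes are reported distinctly in ``status``.
    """
    bounds = effective_bounds(model, env, big_m, min_growth)
    lp = MILP("fba")
    add_flux_system(lp, model, bounds)
    if d:
        for j, dv in d.items():
            if not dv:
                lp.set_bounds(vname(j), 0.0, 0.0)
    if fixed:
        for j, val in fixed.items():
            lp.set_bounds(vname(j), val, val)
    if objective is None:
        objective = model.biomass_reaction_id
    if isinstance(objective, str):
        obj_terms = {vname(objective): 1.0}
    else:
        obj_terms = {vname(j): c for j, c in objective.items()}
    lp.set_objective(obj_terms, maximize=maximize)
    res = lp.solve()
    flux = {j: res.values.get(vname(j), 0.0) for j in model.reactions} \
        if res.values else {}
    return FBAResult(res.status, flux, res.objective)


@dataclass
class RegulatedFBAResult:
    status: str
    flux: dict[str, float]
    state: BooleanState | None
    growth: float | None
    lethal: bool

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def solve_regulated_fba(model: IntegratedModel, env: Environment,
                        perturb: PerturbationVars | None = None,
                        *,
                        min_growth: float = 0.0,
                        regulation: bool = True,
                        objective: str | Mapping[str, float] | None = None,
                        maximize: bool = True,
                        fixed_growth: float | None = None,
                        growth_window: float = 1e-9,
                        indices: tuple[GPRIndex, RegulatoryIndex] | None = None,
                        epsilon: float | None = None,
                        big_m: float = BIG_M) -> RegulatedFBAResult:
    """Regulated FBA: maximize growth (or another objective) over fluxes and
    Boolean states jointly, with fixed interventions.

    The MILP demands a self-consistent fixed point of the regulatory system —
    flux indicators must agree with the fluxes the solver picks.  When several
    fixed points exist the solver returns the one best for the objective; the
    returned :class:`BooleanState` reports which.  Infeasibility (e.g. an
    enforced minimum growth that no consistent state reaches) is flagged
    lethal.
    """
    if indices is None:
        gpr = compile_gpr(model)
        reg = compile_regulation(model, epsilon or 1e-3)
    else:
        gpr, reg = indices
    perturb = (perturb or PerturbationVars()).validate_against(model)
    bounds = effective_bounds(model, env, big_m, min_growth)
    lp = MILP("rfba")
    add_flux_system(lp, model, bounds)
    names = add_logic_system(lp, model, gpr, reg, env, bounds,
                             perturb=perturb, regulation=regulation,
                             big_m=big_m)
    bio = vname(model.biomass_reaction_id)
    if fixed_growth is not None:
        lp.add_constr([(bio, 1.0)], lo=fixed_growth - growth_window,
                      hi=fixed_growth + growth_window)
    if objective is None:
        objective = model.biomass_reaction_id
    if isinstance(objective, str):
        obj_terms = {vname(objective): 1.0}
    else:
        obj_terms = {vname(j): c for j, c in objective.items()}
    lp.set_objective(obj_terms, maximize=maximize)
    res = lp.solve()
    if not res.optimal:
        lethal = res.status == "infeasible"
        return RegulatedFBAResult(res.status, {}, None, None, lethal)
    flux = {j: res.values[vname(j)] for j in model.reactions}
    growth = flux[model.biomass_reaction_id]
    return RegulatedFBAResult(res.status, flux, names.state(res), growth,
                              growth < LETHAL_TOL)


def theoretical_max_product(model: IntegratedModel, env: Environment,
                            product: str) -> float:
    """LP-maximal product flux under the environment, with no growth demand,
    no deletions and no regulation — the yield denominator."""
    res = solve_fba(model, env, objective=product)
    if not res.optimal:
        return np.nan
    return res.objective


# ---------------------------------------------------------------------------
# Production envelopes
# ---------------------------------------------------------------------------

def production_envelope(model: IntegratedModel, env: Environment, product: str,
                        n_points: int = 20,
                        *,
                        regulated: bool = False,
                        perturb: PerturbationVars | None = None,
                        d: Mapping[str, bool] | None = None,
                        indices=None,
                        epsilon: float | None = None) -> pd.DataFrame:
    """Min/max product flux across growth levels from 0 to the maximum.

    Unregulated sweeps are plain LPs with optional fixed reaction states
    ``d``; regulated sweeps re-solve the Boolean MILP at every growth level
    (regulatory constraints are enforced in each sub-solve, so the regulated
    envelope is contained in the unregulated one).  Growth levels that no
    consistent regulatory state can hit yield NaN rows.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")

    def solve_at(growth: float | None, objective, maximize):
        if regulated:
            r = solve_regulated_fba(model, env, perturb, objective=objective,
                                    maximize=maximize, fixed_growth=growth,
                                    growth_window=FEAS_TOL,
                                    indices=indices, epsilon=epsilon)
            return r.status, (None if r.flux == {} else
                              r.flux[objective if isinstance(objective, str) else product])
        fixed = None if growth is None else {model.biomass_reaction_id: growth}
        r = solve_fba(model, env, d=d, objective=objective, maximize=maximize,
                      fixed=fixed)
        return r.status, r.objective

    status, gmax = solve_at(None, model.biomass_reaction_id, True)
    if status != "optimal" or gmax is None or gmax < LETHAL_TOL:
        gmax = 0.0
        levels = [0.0]
    else:
        levels = list(np.linspace(0.0, gmax, n_points))
    rows = []
    for lvl in levels:
        s1, pmin = solve_at(lvl, product, False)
        s2, pmax = solve_at(lvl, product, True)
        rows.append({
            "growth": lvl,
            "product_min": pmin if s1 == "optimal" else np.nan,
            "product_max": pmax if s2 == "optimal" else np.nan,
        })
    return pd.DataFrame(rows)
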