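"""Design-audit analyses: minimal gene covers, regulated re-evaluation,
minimal overexpression rescue, yields, and intervention statistics.

These are the comparisons that expose the gap between reaction-level and
gene-level strain designs: a reaction-deletion strategy generally needs more
gene deletions than reactions (isozymes), removes additional reactions as
collateral (multifunctional enzymes), and may be lethal once transcriptional
regulation is imposed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .design import DesignSolution, evaluate_design
from .fba import FEAS_TOL, add_flux_system, add_logic_system, \
    add_inner_optimality, effective_bounds, theoretical_max_product, vname
from .logic import (GPRIndex, PerturbationVars, RegulatoryIndex, compile_gpr,
                    compile_regulation, reaction_feasibility)
from .milp import MILP
from .model import Environment, IntegratedModel

__all__ = [
    "GeneCover",
    "UncoverableError",
    "minimal_gene_cover",
    "reevaluate_designs",
    "RescueResult",
    "min_overexpression_rescue",
    "yield_percent",
    "intervention_stats",
]


class UncoverableError(ValueError):
    """A target reaction has no GPR and cannot be removed by gene deletion."""


@dataclass
class GeneCover:
    """Minimum-cardinality gene deletion set removing every target reaction,
    with the collaterally disabled non-target reactions."""

    genes: frozenset[str]
    collateral: frozenset[str]
    targets: frozenset[str]


def minimal_gene_cover(model: IntegratedModel, target_reactions: Iterable[str],
                       gpr_index: GPRIndex | None = None) -> GeneCover:
    """Smallest gene set whose deletion disables all targets.

    A reaction is disabled only when every one of its enzyme complexes loses
    a subunit, so this is a minimum hitting set over complexes, solved as a
    small MILP.  Spontaneous/orphan targets (no GPR) raise
    :class:`UncoverableError` — the case where a reaction-level strategy has
    no genetic implementation at all.
    """
    targets = list(dict.fromkeys(target_reactions))
    gpr = gpr_index or compile_gpr(model)
    orphans = [j for j in targets if j not in gpr]
    if orphans:
        raise UncoverableError(
            f"reactions not removable by gene deletion (no GPR): {orphans}")
    lp = MILP("genecover")
    genes = sorted({g for j in targets for cx in gpr.complexes[j] for g in cx})
    for g in genes:
        lp.add_binary(f"z[{g}]")
    for j in targets:
        for cx in gpr.complexes[j]:
            lp.add_constr([(f"z[{g}]", 1.0) for g in sorted(cx)], lo=1.0)
    lp.set_objective({f"z[{g}]": 1.0 for g in genes}, maximize=False)
    res = lp.solve()
    if not res.optimal:
        raise UncoverableError(f"no gene cover exists for {targets}")
    chosen = frozenset(g for g in genes if res.binary(f"z[{g}]"))
    y_hat = {g: g not in chosen for g in model.genes}
    d = reaction_feasibility(gpr, y_hat)
    collateral = frozenset(j for j, on in d.items()
                           if not on and j not in targets)
    return GeneCover(chosen, collateral, frozenset(targets))


def reevaluate_designs(model: IntegratedModel, env: Environment,
                       designs: Iterable[tuple[str, Iterable[str], Iterable[str]]],
                       product: str,
                       *,
                       regulated: bool = True,
                       viability_threshold: float = 0.1,
                       epsilon: float = 1e-3,
                       indices: tuple[GPRIndex, RegulatoryIndex] | None = None
                       ) -> pd.DataFrame:
    """Audit gene designs: growth/product/yield with or without regulation.

    ``designs`` yields (id, gene deletions, overexpressions) rows; reaction
    designs must first be converted with :func:`minimal_gene_cover`.  Growth
    is maximized without a floor, and a design is flagged lethal when its
    regulated optimum falls below ``viability_threshold`` (default 0.1/hr,
    the conventional minimal growth) or no consistent state exists at all.
    """
    if indices is None:
        indices = (compile_gpr(model), compile_regulation(model, epsilon))
    theo = theoretical_max_product(model, env, product)
    rows = []
    for design_id, dels, oes in designs:
        dels, oes = set(dels), set(oes)
        ev = evaluate_design(model, env, dels, oes, product,
                             regulation=regulated, min_growth=0.0,
                             indices=indices, epsilon=epsilon)
        growth = ev.growth if ev.viable else np.nan
        prod = ev.product if ev.viable else np.nan
        lethal = (not ev.viable) or growth < viability_threshold
        rows.append({
            "design_id": design_id,
            "n_deletions": len(dels),
            "n_overexpressions": len(oes),
            "growth": growth,
            "product": prod,
            "yield_pct": (100.0 * prod / theo
                          if theo and theo > FEAS_TOL and np.isfinite(prod)
                          else np.nan),
            "lethal": bool(lethal),
        })
    return pd.DataFrame(rows)


@dataclass
class RescueResult:
    status: str                      # optimal | unreachable
    genes: frozenset[str] | None
    target: float
    product: float | None = None


def min_overexpression_rescue(model: IntegratedModel, env: Environment,
                              deletions: Iterable[str], product: str,
                              target: float | None = None,
                              *,
                              min_growth: float = 0.1,
                              epsilon: float = 1e-3,
                              big_m: float = 1000.0,
                              h_bound: float | None = None) -> RescueResult:
    """Fewest overexpressions restoring a deletion design's unregulated yield.

    The target defaults to the design's product flux at growth optimum when
    regulation is ignored; the MILP then minimizes the number of repressed
    genes forced on, subject to the regulated growth optimum secreting at
    least the target.  Unreachable targets (even with every gene expressed)
    are reported as such.
    """
    dels = frozenset(deletions)
    gpr = compile_gpr(model)
    reg = compile_regulation(model, epsilon)
    if target is None:
        ev = evaluate_design(model, env, dels, (), product, regulation=False,
                             min_growth=min_growth, indices=(gpr, reg),
                             epsilon=epsilon)
        if not ev.viable or ev.product is None:
            return RescueResult("unreachable", None, np.nan)
        target = ev.product
    bounds = effective_bounds(model, env, big_m, min_growth)
    lp = MILP("rescue")
    add_flux_system(lp, model, bounds)
    names = add_logic_system(lp, model, gpr, reg, env, bounds,
                             perturb=PerturbationVars.from_sets(dels),
                             decision="w", k2=len(model.genes),
                             big_m=big_m)
    add_inner_optimality(lp, model, bounds, names.d, h_bound=h_bound,
                         big_m=big_m, link_primal=False)
    lp.add_constr([(vname(product), 1.0)], lo=target - FEAS_TOL)
    wvars = {g: v for g, v in names.w.items() if isinstance(v, str)}
    lp.set_objective({v: 1.0 for v in wvars.values()}, maximize=False)
    res = lp.solve()
    if not res.optimal:
        return RescueResult("unreachable", None, target)
    genes = frozenset(g for g, v in wvars.items() if res.binary(v))
    return RescueResult("optimal", genes, target,
                        res.values[vname(product)])


def yield_percent(model: IntegratedModel, env: Environment, product: str,
                  product_flux: float) -> float:
    """Product flux as % of the theoretical LP maximum (no growth demand)."""
    theo = theoretical_max_product(model, env, product)
    if not np.isfinite(theo) or theo <= FEAS_TOL:
        return np.nan
    return 100.0 * product_flux / theo


def _as_intervention_sets(design) -> tuple[frozenset, frozenset]:
    if isinstance(design, DesignSolution):
        return design.deletions, design.overexpressions
    if isinstance(design, Mapping):
        return (frozenset(design.get("deletions", ())),
                frozenset(design.get("overexpressions", ())))
    dels, *rest = design
    oes = rest[0] if rest else ()
    return frozenset(dels), frozenset(oes)


def intervention_stats(design_lists: Mapping[str, Iterable],
                       *,
                       pooled_threshold: float = 0.15,
                       per_method_threshold: float = 0.10
                       ) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Intervention frequencies and per-method correlation matrices.

    ``design_lists`` maps a method name to its designs (DesignSolution,
    (deletions, overexpressions) pairs, or dicts).  The frequency table lists
    interventions reaching ``pooled_threshold`` across all designs pooled
    (overexpressions are suffixed ``+``), with per-method columns.  For each
    method, interventions reaching ``per_method_threshold`` within that
    method get a Pearson correlation matrix of their 0/1 indicator vectors;
    always-co-occurring pairs correlate at 1, mutually exclusive ones
    negatively, and zero-variance pairs are NaN (reported missing, not 0).
    """
    if not design_lists:
        raise ValueError("at least one design list is required")
    indicators: dict[str, pd.DataFrame] = {}
    for method, designs in design_lists.items():
        rows = []
        for design in designs:
            dels, oes = _as_intervention_sets(design)
            rows.append({**{g: 1 for g in dels}, **{f"{g}+": 1 for g in oes}})
        indicators[method] = pd.DataFrame(rows).fillna(0).astype(int) \
            if rows else pd.DataFrame()

    all_cols = sorted({c for df in indicators.values() for c in df.columns})
    total = sum(len(df) for df in indicators.values())
    freq_rows = []
    for col in all_cols:
        pooled = sum(int(df[col].sum()) if col in df else 0
                     for df in indicators.values())
        row = {"intervention": col, "pooled_frequency": pooled / total}
        for method, df in indicators.items():
            n = len(df)
            row[method] = (float(df[col].sum()) / n if n and col in df else 0.0)
        freq_rows.append(row)
    freq = pd.DataFrame(freq_rows)
    if not freq.empty:
        freq = freq[freq["pooled_frequency"] >= pooled_threshold]
        freq = freq.sort_values("pooled_frequency", ascending=False,
                                kind="stable").reset_index(drop=True)

    correlations: dict[str, pd.DataFrame] = {}
    for method, df in indicators.items():
        if df.empty:
            correlations[method] = pd.DataFrame()
            continue
        keep = [c for c in df.columns
                if df[c].sum() / len(df) >= per_method_threshold]
        correlations[method] = df[keep].corr(method="pearson")
    return freq, correlations
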