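"""Thin mixed-integer linear programming layer over scipy's HiGHS backend.

Named variables, two-sided linear constraints, a single objective.  Constants
are allowed wherever a variable name is expected ("linear values"), which lets
callers build the same constraint blocks with fixed or free perturbations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

__all__ = ["MILP", "SolveResult", "LinVal"]

# a linear value: a variable name or a numeric constant
LinVal = str | float

_STATUS = {0: "optimal", 1: "limit", 2: "infeasible", 3: "unbounded", 4: "error"}


@dataclass
class SolveResult:
    status: str
    objective: float | None
    values: dict[str, float]
    mip_gap: float | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, name: LinVal) -> float:
        if isinstance(name, (int, float)):
            return float(name)
        return self.values[name]

    def binary(self, name: LinVal) -> bool:
        return self[name] > 0.5


class MILP:
    """Incrementally built LP/MILP, solved by HiGHS via scipy.optimize.milp."""

    def __init__(self, name: str = ""):
        self.name = name
        self._index: dict[str, int] = {}
        self._lb: list[float] = []
        self._ub: list[float] = []
        self._integer: list[bool] = []
        self._rows: list[dict[int, float]] = []
        self._row_lo: list[float] = []
        self._row_hi: list[float] = []
        self._obj: dict[int, float] = {}
        self._maximize = True

    # -- variables -----------------------------------------------------------

    def add_var(self, name: str, lb: float = 0.0, ub: float = np.inf,
                integer: bool = False) -> str:
        if name in self._index:
            raise ValueError(f"duplicate variable {name!r}")
        self._index[name] = len(self._lb)
        self._lb.append(float(lb))
        self._ub.append(float(ub))
        self._integer.append(bool(integer))
        return name

    def add_binary(self, name: str) -> str:
        return self.add_var(name, 0.0, 1.0, integer=True)

    def set_bounds(self, name: str, lb: float | None = None,
                   ub: float | None = None) -> None:
        i = self._index[name]
        if lb is not None:
            self._lb[i] = float(lb)
        if ub is not None:
            self._ub[i] = float(ub)

    def has_var(self, name: str) -> bool:
        return name in self._index

    # -- constraints -----------------------------------------------------------

    def add_constr(self, terms: Mapping[LinVal, float] | Sequence[tuple[LinVal, float]],
                   lo: float = -np.inf, hi: float = np.inf) -> None:
        """Add ``lo <= sum(coef * value) <= hi``.

        ``terms`` pairs linear values with coefficients; numeric values fold
        into the bounds, so callers can mix fixed and free quantities freely.
        """
        items = terms.items() if isinstance(terms, Mapping) else terms
        row: dict[int, float] = {}
        const = 0.0
        for val, coef in items:
            if coef == 0:
                continue
            if isinstance(val, str):
                i = self._index[val]
                row[i] = row.get(i, 0.0) + float(coef)
            else:
                const += float(val) * float(coef)
        lo2 = lo - const if np.isfinite(lo) else lo
        hi2 = hi - const if np.isfinite(hi) else hi
        if not row:
            if lo2 > 1e-9 or hi2 < -1e-9:
                # constant constraint violated: encode as an infeasible row
                self._rows.append({})
                self._row_lo.append(1.0)
                self._row_hi.append(-1.0)
            return
        self._rows.append(row)
        self._row_lo.append(lo2)
        self._row_hi.append(hi2)

    def add_eq(self, terms, rhs: float = 0.0) -> None:
        self.add_constr(terms, rhs, rhs)

    # -- objective -------------------------------------------------------------

    def set_objective(self, terms: Mapping[LinVal, float], maximize: bool = True) -> None:
        self._obj = {}
        self._obj_const = 0.0
        for val, coef in terms.items():
            if isinstance(val, str):
                i = self._index[val]
                self._obj[i] = self._obj.get(i, 0.0) + float(coef)
            else:
                self._obj_const += float(val) * float(coef)
        self._maximize = maximize

    # -- solving ----------------------------------------------------------------

    def solve(self, rel_gap: float = 0.0, time_limit: float | None = None) -> SolveResult:
        n = len(self._lb)
        c = np.zeros(n)
        for i, coef in self._obj.items():
            c[i] = coef
        sign = -1.0 if self._maximize else 1.0
        constraints = []
        if self._rows:
            m = len(self._rows)
            data, ri, ci = [], [], []
            for r, row in enumerate(self._rows):
                for i, coef in row.items():
                    ri.append(r)
                    ci.append(i)
                    data.append(coef)
            A = sparse.csr_array((data, (ri, ci)), shape=(m, n))
            constraints = [LinearConstraint(A, np.array(self._row_lo),
                                            np.array(self._row_hi))]
        options: dict = {"mip_rel_gap": rel_gap, "presolve": True}
        if time_limit is not None:
            options["time_limit"] = time_limit
        res = milp(sign * c, constraints=constraints,
                   integrality=np.array(self._integer, dtype=int),
                   bounds=Bounds(np.array(self._lb), np.array(self._ub)),
                   options=options)
        status = _STATUS.get(res.status, "error")
        if res.x is None and status == "optimal":
            status = "error"
        values: dict[str, float] = {}
        objective = None
        if res.x is not None:
            values = {name: float(res.x[i]) for name, i in self._index.items()}
            objective = float(sign * res.fun) + getattr(self, "_obj_const", 0.0)
        gap = getattr(res, "mip_gap", None)
        return SolveResult(status, objective, values, gap)
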