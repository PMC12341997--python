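"""Thin deterministic wrappers around scipy's HiGHS LP/MILP interfaces.

All optimisation in the package funnels through these two helpers so that
solver options, statuses, and tolerances are uniform.  Sense is always
"max" or "min"; scipy minimises, so objectives are negated on the way in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import LinearConstraint, linprog, milp
from scipy.sparse import csr_matrix

from .errors import InfeasibleError, SolverError


@dataclass
class OptResult:
    x: np.ndarray
    objective: float
    status: str  # "optimal" | "infeasible" | "unbounded"


def _check(status_code: int, message: str, allow_nonoptimal: bool) -> str:
    # scipy status codes: 0 optimal, 1 iteration limit, 2 infeasible, 3 unbounded
    mapping = {0: "optimal", 2: "infeasible", 3: "unbounded"}
    status = mapping.get(status_code, "error")
    if status == "optimal" or allow_nonoptimal:
        return status
    if status == "infeasible":
        raise InfeasibleError(message)
    raise SolverError(f"{message}: solver status {status_code}", status=status)


def solve_lp(
    c,
    A_eq=None,
    b_eq=None,
    A_ub=None,
    b_ub=None,
    bounds=None,
    sense: str = "min",
    allow_nonoptimal: bool = False,
) -> OptResult:
    """Solve a linear program with the HiGHS backend.

    ``bounds`` is a sequence of (lo, hi) pairs; ``None`` entries mean free.
    Raises :class:`InfeasibleError`/:class:`SolverError` unless
    ``allow_nonoptimal`` is set, in which case the status is reported.
    """
    c = np.asarray(c, dtype=float)
    sign = -1.0 if sense == "max" else 1.0
    res = linprog(
        sign * c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
    )
    status = _check(res.status, res.message, allow_nonoptimal)
    x = res.x if res.x is not None else np.full(c.shape, np.nan)
    obj = sign * res.fun if res.fun is not None else np.nan
    return OptResult(x=np.asarray(x, dtype=float), objective=obj, status=status)


@dataclass
class MilpProblem:
    """Incrementally built mixed-integer linear program.

    Variables are added with :meth:`add_var`; rows with :meth:`add_constraint`
    as (coeffs, lo, hi) where coeffs maps variable index -> coefficient.
    """

    c: list = field(default_factory=list)
    lb: list = field(default_factory=list)
    ub: list = field(default_factory=list)
    integrality: list = field(default_factory=list)
    rows: list = field(default_factory=list)  # (dict idx->coef, lo, hi)

    def add_var(self, cost=0.0, lb=0.0, ub=np.inf, integer=False) -> int:
        self.c.append(float(cost))
        self.lb.append(lb)
        self.ub.append(ub)
        self.integrality.append(1 if integer else 0)
        return len(self.c) - 1

    def add_constraint(self, coeffs: dict, lo=-np.inf, hi=np.inf) -> None:
        self.rows.append((dict(coeffs), float(lo), float(hi)))

    def solve(self, sense: str = "min", allow_nonoptimal: bool = False) -> OptResult:
        n = len(self.c)
        c = np.asarray(self.c, dtype=float)
        sign = -1.0 if sense == "max" else 1.0
        constraints = []
        if self.rows:
            data, ri, ci, lo, hi = [], [], [], [], []
            for k, (coeffs, l, h) in enumerate(self.rows):
                for j, v in coeffs.items():
                    ri.append(k)
                    ci.append(j)
                    data.append(float(v))
                lo.append(l)
                hi.append(h)
            A = csr_matrix((data, (ri, ci)), shape=(len(self.rows), n))
            constraints = [LinearConstraint(A, lo, hi)]
        from scipy.optimize import Bounds

        res = milp(
            sign * c,
            constraints=constraints,
            integrality=np.asarray(self.integrality),
            bounds=Bounds(np.asarray(self.lb, float), np.asarray(self.ub, float)),
        )
        status = _check(res.status, res.message or "milp failed", allow_nonoptimal)
        x = res.x if res.x is not None else np.full(n, np.nan)
        obj = sign * res.fun if res.fun is not None else np.nan
        return OptResult(x=np.asarray(x, dtype=float), objective=obj, status=status)
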