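"""Assemble and solve menu-planning MILPs; exhaustive oracle for tests.

Serving counts are integer variables with finite upper bounds taken from
the repetition limits; goal-program deviation variables are continuous and
non-negative (partial portions of foods are never selected, but deviations
are plain slack quantities).  Models are solved to proven optimality with
branch-and-bound over the simplex relaxation (HiGHS via
``scipy.optimize.milp``); the enumeration oracle walks the full integer
lattice and evaluates the same objective in closed form, so the two routes
are independent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, sparse

from .constraints import (LinearConstraint, check_feasibility, LE, GE, EQ)
from .items import (MenuItem, NutritionStandards, RepetitionLimits,
                    WeeklyMenu)
from .objectives import ObjectiveSpec, AT_LEAST

log = logging.getLogger(__name__)

OPTIMAL, INFEASIBLE, UNBOUNDED, ERROR = ("optimal", "infeasible",
                                         "unbounded", "error")

#: absolute optimality / integrality tolerance
TOL = 1e-6


@dataclass
class ModelSpec:
    """A complete optimisation model: pool, constraints, objective, bounds."""

    name: str
    pool: list[MenuItem]
    constraints: list[LinearConstraint]
    objective: ObjectiveSpec
    upper_bounds: dict[str, int]

    def __post_init__(self):
        ids = {it.item_id for it in self.pool}
        for c in self.constraints:
            unknown = set(c.coefficients) - ids
            if unknown:
                raise ValueError(
                    f"constraint {c.label} references unknown items "
                    f"{sorted(unknown)}")
        for i in ids:
            ub = self.upper_bounds.get(i)
            if ub is None or not math.isfinite(ub):
                raise ValueError(f"item {i} lacks a finite upper bound")

    def lattice_size(self) -> int:
        size = 1
        for it in self.pool:
            size *= self.upper_bounds[it.item_id] + 1
        return size


@dataclass
class SolveResult:
    status: str
    menu: WeeklyMenu | None = None
    objective_value: float | None = None
    deviations: dict[str, float] = field(default_factory=dict)
    solver_log: str = ""


def assemble_model(pool: Sequence[MenuItem],
                   standards: NutritionStandards,
                   objective: ObjectiveSpec,
                   limits: RepetitionLimits | None = None,
                   constraints: Sequence[LinearConstraint] | None = None,
                   name: str | None = None) -> ModelSpec:
    """Combine the standard constraint set with an objective into a model."""
    from .constraints import build_all_constraints
    if limits is None:
        limits = RepetitionLimits()
    if constraints is None:
        constraints = build_all_constraints(pool, standards, limits)
    # repetition caps, tightened by the implied per-category serving counts
    cat_cap = {"entree": standards.entree_count,
               "fruit": standards.fruit_count,
               "vegetable": standards.vegetable_count_max,
               "milk": standards.milk_count}
    ubs = {it.item_id: min(limits.item_limit(it),
                           cat_cap.get(it.category, standards.week_length))
           for it in pool}
    return ModelSpec(name=name or objective.name, pool=list(pool),
                     constraints=list(constraints), objective=objective,
                     upper_bounds=ubs)


def _deviations(objective: ObjectiveSpec,
                servings: dict[str, int]) -> dict[str, float]:
    return {g.name: g.deviation(servings) for g in objective.goals}


def solve(model: ModelSpec, week_length: int = 5) -> SolveResult:
    """Solve to proven optimality; integer servings, continuous deviations."""
    items = [it.item_id for it in model.pool]
    col = {i: k for k, i in enumerate(items)}
    n_x = len(items)
    goals = model.objective.goals
    n = n_x + len(goals)

    c = np.zeros(n)
    sign = -1.0 if model.objective.sense == "max" else 1.0
    for i, v in model.objective.coefficients.items():
        c[col[i]] = sign * v
    for k, g in enumerate(goals):
        c[n_x + k] = g.weight / g.normaliser

    rows, cols, vals, lo, hi = [], [], [], [], []

    def add_row(coeffs: dict[int, float], lb: float, ub: float):
        r = len(lo)
        for j, v in coeffs.items():
            rows.append(r); cols.append(j); vals.append(v)
        lo.append(lb); hi.append(ub)

    for con in model.constraints:
        coeffs = {col[i]: v for i, v in con.coefficients.items()}
        if con.sense == LE:
            add_row(coeffs, -np.inf, con.rhs)
        elif con.sense == GE:
            add_row(coeffs, con.rhs, np.inf)
        else:
            add_row(coeffs, con.rhs, con.rhs)
    for k, g in enumerate(goals):
        coeffs = {col[i]: v for i, v in g.coefficients.items()}
        if g.direction == AT_LEAST:        # achieved + d >= G
            coeffs[n_x + k] = 1.0
            add_row(coeffs, g.goal_value, np.inf)
        else:                              # achieved - d <= G
            coeffs[n_x + k] = -1.0
            add_row(coeffs, -np.inf, g.goal_value)

    A = sparse.csr_array((vals, (rows, cols)), shape=(len(lo), n))
    lb = np.zeros(n)
    ub = np.array([float(model.upper_bounds[i]) for i in items]
                  + [np.inf] * len(goals))
    integrality = np.array([1] * n_x + [0] * len(goals))

    res = optimize.milp(
        c,
        constraints=optimize.LinearConstraint(A, np.array(lo), np.array(hi)),
        bounds=optimize.Bounds(lb, ub),
        integrality=integrality,
        options={"mip_rel_gap": 0.0, "presolve": True},
    )
    log.info("model %s: status=%s", model.name, res.status)

    if res.status == 2:
        return SolveResult(INFEASIBLE, solver_log=_infeasibility_hint(model))
    if res.status == 3:
        return SolveResult(UNBOUNDED, solver_log=res.message)
    if res.status != 0 or res.x is None:
        return SolveResult(ERROR, solver_log=res.message)

    x = res.x[:n_x]
    xi = np.rint(x).astype(int)
    if np.max(np.abs(x - xi)) > 1e-4:
        return SolveResult(ERROR,
                           solver_log=f"non-integral solution: {x}")
    servings = {items[k]: int(xi[k]) for k in range(n_x)}
    menu = WeeklyMenu(servings=servings, week_length=week_length)
    # evaluate the objective in closed form from the integer solution so the
    # reported value is exact (deviations are determined by x)
    value = model.objective.value(servings)
    return SolveResult(OPTIMAL, menu=menu, objective_value=value,
                       deviations=_deviations(model.objective, servings),
                       solver_log=res.message)


def _infeasibility_hint(model: ModelSpec) -> str:
    """Name the first constraint class unreachable even within variable
    bounds alone — a coarse irreducible-cause hint."""
    ubs = model.upper_bounds
    for con in model.constraints:
        max_lhs = sum(v * ubs[i] for i, v in con.coefficients.items() if v > 0)
        min_lhs = sum(v * ubs[i] for i, v in con.coefficients.items() if v < 0)
        if con.sense in (GE, EQ) and max_lhs < con.rhs - TOL:
            return (f"infeasible: {con.label} cannot reach {con.rhs:g} "
                    f"(max attainable {max_lhs:g})")
        if con.sense in (LE, EQ) and min_lhs > con.rhs + TOL:
            return (f"infeasible: {con.label} cannot get below {con.rhs:g} "
                    f"(min attainable {min_lhs:g})")
    return "infeasible: constraint interaction (no single unreachable bound)"


def enumerate_feasible(model: ModelSpec,
                       enumeration_cap: int = 10_000_000) -> np.ndarray:
    """All feasible integer serving vectors, as an (n_items, n_feasible)
    array in pool order.  Depends only on the constraints and bounds, so it
    can be shared by every objective over the same pool.  Refuses lattices
    above ``enumeration_cap``."""
    size = model.lattice_size()
    if size > enumeration_cap:
        raise ValueError(
            f"lattice of {size} vectors exceeds enumeration cap "
            f"{enumeration_cap}")
    items = [it.item_id for it in model.pool]
    col = {i: k for k, i in enumerate(items)}
    ranges = [np.arange(model.upper_bounds[i] + 1, dtype=np.int16)
              for i in items]
    grids = np.meshgrid(*ranges, indexing="ij")
    X = np.stack([g.ravel() for g in grids]).astype(np.float64)  # (n, size)

    feasible = np.ones(X.shape[1], dtype=bool)
    for con in model.constraints:
        a = np.zeros(len(items))
        for i, v in con.coefficients.items():
            a[col[i]] = v
        lhs = a @ X
        if con.sense == LE:
            feasible &= lhs <= con.rhs + TOL
        elif con.sense == GE:
            feasible &= lhs >= con.rhs - TOL
        else:
            feasible &= np.abs(lhs - con.rhs) <= TOL
    return X[:, feasible]


def brute_force_optimum(model: ModelSpec,
                        enumeration_cap: int = 10_000_000,
                        week_length: int = 5,
                        feasible: np.ndarray | None = None) -> SolveResult:
    """Exhaustively enumerate the integer lattice and return the true
    optimum.  Test oracle only; refuses lattices above ``enumeration_cap``.

    Goal-program deviations are not enumerated: given integer servings x
    the optimal deviations are determined in closed form, so enumerating x
    alone suffices.  A precomputed ``feasible`` set (from
    :func:`enumerate_feasible` on a model with the same constraints and
    bounds) may be supplied to amortise the lattice walk across objectives.
    """
    if feasible is None:
        feasible = enumerate_feasible(model, enumeration_cap)
    if feasible.shape[1] == 0:
        return SolveResult(INFEASIBLE, solver_log="enumeration: empty lattice")
    items = [it.item_id for it in model.pool]
    col = {i: k for k, i in enumerate(items)}
    Xf = feasible
    obj = model.objective
    if obj.is_goal_program:
        values = np.zeros(Xf.shape[1])
        for g in obj.goals:
            a = np.zeros(len(items))
            for i, v in g.coefficients.items():
                a[col[i]] = v
            achieved = a @ Xf
            dev = (np.maximum(0.0, g.goal_value - achieved)
                   if g.direction == AT_LEAST
                   else np.maximum(0.0, achieved - g.goal_value))
            values += g.weight * dev / g.normaliser
        best = int(np.argmin(values))
    else:
        a = np.zeros(len(items))
        for i, v in obj.coefficients.items():
            a[col[i]] = v
        values = a @ Xf
        best = int(np.argmax(values) if obj.sense == "max"
                   else np.argmin(values))
    servings = {items[k]: int(Xf[k, best]) for k in range(len(items))}
    menu = WeeklyMenu(servings=servings, week_length=week_length)
    return SolveResult(OPTIMAL, menu=menu,
                       objective_value=obj.value(servings),
                       deviations=_deviations(obj, servings),
                       solver_log=f"enumeration over {Xf.shape[1]} "
                                  f"feasible vectors")


def to_lp_string(model: ModelSpec) -> str:
    """Export the model in CPLEX LP text format for inspection."""
    items = [it.item_id for it in model.pool]
    goals = model.objective.goals

    def term(v: float, name: str) -> str:
        return f"{'+' if v >= 0 else '-'} {abs(v):.12g} {name}"

    lines = ["Minimize" if model.objective.sense == "min" or goals
             else "Maximize", " obj:"]
    if goals:
        parts = [term(g.weight / g.normaliser, f"d_{g.name}") for g in goals]
    else:
        parts = [term(v, i) for i, v in model.objective.coefficients.items()]
    lines[-1] += " " + " ".join(parts)
    lines.append("Subject To")
    for k, con in enumerate(model.constraints):
        body = " ".join(term(v, i) for i, v in con.coefficients.items())
        sense = {LE: "<=", GE: ">=", EQ: "="}[con.sense]
        lines.append(f" c{k}_{con.label.replace(' ', '_')}: "
                     f"{body} {sense} {con.rhs:.12g}")
    for g in goals:
        body = " ".join(term(v, i) for i, v in g.coefficients.items())
        if g.direction == AT_LEAST:
            lines.append(f" goal_{g.name}: {body} + 1 d_{g.name} "
                         f">= {g.goal_value:.12g}")
        else:
            lines.append(f" goal_{g.name}: {body} - 1 d_{g.name} "
                         f"<= {g.goal_value:.12g}")
    lines.append("Bounds")
    for i in items:
        lines.append(f" 0 <= {i} <= {model.upper_bounds[i]}")
    lines.append("General")
    lines.append(" " + " ".join(items))
    lines.append("End")
    return "\n".join(lines) + "\n"


def verify_solution(result: SolveResult, model: ModelSpec) -> list:
    """Feasibility violations of a solve result (empty for a true optimum)."""
    if result.status != OPTIMAL or result.menu is None:
        return []
    return check_feasibility(result.menu, model.constraints)
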