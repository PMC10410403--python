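"""The seven objective functions, including weighted goal programs.

Single-objective models are plain linear forms over the serving counts:

* MAX-CALCON  — maximise kcal consumed (per-serving kcal x consumption
  fraction),
* MAX-COSTCON — maximise USD of food value consumed,
* MIN-COST    — minimise weekly food cost,
* MAX-HEI     — a goal program driving each of the 13 HEI components to its
  max-score standard (HEI itself is a ratio of linear forms, hence not
  directly maximisable by linear programming; the exact HEI of the optimum
  is always recomputed afterwards by the scorer).

Multi-objective models (MIN-DEV, MIN-DEV10, MIN-DEV30) minimise the
weighted sum of relative deviations from a set of goals: for each goal g
with value G_g a deviation variable d_g >= 0 is linked by

    at_least:  achieved_g + d_g >= G_g
    at_most:   achieved_g - d_g <= G_g

and the objective is  minimise sum_g w_g * d_g / |G_g|.  The three models
differ only in the weight on the calories-consumed goal (1, 10, 30).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .hei import (HEIStandards, KCAL_PER_G_FAT, KCAL_PER_TSP_ADDED_SUGAR,
                  ADEQUACY)
from .items import MenuItem, NutritionStandards, consumption_fraction

AT_LEAST, AT_MOST = "at_least", "at_most"

MODEL_NAMES = ("MAX-CALCON", "MAX-COSTCON", "MIN-COST", "MAX-HEI",
               "MIN-DEV", "MIN-DEV10", "MIN-DEV30")


class GoalError(ValueError):
    pass


@dataclass(frozen=True)
class GoalSpec:
    """One goal of a weighted goal program.

    ``coefficients`` define the achieved value as a linear form over the
    serving counts.  ``scale`` normalises the deviation (relative
    deviation); it defaults to |goal_value| and must be supplied explicitly
    for the rare zero-valued goal.
    """

    name: str
    coefficients: dict[str, float]
    goal_value: float
    direction: str                 # at_least | at_most
    weight: float = 1.0
    scale: float | None = None

    def __post_init__(self):
        if self.direction not in (AT_LEAST, AT_MOST):
            raise GoalError(f"{self.name}: bad direction {self.direction}")
        if self.weight < 0:
            raise GoalError(f"{self.name}: negative weight")
        if self.goal_value == 0 and not self.scale:
            raise GoalError(
                f"{self.name}: zero goal value needs an explicit scale "
                f"for the relative deviation")
        if self.scale is not None and self.scale <= 0:
            raise GoalError(f"{self.name}: scale must be positive")

    @property
    def normaliser(self) -> float:
        return self.scale if self.scale is not None else abs(self.goal_value)

    def achieved(self, servings: dict[str, int]) -> float:
        return sum(c * servings.get(i, 0)
                   for i, c in self.coefficients.items())

    def deviation(self, servings: dict[str, int]) -> float:
        """The penalised (one-sided) deviation at a given serving vector."""
        a = self.achieved(servings)
        if self.direction == AT_LEAST:
            return max(0.0, self.goal_value - a)
        return max(0.0, a - self.goal_value)


@dataclass
class ObjectiveSpec:
    """A linear objective: either a direct form or a goal program."""

    name: str
    sense: str                                   # min | max
    coefficients: dict[str, float] = field(default_factory=dict)
    goals: list[GoalSpec] = field(default_factory=list)

    def __post_init__(self):
        if self.sense not in ("min", "max"):
            raise GoalError(f"bad sense {self.sense}")
        if self.goals and self.sense != "min":
            raise GoalError("goal programs minimise deviations")
        if self.goals and not any(g.weight > 0 for g in self.goals):
            raise GoalError("at least one goal weight must be positive")

    @property
    def is_goal_program(self) -> bool:
        return bool(self.goals)

    def value(self, servings: dict[str, int]) -> float:
        """Objective value at a serving vector (deviations computed in
        closed form for goal programs — the optimal d_g given x)."""
        if self.is_goal_program:
            return sum(g.weight * g.deviation(servings) / g.normaliser
                       for g in self.goals)
        return sum(c * servings.get(i, 0)
                   for i, c in self.coefficients.items())


def _consumed_coeffs(pool: Sequence[MenuItem], attr: str) -> dict[str, float]:
    out = {}
    for it in pool:
        per = it.nutrients["energy_kcal"] if attr == "energy" else it.cost
        out[it.item_id] = per * consumption_fraction(it)
    return out


def objective_max_kcal_consumed(pool: Sequence[MenuItem]) -> ObjectiveSpec:
    """O1 / MAX-CALCON: maximise total energy consumed."""
    return ObjectiveSpec("MAX-CALCON", "max", _consumed_coeffs(pool, "energy"))


def objective_max_value_consumed(pool: Sequence[MenuItem]) -> ObjectiveSpec:
    """O2 / MAX-COSTCON: maximise total food value (USD) consumed."""
    return ObjectiveSpec("MAX-COSTCON", "max", _consumed_coeffs(pool, "cost"))


def objective_min_cost(pool: Sequence[MenuItem]) -> ObjectiveSpec:
    """O3 / MIN-COST: minimise weekly food cost."""
    return ObjectiveSpec("MIN-COST", "min",
                         {it.item_id: it.cost for it in pool})


def objective_min_footprint(pool: Sequence[MenuItem],
                            which: str) -> ObjectiveSpec:
    """Auxiliary single objectives minimising GWP or water scarcity; used
    to place the environmental goals of the multi-objective models at their
    ideal point."""
    if which == "gwp":
        return ObjectiveSpec("MIN-GWP", "min",
                             {it.item_id: it.gwp for it in pool})
    return ObjectiveSpec("MIN-WATER", "min",
                         {it.item_id: it.water_scarcity for it in pool})


def hei_component_goals(pool: Sequence[MenuItem],
                        standards: HEIStandards,
                        e_ref: float,
                        weight: float = 1.0) -> list[GoalSpec]:
    """Goals driving each HEI component to its max-score standard.

    Densities are ratios of linear forms, so each component's standard is
    converted to a weekly amount at a fixed reference energy ``e_ref``
    (kcal per week): adequacy goals ask for at least max_standard x
    e_ref/1000 of the component; moderation goals ask for at most
    min_standard x e_ref/1000 (amounts) or min_standard% of e_ref
    (percent-energy components).  The fatty-acid ratio goal is linearised
    as sum((pufa+mufa - R*sfa) x) >= 0 with R the max-score ratio, using an
    explicit scale since the goal value is zero.
    """
    if e_ref <= 0:
        raise GoalError("reference energy must be positive")
    goals: list[GoalSpec] = []
    for name, std in standards.components.items():
        if std.kind == "fat_ratio":
            coeffs = {it.item_id:
                      it.nutrients.get("pufa_g", 0.0)
                      + it.nutrients.get("mufa_g", 0.0)
                      - std.max_standard * it.nutrients.get("sfa_g", 0.0)
                      for it in pool}
            goals.append(GoalSpec(f"hei_{name}", coeffs, 0.0, AT_LEAST,
                                  weight=weight, scale=e_ref / 1000.0))
            continue
        if std.kind == "percent_energy":
            if name == "added_sugars":
                coeffs = {it.item_id:
                          it.nutrients.get("added_sugar_tsp", 0.0)
                          * KCAL_PER_TSP_ADDED_SUGAR for it in pool}
            else:
                coeffs = {it.item_id:
                          it.nutrients.get("saturated_fat_g", 0.0)
                          * KCAL_PER_G_FAT for it in pool}
            target_pct = (std.max_standard if std.direction == ADEQUACY
                          else std.min_standard)
            goals.append(GoalSpec(f"hei_{name}", coeffs,
                                  target_pct / 100.0 * e_ref,
                                  AT_LEAST if std.direction == ADEQUACY
                                  else AT_MOST, weight=weight))
            continue
        if name == "sodium":
            coeffs = {it.item_id: it.nutrients.get("sodium_mg", 0.0) / 1000.0
                      for it in pool}
        else:
            coeffs = {it.item_id: it.hei_components.get(name, 0.0)
                      for it in pool}
        if std.direction == ADEQUACY:
            goals.append(GoalSpec(f"hei_{name}", coeffs,
                                  std.max_standard * e_ref / 1000.0,
                                  AT_LEAST, weight=weight))
        else:
            goals.append(GoalSpec(f"hei_{name}", coeffs,
                                  std.min_standard * e_ref / 1000.0,
                                  AT_MOST, weight=weight))
    return goals


def objective_max_hei(pool: Sequence[MenuItem],
                      standards: HEIStandards,
                      e_ref: float) -> ObjectiveSpec:
    """O4 / MAX-HEI: equal-weight goal program over the 13 HEI components."""
    return ObjectiveSpec("MAX-HEI", "min",
                         goals=hei_component_goals(pool, standards, e_ref))


def build_goal_program(name: str, goals: Sequence[GoalSpec]) -> ObjectiveSpec:
    """O5–O7: minimise the weighted sum of relative deviations."""
    return ObjectiveSpec(name, "min", goals=list(goals))


def reference_energy(standards: NutritionStandards) -> float:
    """Midpoint of the weekly energy band, fixing the density denominator."""
    return 0.5 * (standards.energy_min_kcal + standards.energy_max_kcal)


def multiobjective_goals(pool: Sequence[MenuItem],
                         nutrition: NutritionStandards,
                         hei_standards: HEIStandards,
                         ideal: dict[str, float],
                         kcal_weight: float = 1.0) -> list[GoalSpec]:
    """Goal set of the multi-objective models, anchored at the ideal point.

    ``ideal`` maps {kcal_consumed, cost, gwp, water_scarcity} to the
    corresponding single-objective optimum under the common constraints.
    ``kcal_weight`` is 1, 10 or 30 for MIN-DEV, MIN-DEV10, MIN-DEV30.
    """
    goals = [
        GoalSpec("kcal_consumed", _consumed_coeffs(pool, "energy"),
                 ideal["kcal_consumed"], AT_LEAST, weight=kcal_weight),
        GoalSpec("cost", {it.item_id: it.cost for it in pool},
                 ideal["cost"], AT_MOST),
        GoalSpec("gwp", {it.item_id: it.gwp for it in pool},
                 ideal["gwp"], AT_MOST,
                 scale=ideal["gwp"] if ideal["gwp"] > 0 else 1.0),
        GoalSpec("water_scarcity",
                 {it.item_id: it.water_scarcity for it in pool},
                 ideal["water_scarcity"], AT_MOST,
                 scale=(ideal["water_scarcity"]
                        if ideal["water_scarcity"] > 0 else 1.0)),
    ]
    goals += hei_component_goals(pool, hei_standards,
                                 reference_energy(nutrition))
    return goals


def default_goals(pool: Sequence[MenuItem],
                  nutrition: NutritionStandards,
                  hei_standards: HEIStandards,
                  limits=None,
                  kcal_weight: float = 1.0) -> list[GoalSpec]:
    """Goal values anchored at the ideal point.

    Each of {kcal consumed, cost, GWP, water scarcity} is set to its own
    single-objective optimum under the common constraints, so every goal is
    individually attainable and deviations measure the price of pursuing
    all of them at once.  Deterministic: repeated calls give identical
    goals.  Raises if any underlying single-objective model is infeasible.
    """
    from . import solver  # deferred: solver depends on this module

    ideal: dict[str, float] = {}
    for key, obj in [
        ("kcal_consumed", objective_max_kcal_consumed(pool)),
        ("cost", objective_min_cost(pool)),
        ("gwp", objective_min_footprint(pool, "gwp")),
        ("water_scarcity", objective_min_footprint(pool, "water")),
    ]:
        res = solver.solve(solver.assemble_model(pool, nutrition, obj,
                                                 limits=limits),
                           week_length=nutrition.week_length)
        if res.status != "optimal":
            raise GoalError(
                f"cannot anchor goal {key}: model {obj.name} is {res.status}")
        ideal[key] = res.objective_value
    return multiobjective_goals(pool, nutrition, hei_standards, ideal,
                                kcal_weight=kcal_weight)
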