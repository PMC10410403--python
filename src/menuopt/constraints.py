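"""Translate NSLP standards and repetition rules into linear constraints.

Every constraint is linear over the integer serving counts x_i.  Food-group
quantities (fruit cups, grain oz eq, ...) are taken from the per-item HEI
component amounts; nutrient bounds from the per-item nutrient maps.  The
saturated-fat cap, stated as a percent of energy, is linearised by moving
all terms to one side:  sum((satfat_kcal_i - frac * energy_i) * x_i) <= 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .hei import KCAL_PER_G_FAT
from .items import (MenuItem, NutritionStandards, RepetitionLimits,
                    WeeklyMenu, MenuDataError)

LE, GE, EQ = "<=", ">=", "=="


class InfeasibleStructureError(MenuDataError):
    """The pool cannot structurally satisfy the category requirements."""


@dataclass(frozen=True)
class LinearConstraint:
    """One linear row: sum(coefficients[i] * x_i)  sense  rhs."""

    coefficients: dict[str, float]
    sense: str
    rhs: float
    label: str

    def __post_init__(self):
        if self.sense not in (LE, GE, EQ):
            raise MenuDataError(f"{self.label}: bad sense {self.sense}")
        if not self.label:
            raise MenuDataError("constraint label must be non-empty")

    def lhs(self, servings: dict[str, int]) -> float:
        return sum(c * servings.get(i, 0)
                   for i, c in self.coefficients.items())

    def satisfied(self, servings: dict[str, int], tol: float = 1e-6) -> bool:
        v = self.lhs(servings)
        if self.sense == LE:
            return v <= self.rhs + tol
        if self.sense == GE:
            return v >= self.rhs - tol
        return abs(v - self.rhs) <= tol


@dataclass
class Violation:
    label: str
    lhs: float
    sense: str
    rhs: float

    def __str__(self) -> str:
        return f"{self.label}: {self.lhs:g} {self.sense} {self.rhs:g} violated"


def build_category_constraints(pool: Sequence[MenuItem],
                               standards: NutritionStandards,
                               ) -> list[LinearConstraint]:
    """One entrée, fruit and milk per lunch; one to two vegetables."""
    by_cat: dict[str, list[str]] = {}
    for it in pool:
        by_cat.setdefault(it.category, []).append(it.item_id)
    for cat in ("entree", "fruit", "vegetable", "milk"):
        if cat not in by_cat:
            raise InfeasibleStructureError(f"pool has no {cat} items")
    ones = lambda ids: {i: 1.0 for i in ids}
    return [
        LinearConstraint(ones(by_cat["entree"]), EQ,
                         standards.entree_count, "entree-count"),
        LinearConstraint(ones(by_cat["fruit"]), EQ,
                         standards.fruit_count, "fruit-count"),
        LinearConstraint(ones(by_cat["milk"]), EQ,
                         standards.milk_count, "milk-count"),
        LinearConstraint(ones(by_cat["vegetable"]), GE,
                         standards.vegetable_count_min, "vegetable-count-min"),
        LinearConstraint(ones(by_cat["vegetable"]), LE,
                         standards.vegetable_count_max, "vegetable-count-max"),
    ]


def build_nutrition_constraints(pool: Sequence[MenuItem],
                                standards: NutritionStandards,
                                ) -> list[LinearConstraint]:
    for it in pool:
        for key in ("energy_kcal", "sodium_mg", "saturated_fat_g"):
            if key not in it.nutrients:
                raise MenuDataError(
                    f"item {it.item_id} is missing nutrient {key}")

    def coeffs(fn) -> dict[str, float]:
        return {it.item_id: v for it in pool if (v := fn(it)) != 0.0}

    rows = [
        LinearConstraint(coeffs(lambda i: i.nutrients["energy_kcal"]), GE,
                         standards.energy_min_kcal, "energy-min"),
        LinearConstraint(coeffs(lambda i: i.nutrients["energy_kcal"]), LE,
                         standards.energy_max_kcal, "energy-max"),
        LinearConstraint(coeffs(lambda i: i.nutrients["sodium_mg"]), LE,
                         standards.sodium_max_mg, "sodium-max"),
        # sat-fat cap as % of energy, all terms on one side
        LinearConstraint(
            coeffs(lambda i:
                   i.nutrients["saturated_fat_g"] * KCAL_PER_G_FAT
                   - standards.saturated_fat_max_frac_energy
                   * i.nutrients["energy_kcal"]),
            LE, 0.0, "saturated-fat-pct-energy"),
        LinearConstraint(
            coeffs(lambda i: i.hei_components.get("total_fruit", 0.0)), GE,
            standards.fruit_min_cup, "fruit-cups-min"),
        LinearConstraint(
            coeffs(lambda i: i.hei_components.get("total_veg", 0.0)), GE,
            standards.total_veg_min_cup, "vegetable-cups-min"),
        LinearConstraint(
            coeffs(lambda i: i.hei_components.get("whole_grains", 0.0)
                   + i.hei_components.get("refined_grains", 0.0)), GE,
            standards.grains_min_oz, "grains-oz-min"),
        LinearConstraint(
            coeffs(lambda i: i.hei_components.get("whole_grains", 0.0)
                   + i.hei_components.get("refined_grains", 0.0)), LE,
            standards.grains_max_oz, "grains-oz-max"),
        LinearConstraint(
            coeffs(lambda i: i.hei_components.get("total_protein", 0.0)), GE,
            standards.meat_alt_min_oz, "meat-alt-oz-min"),
        LinearConstraint(
            coeffs(lambda i: i.hei_components.get("total_protein", 0.0)), LE,
            standards.meat_alt_max_oz, "meat-alt-oz-max"),
        LinearConstraint(
            coeffs(lambda i: i.hei_components.get("dairy", 0.0)
                   if i.category == "milk" else 0.0), GE,
            standards.milk_min_cup, "milk-cups-min"),
    ]
    for subgroup, min_cup in standards.veg_subgroup_min_cup.items():
        if min_cup <= 0:
            continue
        rows.append(LinearConstraint(
            coeffs(lambda i, s=subgroup:
                   i.hei_components.get("total_veg", 0.0)
                   if i.vegetable_subgroup == s else 0.0),
            GE, min_cup, f"veg-subgroup-{subgroup}-min"))
    return rows


def build_cost_constraint(pool: Sequence[MenuItem],
                          standards: NutritionStandards) -> LinearConstraint:
    """Weekly food cost must not exceed the reimbursement-derived budget."""
    return LinearConstraint(
        {it.item_id: it.cost for it in pool}, LE, standards.budget, "budget")


def build_repetition_constraints(pool: Sequence[MenuItem],
                                 limits: RepetitionLimits,
                                 ) -> list[LinearConstraint]:
    """Per-item caps plus protein-type and flavour-profile group caps."""
    rows = [LinearConstraint({it.item_id: 1.0}, LE, limits.item_limit(it),
                             f"repeat-{it.item_id}")
            for it in pool]
    proteins: dict[str, list[str]] = {}
    flavors: dict[str, list[str]] = {}
    for it in pool:
        if it.category != "entree":
            continue
        proteins.setdefault(it.protein_subcategory, []).append(it.item_id)
        if it.flavor_subcategory:
            flavors.setdefault(it.flavor_subcategory, []).append(it.item_id)
    for sub, ids in sorted(proteins.items()):
        rows.append(LinearConstraint({i: 1.0 for i in ids}, LE,
                                     limits.protein_subcategory_limit,
                                     f"protein-{sub}-limit"))
    for sub, ids in sorted(flavors.items()):
        rows.append(LinearConstraint({i: 1.0 for i in ids}, LE,
                                     limits.flavor_subcategory_limit,
                                     f"flavor-{sub}-limit"))
    return rows


def build_all_constraints(pool: Sequence[MenuItem],
                          standards: NutritionStandards,
                          limits: RepetitionLimits | None = None,
                          ) -> list[LinearConstraint]:
    if limits is None:
        limits = RepetitionLimits()
    return (build_category_constraints(pool, standards)
            + build_nutrition_constraints(pool, standards)
            + [build_cost_constraint(pool, standards)]
            + build_repetition_constraints(pool, limits))


def check_feasibility(menu: WeeklyMenu,
                      constraints: Iterable[LinearConstraint],
                      tol: float = 1e-6) -> list[Violation]:
    """Empty list iff the menu satisfies every constraint (within tol)."""
    out = []
    for c in constraints:
        if not c.satisfied(menu.servings, tol):
            out.append(Violation(c.label, c.lhs(menu.servings),
                                 c.sense, c.rhs))
    return out
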