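"""Constraint construction and feasibility checking."""

import pytest

from menuopt import NutritionStandards, RepetitionLimits, WeeklyMenu
from menuopt.constraints import (InfeasibleStructureError,
                                 build_all_constraints,
                                 build_category_constraints,
                                 build_cost_constraint,
                                 build_nutrition_constraints,
                                 build_repetition_constraints,
                                 check_feasibility, LE, GE, EQ)
from menuopt.items import MenuDataError

from conftest import make_item


def small_pool():
    return [
        make_item("E1", "entree", protein="beef", cost=1.0,
                  nutrients={"energy_kcal": 400.0, "sodium_mg": 500.0,
                             "saturated_fat_g": 4.0}),
        make_item("E2", "entree", protein="chicken", cost=1.2,
                  nutrients={"energy_kcal": 380.0, "sodium_mg": 450.0,
                             "saturated_fat_g": 2.0}),
        make_item("F1", "fruit", cost=0.2, repeats=2,
                  nutrients={"energy_kcal": 80.0, "sodium_mg": 0.0,
                             "saturated_fat_g": 0.0},
                  hei={"total_fruit": 0.5}),
        make_item("V1", "vegetable", subgroup="red_orange", cost=0.1,
                  repeats=2,
                  nutrients={"energy_kcal": 40.0, "sodium_mg": 100.0,
                             "saturated_fat_g": 0.0},
                  hei={"total_veg": 0.5}),
        make_item("V2", "vegetable", subgroup="dark_green", cost=0.1,
                  repeats=2,
                  nutrients={"energy_kcal": 30.0, "sodium_mg": 80.0,
                             "saturated_fat_g": 0.0},
                  hei={"total_veg": 0.4}),
        make_item("M1", "milk", cost=0.15, repeats=5,
                  nutrients={"energy_kcal": 110.0, "sodium_mg": 120.0,
                             "saturated_fat_g": 1.5},
                  hei={"dairy": 1.0}),
    ]


class TestCategoryConstraints:
    def test_default_week_counts(self):
        rows = {c.label: c for c in build_category_constraints(
            small_pool(), NutritionStandards())}
        assert rows["entree-count"].rhs == 5 and \
            rows["entree-count"].sense == EQ
        assert rows["fruit-count"].rhs == 5
        assert rows["milk-count"].rhs == 5
        assert rows["vegetable-count-min"].rhs == 5
        assert rows["vegetable-count-max"].rhs == 10  # two per day

    def test_three_day_week_scales(self):
        std = NutritionStandards.k5_defaults(week_length=3)
        rows = {c.label: c for c in build_category_constraints(
            small_pool(), std)}
        assert rows["entree-count"].rhs == 3
        assert rows["vegetable-count-min"].rhs == 3
        assert rows["vegetable-count-max"].rhs == 6

    def test_missing_category_is_structural_error(self):
        pool = [it for it in small_pool() if it.category != "milk"]
        with pytest.raises(InfeasibleStructureError, match="milk"):
            build_category_constraints(pool, NutritionStandards())


class TestNutritionConstraints:
    def test_sodium_cap_is_direct_translation(self):
        rows = {c.label: c for c in build_nutrition_constraints(
            small_pool(), NutritionStandards())}
        sodium = rows["sodium-max"]
        assert sodium.sense == LE and sodium.rhs == 6150.0
        assert sodium.coefficients["E1"] == 500.0

    def test_saturated_fat_linearisation(self):
        """10 % energy cap becomes sum((satfat_kcal - 0.1*energy) x) <= 0."""
        rows = {c.label: c for c in build_nutrition_constraints(
            small_pool(), NutritionStandards())}
        sf = rows["saturated-fat-pct-energy"]
        assert sf.sense == LE and sf.rhs == 0.0
        assert sf.coefficients["E1"] == pytest.approx(4.0 * 9.0 - 0.1 * 400.0)

    def test_subgroup_minimum_masks_other_items(self):
        rows = {c.label: c for c in build_nutrition_constraints(
            small_pool(), NutritionStandards())}
        ro = rows["veg-subgroup-red_orange-min"]
        assert set(ro.coefficients) == {"V1"}
        assert ro.sense == GE

    def test_missing_nutrient_names_item(self):
        # MenuItem canonicalises its nutrient map, so exercise the guard
        # with a record that skipped that normalisation
        from types import SimpleNamespace
        bad = SimpleNamespace(item_id="E9", category="entree",
                              vegetable_subgroup="none",
                              nutrients={"energy_kcal": 1.0},
                              hei_components={})
        with pytest.raises(MenuDataError, match="E9"):
            build_nutrition_constraints([bad], NutritionStandards())


class TestCostConstraint:
    def test_default_budget_is_per_lunch_times_week(self):
        con = build_cost_constraint(small_pool(), NutritionStandards())
        assert con.rhs == pytest.approx(6.70)

    def test_three_day_scaling(self):
        con = build_cost_constraint(
            small_pool(), NutritionStandards.k5_defaults(week_length=3))
        assert con.rhs == pytest.approx(4.02)

    def test_override_passthrough(self):
        from dataclasses import replace
        std = replace(NutritionStandards(), budget=10.0)
        assert build_cost_constraint(small_pool(), std).rhs == 10.0


class TestRepetitionConstraints:
    def test_per_item_and_group_limits(self):
        rows = {c.label: c for c in build_repetition_constraints(
            small_pool(), RepetitionLimits())}
        assert rows["repeat-E1"].rhs == 1
        assert rows["repeat-M1"].rhs == 5
        assert rows["protein-beef-limit"].coefficients == {"E1": 1.0}
        assert rows["protein-beef-limit"].rhs == 2


class TestFeasibilityCheck:
    def test_six_entrees_violates_count(self):
        std = NutritionStandards()
        cons = build_category_constraints(small_pool(), std)
        menu = WeeklyMenu(servings={"E1": 3, "E2": 3, "F1": 5, "V1": 5,
                                    "M1": 5})
        labels = [v.label for v in check_feasibility(menu, cons)]
        assert "entree-count" in labels

    def test_cost_violation_carries_lhs(self):
        con = build_cost_constraint(small_pool(), NutritionStandards())
        menu = WeeklyMenu(servings={"E2": 5, "F1": 3, "V1": 2, "M1": 2})
        # 5*1.2 + 3*0.2 + 2*0.1 + 2*0.15 = 7.10 > 6.70
        violations = check_feasibility(menu, [con])
        assert len(violations) == 1
        assert violations[0].lhs == pytest.approx(7.10)
        assert violations[0].rhs == pytest.approx(6.70)

    def test_constraint_count_deterministic(self, default_pool):
        std, lim = NutritionStandards(), RepetitionLimits()
        n1 = len(build_all_constraints(default_pool, std, lim))
        n2 = len(build_all_constraints(default_pool, std, lim))
        assert n1 == n2
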