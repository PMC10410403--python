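"""Menu metrics, baseline averaging, comparisons and extrapolation."""

import pytest

from menuopt import (WeeklyMenu, annual_extrapolation,
                     baseline_weekly_average, compare_to_baseline,
                     composition_by_protein, evaluate_menu)
from menuopt.items import EvaluationMetrics, MenuDataError

from conftest import make_item


def toy_pool():
    return [
        make_item("E1", "entree", protein="chicken", cost=1.00,
                  serving_weight=100.0, consumed_weight=60.0,
                  nutrients={"energy_kcal": 400.0, "fiber_g": 3.0},
                  hei={"whole_grains": 2.0, "total_protein": 2.0},
                  gwp=0.8, water=0.2),
        make_item("E2", "entree", protein="beef", cost=0.80,
                  serving_weight=100.0, consumed_weight=80.0,
                  nutrients={"energy_kcal": 450.0, "fiber_g": 2.0},
                  hei={"whole_grains": 1.5, "total_protein": 2.5},
                  gwp=2.5, water=0.5),
        make_item("F1", "fruit", cost=0.20, serving_weight=100.0,
                  consumed_weight=50.0,
                  nutrients={"energy_kcal": 80.0, "fiber_g": 1.0},
                  hei={"total_fruit": 0.5, "whole_fruit": 0.5},
                  gwp=0.1, water=0.05),
    ]


class TestEvaluateMenu:
    def test_single_item_cost_and_value(self):
        """5 servings at 1.00 USD with 60 % consumption: 5.00 offered,
        3.00 consumed."""
        pool = toy_pool()
        menu = WeeklyMenu(servings={"E1": 5})
        m = evaluate_menu(menu, pool)
        assert m.cost_offered == pytest.approx(5.00)
        assert m.value_consumed == pytest.approx(3.00)
        assert m.energy_offered == pytest.approx(2000.0)
        assert m.energy_consumed == pytest.approx(1200.0)

    def test_hand_summed_fixture(self):
        """Spreadsheet-style hand computation over three items."""
        pool = toy_pool()
        menu = WeeklyMenu(servings={"E1": 2, "E2": 1, "F1": 3})
        m = evaluate_menu(menu, pool)
        assert m.cost_offered == pytest.approx(2 * 1.0 + 0.8 + 3 * 0.2)
        assert m.value_consumed == pytest.approx(
            2 * 1.0 * 0.6 + 0.8 * 0.8 + 3 * 0.2 * 0.5)
        assert m.energy_offered == pytest.approx(2 * 400 + 450 + 3 * 80)
        assert m.energy_consumed == pytest.approx(
            2 * 400 * 0.6 + 450 * 0.8 + 3 * 80 * 0.5)
        assert m.gwp == pytest.approx(2 * 0.8 + 2.5 + 3 * 0.1)
        assert m.water_scarcity == pytest.approx(2 * 0.2 + 0.5 + 3 * 0.05)
        assert m.nutrients_offered["fiber_g"] == pytest.approx(
            2 * 3 + 2 + 3 * 1)
        assert m.protein_composition == {"beef": pytest.approx(1 / 3),
                                         "chicken": pytest.approx(2 / 3)}

    def test_full_consumption_identity(self):
        it = make_item("E1", "entree", cost=1.0, serving_weight=50.0,
                       consumed_weight=50.0,
                       nutrients={"energy_kcal": 300.0},
                       hei={"whole_grains": 1.0})
        m = evaluate_menu(WeeklyMenu(servings={"E1": 2}), [it])
        assert m.value_consumed == m.cost_offered
        assert m.energy_consumed == m.energy_offered

    def test_consumed_never_exceeds_offered(self, default_pool,
                                            baseline_menus):
        for menu in baseline_menus[:6]:
            m = evaluate_menu(menu, default_pool)
            assert m.value_consumed <= m.cost_offered + 1e-9
            assert m.energy_consumed <= m.energy_offered + 1e-9

    def test_empty_menu_rejected(self, default_pool):
        with pytest.raises(MenuDataError):
            evaluate_menu(WeeklyMenu(servings={}), default_pool)


class TestComposition:
    def test_two_of_five_chicken(self):
        pool = toy_pool()
        menu = WeeklyMenu(servings={"E1": 2, "E2": 3})
        comp = composition_by_protein(menu, pool)
        assert comp["chicken"] == pytest.approx(0.40)
        assert sum(comp.values()) == pytest.approx(1.0, abs=1e-9)

    def test_single_type_is_one(self):
        menu = WeeklyMenu(servings={"E2": 5})
        assert composition_by_protein(menu, toy_pool()) == {"beef": 1.0}

    def test_pooled_weeks_denominator(self, default_pool, all_model_runs):
        """Seven optimised menus of 5 entrées pool to 35 entrée servings."""
        pooled: dict[str, int] = {}
        n_menus = 0
        for run in all_model_runs.values():
            if run.result.status != "optimal":
                continue
            n_menus += 1
            for item_id, c in run.result.menu.servings.items():
                pooled[item_id] = pooled.get(item_id, 0) + c
        entree_ids = {it.item_id for it in default_pool
                      if it.category == "entree"}
        total = sum(c for i, c in pooled.items() if i in entree_ids)
        assert total == 5 * n_menus

    def test_no_entrees_is_an_error(self):
        with pytest.raises(MenuDataError):
            composition_by_protein(WeeklyMenu(servings={"F1": 5}), toy_pool())


class TestComparison:
    def test_identical_metrics_change_zero(self, baseline_metrics):
        changes = compare_to_baseline(baseline_metrics, baseline_metrics)
        assert all(v == pytest.approx(0.0) for v in changes.values())

    @pytest.mark.parametrize("base,opt,expected", [
        (100.0, 127.0, 27.0),
        (10.0, 2.9, -71.0),
    ])
    def test_signed_percent_definition(self, base, opt, expected):
        b = EvaluationMetrics(cost_offered=base, gwp=base)
        o = EvaluationMetrics(cost_offered=opt, gwp=opt)
        changes = compare_to_baseline(o, b)
        assert changes["cost_offered"] == pytest.approx(expected)
        assert changes["gwp"] == pytest.approx(expected)

    def test_zero_baseline_rejected(self):
        with pytest.raises(MenuDataError):
            compare_to_baseline(EvaluationMetrics(cost_offered=1.0),
                                EvaluationMetrics(cost_offered=0.0))


class TestBaselineAverage:
    def test_one_week_equals_evaluate(self, default_pool, baseline_menus):
        week = baseline_menus[0]
        avg = baseline_weekly_average([week], default_pool)
        single = evaluate_menu(week, default_pool)
        assert avg.cost_offered == pytest.approx(single.cost_offered)
        assert avg.energy_consumed == pytest.approx(single.energy_consumed)
        assert avg.hei_offered == pytest.approx(single.hei_offered)

    def test_duplicate_weeks_idempotent(self, default_pool, baseline_menus):
        week = baseline_menus[0]
        a1 = baseline_weekly_average([week], default_pool)
        a2 = baseline_weekly_average([week, week], default_pool)
        assert a1.cost_offered == pytest.approx(a2.cost_offered)
        assert a1.hei_offered == pytest.approx(a2.hei_offered)

    def test_mean_matches_hand_average(self, default_pool, baseline_menus):
        weeks = baseline_menus[:4]
        avg = baseline_weekly_average(weeks, default_pool)
        per = [evaluate_menu(w, default_pool) for w in weeks]
        assert avg.cost_offered == pytest.approx(
            sum(p.cost_offered for p in per) / 4)
        assert avg.gwp == pytest.approx(sum(p.gwp for p in per) / 4)

    def test_empty_list_rejected(self, default_pool):
        with pytest.raises(MenuDataError):
            baseline_weekly_average([], default_pool)


class TestAnnualExtrapolation:
    def test_school_year_saving(self):
        """2.60 USD/week over a 36-week year is 93.60 USD per student."""
        out = annual_extrapolation(2.60, weeks_per_year=36)
        assert out["per_student"] == pytest.approx(93.6)

    def test_zero_saving(self):
        assert annual_extrapolation(0.0)["per_student"] == 0.0

    def test_district_scaling(self):
        out = annual_extrapolation(1.00, weeks_per_year=40, enrollment=50_000)
        assert out["per_student"] == pytest.approx(40.0)
        assert out["district"] == pytest.approx(2_000_000.0)

    def test_nonpositive_year_rejected(self):
        with pytest.raises(MenuDataError):
            annual_extrapolation(1.0, weeks_per_year=0)
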