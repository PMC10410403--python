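"""HEI-2015 scoring: cut-point behaviour, hand-computed totals,
monotonicity, and the consumed-basis variant."""

import pytest
from hypothesis import given, settings, strategies as st

from menuopt import HEIStandards, WeeklyMenu, score_component, score_menu
from menuopt.hei import (ComponentStandard, HEIError, component_density,
                         ADEQUACY, MODERATION)

from conftest import make_item


def perfect_item():
    """One serving meeting every max-score standard at 1000 kcal."""
    return make_item("P1", "entree", nutrients={
        "energy_kcal": 1000.0, "sodium_mg": 1000.0, "saturated_fat_g": 5.0,
        "added_sugar_tsp": 0.0, "sfa_g": 5.0, "mufa_g": 5.0, "pufa_g": 7.5,
    }, hei={
        "total_fruit": 0.8, "whole_fruit": 0.4, "total_veg": 1.1,
        "greens_beans": 0.2, "whole_grains": 1.5, "dairy": 1.3,
        "total_protein": 2.5, "seafood_plant_protein": 0.8,
        "refined_grains": 0.0,
    })


def worst_item():
    """Zero adequacy amounts; every moderation density at/above its zero
    -score standard (1000 kcal: 4.3 oz refined grain, 2 g sodium, 26 % of
    energy added sugar, 16 % saturated fat, no unsaturated fat)."""
    return make_item("W1", "entree", nutrients={
        "energy_kcal": 1000.0, "sodium_mg": 2000.0,
        "saturated_fat_g": 160.0 / 9.0, "added_sugar_tsp": 260.0 / 16.0,
        "sfa_g": 160.0 / 9.0, "mufa_g": 0.0, "pufa_g": 0.0,
    }, hei={"refined_grains": 4.3})


class TestComponentScoring:
    def test_adequacy_cap_and_floor(self, hei2015):
        std = hei2015.components["total_fruit"]
        assert score_component(std.max_standard, std) == std.max_score
        assert score_component(2 * std.max_standard, std) == std.max_score
        assert score_component(0.0, std) == 0.0

    def test_moderation_cap_and_floor(self, hei2015):
        std = hei2015.components["sodium"]
        assert score_component(std.min_standard, std) == std.max_score
        assert score_component(std.max_standard, std) == 0.0
        assert score_component(10 * std.max_standard, std) == 0.0

    @pytest.mark.parametrize("name", list(HEIStandards.hei2015().components))
    def test_midpoint_density_scores_half(self, hei2015, name):
        """Intakes between the standards score proportionately: the exact
        midpoint earns exactly half the component maximum."""
        std = hei2015.components[name]
        mid = 0.5 * (std.min_standard + std.max_standard)
        assert score_component(mid, std) == pytest.approx(
            std.max_score / 2.0)

    @given(st.floats(min_value=0.0, max_value=10.0),
           st.floats(min_value=0.0, max_value=10.0))
    @settings(derandomize=True, max_examples=60)
    def test_score_bounded_and_monotone(self, d1, d2):
        std = ComponentStandard("x", 10, 0.0, 2.0, ADEQUACY)
        s1, s2 = score_component(d1, std), score_component(d2, std)
        assert 0.0 <= s1 <= 10.0
        if d1 <= d2:
            assert s1 <= s2
        mod = ComponentStandard("y", 10, 1.0, 2.0, MODERATION)
        if d1 <= d2:
            assert score_component(d1, mod) >= score_component(d2, mod)


class TestDensity:
    def test_per_1000_kcal(self, hei2015):
        std = hei2015.components["total_fruit"]
        assert component_density(2.0, 2000.0, std) == pytest.approx(1.0)
        assert component_density(0.0, 2000.0, std) == 0.0

    def test_fat_ratio(self, hei2015):
        std = hei2015.components["fatty_acids"]
        assert component_density(0.0, 1000.0, std, sfa=10.0,
                                 unsat=25.0) == pytest.approx(2.5)
        # limit behaviour at sfa = 0
        assert component_density(0.0, 1000.0, std, sfa=0.0,
                                 unsat=1.0) == std.max_standard
        assert component_density(0.0, 1000.0, std, sfa=0.0, unsat=0.0) == 0.0

    def test_zero_energy_undefined(self, hei2015):
        with pytest.raises(HEIError):
            component_density(1.0, 0.0, hei2015.components["total_fruit"])


class TestMenuScoring:
    def test_perfect_menu_scores_100(self):
        pool = [perfect_item()]
        menu = WeeklyMenu(servings={"P1": 1})
        assert score_menu(menu, pool).total == pytest.approx(100.0)

    def test_all_worst_menu_scores_0(self):
        pool = [worst_item()]
        menu = WeeklyMenu(servings={"W1": 1})
        assert score_menu(menu, pool).total == pytest.approx(0.0)

    def test_three_item_toy_menu_matches_hand_sum(self):
        """Component-by-component hand computation of a 2000 kcal menu."""
        pool = [
            make_item("A", "entree", nutrients={
                "energy_kcal": 1000.0, "sodium_mg": 1500.0,
                "saturated_fat_g": 10.0, "sfa_g": 10.0, "mufa_g": 10.0,
                "pufa_g": 10.0,
            }, hei={"whole_grains": 2.0, "total_protein": 3.0}),
            make_item("B", "fruit", nutrients={"energy_kcal": 500.0},
                      hei={"total_fruit": 1.2, "whole_fruit": 0.6}),
            make_item("C", "milk", nutrients={
                "energy_kcal": 500.0, "added_sugar_tsp": 12.5,
            }, hei={"dairy": 2.0}),
        ]
        menu = WeeklyMenu(servings={"A": 1, "B": 1, "C": 1})
        score = score_menu(menu, pool)
        # densities per 1000 kcal of the 2000 kcal menu, scored linearly:
        expected = {
            "total_fruit": 5 * 0.6 / 0.8,          # 3.75
            "whole_fruit": 5 * 0.3 / 0.4,          # 3.75
            "total_veg": 0.0,
            "greens_beans": 0.0,
            "whole_grains": 10 * 1.0 / 1.5,        # 6.6667
            "dairy": 10 * 1.0 / 1.3,               # 7.6923
            "total_protein": 5 * 1.5 / 2.5,        # 3.0
            "seafood_plant_protein": 0.0,
            "fatty_acids": 10 * (2.0 - 1.2) / 1.3,  # ratio 20/10
            "refined_grains": 10.0,
            "sodium": 10.0,                        # 0.75 g/1000 below 1.1
            "added_sugars": 10 * (26 - 10.0) / 19.5,  # 200/2000 kcal = 10 %
            "saturated_fats": 10.0,                # 90/2000 kcal = 4.5 %
        }
        for name, pts in expected.items():
            assert score.component_scores[name] == pytest.approx(pts), name
        assert score.total == pytest.approx(sum(expected.values()))
        assert score.total == pytest.approx(69.2179487, abs=1e-6)

    def test_consumed_equals_offered_when_fully_eaten(self, default_pool):
        eaten = [make_item(f"I{k}", c, serving_weight=100.0,
                           consumed_weight=100.0,
                           nutrients={"energy_kcal": 300.0, "sodium_mg": 300.0},
                           hei={"total_fruit": 0.5} if c == "fruit" else
                               {"whole_grains": 1.0})
                 for k, c in enumerate(["entree", "fruit", "milk"])]
        menu = WeeklyMenu(servings={it.item_id: 1 for it in eaten})
        assert (score_menu(menu, eaten, basis="consumed").total
                == pytest.approx(score_menu(menu, eaten,
                                            basis="offered").total))

    def test_consumed_basis_uses_offered_energy(self):
        """Half-eaten servings halve the component densities because the
        denominator stays at the energy offered."""
        it = make_item("H", "fruit", serving_weight=100.0,
                       consumed_weight=50.0,
                       nutrients={"energy_kcal": 1000.0},
                       hei={"total_fruit": 0.8, "whole_fruit": 0.8})
        menu = WeeklyMenu(servings={"H": 1})
        offered = score_menu(menu, [it], basis="offered")
        consumed = score_menu(menu, [it], basis="consumed")
        assert offered.component_scores["total_fruit"] == 5.0
        # density drops from 0.8 to 0.4 cup eq / 1000 kcal -> half score
        assert consumed.component_scores["total_fruit"] == pytest.approx(2.5)

    def test_adequacy_monotone_in_amount(self):
        def total(fruit_cups):
            it = make_item("F", "fruit",
                           nutrients={"energy_kcal": 1000.0},
                           hei={"total_fruit": fruit_cups})
            return score_menu(WeeklyMenu(servings={"F": 1}), [it]).total
        scores = [total(c) for c in (0.0, 0.2, 0.5, 0.8, 1.5)]
        assert scores == sorted(scores)

    def test_empty_menu_rejected(self, default_pool):
        with pytest.raises(HEIError):
            score_menu(WeeklyMenu(servings={}), default_pool)

    def test_standards_must_sum_to_100(self, hei2015):
        bad = dict(hei2015.components)
        bad["total_fruit"] = ComponentStandard("total_fruit", 6, 0.0, 0.8,
                                               ADEQUACY)
        with pytest.raises(HEIError, match="100"):
            HEIStandards(components=bad)

    def test_default_pool_scores_in_range(self, default_pool, baseline_menus):
        for menu in baseline_menus[:5]:
            s = score_menu(menu, default_pool)
            assert 0.0 <= s.total <= 100.0
            assert s.total == pytest.approx(sum(s.component_scores.values()))
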