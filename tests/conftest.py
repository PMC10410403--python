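"""Shared fixtures: the default synthetic pool, a baseline menu cycle, and
test-scale (3-day week) standards small enough for exhaustive enumeration."""

from dataclasses import replace

import pytest

from menuopt import (HEIStandards, MenuItem, NutritionStandards,
                     PoolRecipe, RepetitionLimits, baseline_weekly_average,
                     generate_baseline_menus, generate_pool, run_all_models,
                     tiny_recipe)

TEST_SEED = 42


@pytest.fixture(scope="session")
def default_pool():
    return generate_pool(PoolRecipe(seed=TEST_SEED))


@pytest.fixture(scope="session")
def baseline_menus(default_pool):
    return generate_baseline_menus(default_pool, 36, seed=TEST_SEED)


@pytest.fixture(scope="session")
def baseline_metrics(default_pool, baseline_menus):
    return baseline_weekly_average(baseline_menus, default_pool)


@pytest.fixture(scope="session")
def all_model_runs(default_pool):
    return run_all_models(default_pool)


def tiny_standards() -> NutritionStandards:
    """3-day-week standards for enumeration-scale pools: bands widened so
    that a random 13-item pool is usually feasible, vegetable-subgroup
    minima dropped (a 4-item vegetable side cannot cover five subgroups)."""
    return replace(
        NutritionStandards.k5_defaults(3),
        veg_subgroup_min_cup={},
        grains_max_oz=7.5,
        meat_alt_max_oz=7.5,
        energy_min_kcal=1500.0,
        energy_max_kcal=2150.0,
        fruit_min_cup=1.1,
        total_veg_min_cup=1.5,
    )


def tiny_limits() -> RepetitionLimits:
    return RepetitionLimits(per_item_default={
        "entree": 1, "fruit": 2, "vegetable": 2, "milk": 3})


@pytest.fixture
def tiny_setup():
    """Factory: seed -> (pool, standards, limits) at enumeration scale."""
    def make(seed: int):
        return generate_pool(tiny_recipe(seed)), tiny_standards(), tiny_limits()
    return make


def make_item(item_id="X1", category="entree", *, cost=1.0,
              serving_weight=100.0, consumed_weight=100.0,
              nutrients=None, hei=None, gwp=0.0, water=0.0,
              protein="chicken", subgroup="other", flavor="",
              repeats=1) -> MenuItem:
    """Toy item with explicit numbers for hand-computed expectations."""
    base = {"energy_kcal": 0.0, "sodium_mg": 0.0, "saturated_fat_g": 0.0,
            "added_sugar_tsp": 0.0, "fiber_g": 0.0, "calcium_mg": 0.0,
            "iron_mg": 0.0, "mufa_g": 0.0, "pufa_g": 0.0, "sfa_g": 0.0}
    base.update(nutrients or {})
    return MenuItem(
        item_id=item_id, name=item_id, category=category,
        protein_subcategory=protein if category == "entree" else "none",
        flavor_subcategory=flavor,
        vegetable_subgroup=subgroup if category == "vegetable" else "none",
        cost=cost, serving_weight=serving_weight,
        consumed_weight=consumed_weight, nutrients=base,
        hei_components=hei or {}, gwp=gwp, water_scarcity=water,
        max_weekly_repeats=repeats)


@pytest.fixture
def toy_item():
    return make_item


@pytest.fixture(scope="session")
def hei2015():
    return HEIStandards.hei2015()
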