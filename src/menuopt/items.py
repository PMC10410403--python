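"""Domain types and I/O for menu-item pools, weekly menus and standards.

The unit of analysis is one school week (default 5 lunches).  A weekly menu
is a multiset of menu items — integer serving counts over an item pool —
with no per-day assignment, matching the weekly basis of the US National
School Lunch Programme (NSLP) meal pattern.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

CATEGORIES = ("entree", "fruit", "vegetable", "milk")

PROTEIN_SUBCATEGORIES = (
    "beef", "cheese", "chicken", "fish", "legume", "turkey",
    "vegetarian_other", "none",
)

VEGETABLE_SUBGROUPS = (
    "dark_green", "red_orange", "beans_peas", "starchy", "other", "none",
)

#: per-serving nutrient fields, with units
NUTRIENT_KEYS = (
    "energy_kcal",
    "sodium_mg",
    "saturated_fat_g",
    "added_sugar_tsp",   # teaspoon-equivalents; 16 kcal per tsp at scoring time
    "fiber_g",
    "calcium_mg",
    "iron_mg",
    "mufa_g",
    "pufa_g",
    "sfa_g",
)

#: per-serving HEI-2015 component amounts (cup eq / oz eq)
HEI_COMPONENT_KEYS = (
    "total_fruit",            # cup eq
    "whole_fruit",            # cup eq
    "total_veg",              # cup eq
    "greens_beans",           # cup eq
    "whole_grains",           # oz eq
    "dairy",                  # cup eq
    "total_protein",          # oz eq
    "seafood_plant_protein",  # oz eq
    "refined_grains",         # oz eq
)


class MenuDataError(ValueError):
    """Base class for menu-data validation failures."""


class SchemaError(MenuDataError):
    """A required column is missing from a pool table."""


class ValidationError(MenuDataError):
    """A row violates a MenuItem invariant; message names the item."""


@dataclass(frozen=True)
class MenuItem:
    """One food offering with cost, nutrients, HEI amounts and footprints.

    ``consumed_weight`` is the mean edible grams students actually ate per
    serving (plate-waste measurement); dividing by ``serving_weight`` gives
    the item's consumption fraction.
    """

    item_id: str
    name: str
    category: str
    protein_subcategory: str = "none"
    flavor_subcategory: str = ""
    vegetable_subgroup: str = "none"
    cost: float = 0.0              # USD per serving
    serving_weight: float = 0.0    # g edible portion served
    consumed_weight: float = 0.0   # g mean edible portion consumed
    nutrients: Mapping[str, float] = field(default_factory=dict)
    hei_components: Mapping[str, float] = field(default_factory=dict)
    gwp: float = 0.0               # kg CO2 eq per serving
    water_scarcity: float = 0.0    # m3 water eq per serving
    max_weekly_repeats: int = 1

    def __post_init__(self) -> None:
        # canonicalise the maps so equality is insensitive to omitted zeros
        nutrients = {k: 0.0 for k in NUTRIENT_KEYS}
        nutrients.update(self.nutrients)
        object.__setattr__(self, "nutrients", nutrients)
        hei = {k: 0.0 for k in HEI_COMPONENT_KEYS}
        hei.update(self.hei_components)
        object.__setattr__(self, "hei_components", hei)
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"{self.item_id}: unknown category {self.category!r}")
        if self.protein_subcategory not in PROTEIN_SUBCATEGORIES:
            raise ValidationError(
                f"{self.item_id}: unknown protein subcategory "
                f"{self.protein_subcategory!r}")
        if self.vegetable_subgroup not in VEGETABLE_SUBGROUPS:
            raise ValidationError(
                f"{self.item_id}: unknown vegetable subgroup "
                f"{self.vegetable_subgroup!r}")
        if (self.protein_subcategory == "none") != (self.category != "entree"):
            raise ValidationError(
                f"{self.item_id}: protein subcategory must be set iff the "
                f"item is an entree")
        if (self.vegetable_subgroup == "none") != (self.category != "vegetable"):
            raise ValidationError(
                f"{self.item_id}: vegetable subgroup must be set iff the "
                f"item is a vegetable")
        if not 0.0 <= self.consumed_weight <= self.serving_weight:
            raise ValidationError(
                f"{self.item_id}: consumed weight {self.consumed_weight} g "
                f"outside [0, serving weight {self.serving_weight} g]")
        if self.cost < 0:
            raise ValidationError(f"{self.item_id}: negative cost")
        if self.gwp < 0 or self.water_scarcity < 0:
            raise ValidationError(
                f"{self.item_id}: negative environmental coefficient")
        for key, value in {**self.nutrients, **self.hei_components}.items():
            if value < 0:
                raise ValidationError(
                    f"{self.item_id}: negative amount for {key}")
        if self.max_weekly_repeats < 0:
            raise ValidationError(
                f"{self.item_id}: negative repetition limit")


def consumption_fraction(item: MenuItem) -> float:
    """Edible grams consumed divided by edible grams served, in [0, 1]."""
    if item.serving_weight <= 0:
        raise MenuDataError(
            f"{item.item_id}: consumption fraction undefined for "
            f"serving weight {item.serving_weight}")
    return item.consumed_weight / item.serving_weight


@dataclass
class WeeklyMenu:
    """Integer serving counts over an item pool for one week of lunches."""

    servings: dict[str, int]
    week_length: int = 5

    def __post_init__(self) -> None:
        for item_id, count in self.servings.items():
            if count != int(count) or count < 0:
                raise MenuDataError(
                    f"serving count for {item_id} must be a non-negative "
                    f"integer, got {count}")
            self.servings[item_id] = int(count)

    def total_servings(self) -> int:
        return sum(self.servings.values())

    def nonzero(self) -> dict[str, int]:
        return {k: v for k, v in sorted(self.servings.items()) if v > 0}


@dataclass
class NutritionStandards:
    """Weekly NSLP-style bounds, budget and category counts.

    Defaults follow the K-5 lunch meal pattern with every daily quantity
    enforced at the weekly level (x week_length), since the menu is a weekly
    multiset without day assignment.  All values are overridable from config.
    """

    week_length: int = 5
    energy_min_kcal: float = 2750.0          # 550 kcal/lunch x 5
    energy_max_kcal: float = 3250.0          # 650 kcal/lunch x 5
    sodium_max_mg: float = 6150.0            # 1230 mg/lunch x 5 (Target 1)
    saturated_fat_max_frac_energy: float = 0.10
    fruit_min_cup: float = 2.5
    total_veg_min_cup: float = 3.75
    veg_subgroup_min_cup: dict[str, float] = field(default_factory=lambda: {
        "dark_green": 0.5,
        "red_orange": 0.75,
        "beans_peas": 0.5,
        "starchy": 0.5,
        "other": 0.5,
    })
    grains_min_oz: float = 8.0
    grains_max_oz: float = 10.0
    meat_alt_min_oz: float = 8.0
    meat_alt_max_oz: float = 10.0
    milk_min_cup: float = 5.0
    budget: float = 6.70                     # USD per weekly menu (1.34 x 5)
    entree_count: int = 5
    fruit_count: int = 5
    milk_count: int = 5
    vegetable_count_min: int = 5
    vegetable_count_max: int = 10            # up to two vegetables per day

    def __post_init__(self) -> None:
        if self.budget <= 0:
            raise MenuDataError("budget must be positive")
        pairs = [
            (self.energy_min_kcal, self.energy_max_kcal, "energy"),
            (self.grains_min_oz, self.grains_max_oz, "grains"),
            (self.meat_alt_min_oz, self.meat_alt_max_oz, "meat/meat-alt"),
            (self.vegetable_count_min, self.vegetable_count_max,
             "vegetable count"),
        ]
        for lo, hi, label in pairs:
            if lo > hi:
                raise MenuDataError(f"{label}: min {lo} exceeds max {hi}")

    @classmethod
    def k5_defaults(cls, week_length: int = 5,
                    budget_per_lunch: float = 1.34) -> "NutritionStandards":
        """K-5 standards scaled to an arbitrary week length (used at test
        scale, e.g. 3-day weeks)."""
        f = week_length / 5.0
        return cls(
            week_length=week_length,
            energy_min_kcal=550.0 * week_length,
            energy_max_kcal=650.0 * week_length,
            sodium_max_mg=1230.0 * week_length,
            fruit_min_cup=2.5 * f,
            total_veg_min_cup=3.75 * f,
            veg_subgroup_min_cup={k: v * f for k, v in
                                  cls().veg_subgroup_min_cup.items()},
            grains_min_oz=8.0 * f,
            grains_max_oz=10.0 * f,
            meat_alt_min_oz=8.0 * f,
            meat_alt_max_oz=10.0 * f,
            milk_min_cup=1.0 * week_length,
            budget=budget_per_lunch * week_length,
            entree_count=week_length,
            fruit_count=week_length,
            milk_count=week_length,
            vegetable_count_min=week_length,
            vegetable_count_max=2 * week_length,
        )


@dataclass
class RepetitionLimits:
    """Weekly repetition caps providing menu variety.

    ``per_item_default`` caps each item by category; subcategory limits cap
    the summed servings over entrées sharing a protein type or flavour
    profile.
    """

    per_item_default: dict[str, int] = field(default_factory=lambda: {
        "entree": 1, "fruit": 2, "vegetable": 2, "milk": 5,
    })
    protein_subcategory_limit: int = 2
    flavor_subcategory_limit: int = 2

    def item_limit(self, item: MenuItem) -> int:
        if item.max_weekly_repeats > 0:
            return item.max_weekly_repeats
        return self.per_item_default.get(item.category, 1)


@dataclass
class EvaluationMetrics:
    """All reported per-menu quantities, offered and consumed."""

    cost_offered: float = 0.0
    value_consumed: float = 0.0
    energy_offered: float = 0.0
    energy_consumed: float = 0.0
    hei_offered: float | None = None
    hei_consumed: float | None = None
    gwp: float = 0.0
    water_scarcity: float = 0.0
    protein_composition: dict[str, float] = field(default_factory=dict)
    nutrients_offered: dict[str, float] = field(default_factory=dict)
    nutrients_consumed: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Pool table I/O
# ---------------------------------------------------------------------------

_BASE_COLUMNS = [
    "item_id", "name", "category", "protein_subcategory",
    "flavor_subcategory", "vegetable_subgroup", "cost", "serving_weight",
    "consumed_weight", "gwp", "water_scarcity", "max_weekly_repeats",
]
_NUTRIENT_COLUMNS = [f"nutrient_{k}" for k in NUTRIENT_KEYS]
_HEI_COLUMNS = [f"hei_{k}" for k in HEI_COMPONENT_KEYS]

#: fixed column order for bit-exact pool round-trips
POOL_COLUMNS = _BASE_COLUMNS + _NUTRIENT_COLUMNS + _HEI_COLUMNS


def pool_to_frame(pool: Iterable[MenuItem]) -> pd.DataFrame:
    rows = []
    for it in pool:
        row: dict[str, object] = {
            "item_id": it.item_id,
            "name": it.name,
            "category": it.category,
            "protein_subcategory": it.protein_subcategory,
            "flavor_subcategory": it.flavor_subcategory,
            "vegetable_subgroup": it.vegetable_subgroup,
            "cost": it.cost,
            "serving_weight": it.serving_weight,
            "consumed_weight": it.consumed_weight,
            "gwp": it.gwp,
            "water_scarcity": it.water_scarcity,
            "max_weekly_repeats": it.max_weekly_repeats,
        }
        for k in NUTRIENT_KEYS:
            row[f"nutrient_{k}"] = it.nutrients.get(k, 0.0)
        for k in HEI_COMPONENT_KEYS:
            row[f"hei_{k}"] = it.hei_components.get(k, 0.0)
        rows.append(row)
    return pd.DataFrame(rows, columns=POOL_COLUMNS)


def frame_to_pool(frame: pd.DataFrame) -> list[MenuItem]:
    missing = [c for c in POOL_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"pool table is missing columns: {missing}")
    items = []
    for _, row in frame.iterrows():
        items.append(MenuItem(
            item_id=str(row["item_id"]),
            name=str(row["name"]),
            category=str(row["category"]),
            protein_subcategory=str(row["protein_subcategory"]),
            flavor_subcategory=str(row["flavor_subcategory"]),
            vegetable_subgroup=str(row["vegetable_subgroup"]),
            cost=float(row["cost"]),
            serving_weight=float(row["serving_weight"]),
            consumed_weight=float(row["consumed_weight"]),
            nutrients={k: float(row[f"nutrient_{k}"]) for k in NUTRIENT_KEYS},
            hei_components={k: float(row[f"hei_{k}"])
                            for k in HEI_COMPONENT_KEYS},
            gwp=float(row["gwp"]),
            water_scarcity=float(row["water_scarcity"]),
            max_weekly_repeats=int(row["max_weekly_repeats"]),
        ))
    return items


def read_menu_pool(path: str | Path) -> list[MenuItem]:
    """Read a tab-separated menu-item pool table into validated MenuItems."""
    frame = pd.read_csv(path, sep="\t", dtype={
        "item_id": str, "name": str, "flavor_subcategory": str})
    frame["flavor_subcategory"] = frame["flavor_subcategory"].fillna("")
    return frame_to_pool(frame)


def write_menu_pool(pool: Iterable[MenuItem], path: str | Path) -> None:
    pool_to_frame(pool).to_csv(path, sep="\t", index=False)


def pool_index(pool: Iterable[MenuItem]) -> dict[str, MenuItem]:
    index: dict[str, MenuItem] = {}
    for it in pool:
        if it.item_id in index:
            raise MenuDataError(f"duplicate item_id {it.item_id}")
        index[it.item_id] = it
    return index


# ---------------------------------------------------------------------------
# Menu result I/O (round-trippable JSON)
# ---------------------------------------------------------------------------

def write_menu(menu: WeeklyMenu, metrics: EvaluationMetrics | None,
               path: str | Path, pool: Iterable[MenuItem] | None = None
               ) -> None:
    """Write a solved menu (servings + metrics) to a JSON result file.

    Re-reading reproduces the menu bit-exactly.  If ``pool`` is given, every
    referenced item id must exist in it.
    """
    if pool is not None:
        known = {it.item_id for it in pool}
        unknown = sorted(set(menu.servings) - known)
        if unknown:
            raise MenuDataError(f"menu references unknown items: {unknown}")
    payload = {
        "week_length": menu.week_length,
        "servings": dict(sorted(menu.servings.items())),
        "metrics": metrics.to_dict() if metrics is not None else None,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_menu(path: str | Path) -> tuple[WeeklyMenu, EvaluationMetrics | None]:
    payload = json.loads(Path(path).read_text())
    menu = WeeklyMenu(servings={k: int(v) for k, v in
                                payload["servings"].items()},
                      week_length=int(payload["week_length"]))
    metrics = None
    if payload.get("metrics") is not None:
        metrics = EvaluationMetrics(**payload["metrics"])
    return menu, metrics
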