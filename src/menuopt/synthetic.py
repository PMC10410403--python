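"""Seeded synthetic menu-item pools and baseline menu cycles.

The generator emulates a large urban K-5 district's lunch offerings: a
142-item pool (77 entrées, 18 fruit sides, 43 vegetable sides, 4 milk
options) whose qualitative structure drives the optimisation trade-offs:

* beef and cheese entrées: cheap, highly consumed, high global-warming
  potential (ruminant/dairy production);
* legume entrées: the least cost, lowest consumption, smallest footprint;
* fish entrées: high cost, modest consumption, high nutritional quality
  (seafood/plant protein, favourable fatty-acid profile);
* vegetable sides: low consumption fractions.

Attribute values are drawn from truncated normals whose truncation windows
are disjoint wherever an ordering matters (e.g. every beef consumption
fraction exceeds every non-pizza vegetarian one), so realised orderings
hold by construction, not merely in expectation.  Everything is driven by
a single integer seed through one ``numpy.random.Generator``; identical
seeds give bit-identical pools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .items import (MenuItem, RepetitionLimits, WeeklyMenu, pool_index)

PROTEIN_ORDER = ("beef", "cheese", "chicken", "fish", "legume", "turkey",
                 "vegetarian_other")

#: entrée protein mixture of baseline offerings.  The published composition
#: (beef 29 %, chicken 28 %, vegetarian 34 %, turkey 3 %, fish 5 %) folds
#: cheese and legume entrées into "vegetarian"; they are split out here so
#: that beef+cheese vs fish+legume shifts are observable.
DEFAULT_PROTEIN_WEIGHTS = {
    "beef": 0.29, "chicken": 0.28, "cheese": 0.12, "vegetarian_other": 0.18,
    "legume": 0.05, "fish": 0.05, "turkey": 0.03,
}

#: truncation windows (lo, hi) per protein type; windows are ordered so the
#: documented cost / consumption / footprint rankings hold by construction
ENTREE_COST_WINDOW = {
    "legume": (0.45, 0.60), "beef": (0.60, 0.80), "cheese": (0.68, 0.88),
    "chicken": (0.90, 1.10), "vegetarian_other": (0.92, 1.18),
    "turkey": (1.00, 1.20), "fish": (1.25, 1.55),
}
ENTREE_CONSUMPTION_WINDOW = {
    "beef": (0.68, 0.88), "cheese": (0.62, 0.82), "chicken": (0.54, 0.74),
    "turkey": (0.48, 0.68), "fish": (0.40, 0.58),
    "vegetarian_other": (0.38, 0.56), "legume": (0.30, 0.48),
}
ENTREE_GWP_WINDOW = {
    "beef": (2.2, 3.2), "cheese": (1.2, 1.9), "chicken": (0.55, 0.90),
    "turkey": (0.55, 0.90), "fish": (0.45, 0.75),
    "vegetarian_other": (0.35, 0.65), "legume": (0.12, 0.30),
}
ENTREE_WATER_WINDOW = {
    "beef": (0.38, 0.55), "cheese": (0.25, 0.40), "chicken": (0.18, 0.30),
    "turkey": (0.18, 0.30), "fish": (0.12, 0.22),
    "vegetarian_other": (0.20, 0.38), "legume": (0.06, 0.15),
}

VEG_SUBGROUP_COUNTS = {
    "dark_green": 8, "red_orange": 9, "beans_peas": 6,
    "starchy": 10, "other": 10,
}

N_FLAVORS = 10


@dataclass
class PoolRecipe:
    """Parameters of the synthetic pool generator."""

    n_entrees: int = 77
    n_fruits: int = 18
    n_vegetables: int = 43
    n_milks: int = 4
    protein_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROTEIN_WEIGHTS))
    veg_subgroup_counts: dict[str, int] = field(
        default_factory=lambda: dict(VEG_SUBGROUP_COUNTS))
    seed: int = 0

    def __post_init__(self):
        for n in (self.n_entrees, self.n_fruits, self.n_vegetables,
                  self.n_milks):
            if n <= 0:
                raise ValueError("category counts must be positive")
        total = sum(self.protein_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"protein weights sum to {total}, not 1")
        if sum(self.veg_subgroup_counts.values()) != self.n_vegetables:
            raise ValueError("vegetable subgroup counts must sum to "
                             "n_vegetables")

    def protein_counts(self) -> dict[str, int]:
        """Integer entrée counts per protein type by largest remainder."""
        raw = {s: self.protein_weights.get(s, 0.0) * self.n_entrees
               for s in PROTEIN_ORDER}
        counts = {s: int(np.floor(v)) for s, v in raw.items()}
        short = self.n_entrees - sum(counts.values())
        by_rem = sorted(raw, key=lambda s: (counts[s] - raw[s], s))
        for s in by_rem[:short]:
            counts[s] += 1
        return counts


def _trunc(rng: np.random.Generator, lo: float, hi: float,
           mean: float | None = None, sd: float | None = None) -> float:
    """One draw from a normal truncated to [lo, hi] (rejection, clip
    fallback)."""
    if mean is None:
        mean = 0.5 * (lo + hi)
    if sd is None:
        sd = (hi - lo) / 4.0
    for _ in range(64):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def _entree(rng, idx: int, subcat: str) -> MenuItem:
    lo, hi = ENTREE_COST_WINDOW[subcat]
    cost = _trunc(rng, lo, hi)
    lo, hi = ENTREE_CONSUMPTION_WINDOW[subcat]
    frac = _trunc(rng, lo, hi)
    lo, hi = ENTREE_GWP_WINDOW[subcat]
    gwp = _trunc(rng, lo, hi)
    lo, hi = ENTREE_WATER_WINDOW[subcat]
    water = _trunc(rng, lo, hi)
    energy = _trunc(rng, 300.0, 460.0, mean=380.0, sd=40.0)
    sodium = _trunc(rng, 350.0, 780.0, mean=560.0, sd=90.0)
    sat_fat = {"beef": (3.5, 5.5), "cheese": (4.0, 6.0),
               "chicken": (1.5, 3.0), "turkey": (1.5, 3.0),
               "fish": (0.8, 1.8), "legume": (0.5, 1.5),
               "vegetarian_other": (1.0, 3.5)}[subcat]
    sfa = _trunc(rng, *sat_fat)
    mufa = _trunc(rng, 1.0, 3.5)
    pufa = {"fish": (4.0, 7.0), "legume": (2.0, 4.0),
            "vegetarian_other": (1.5, 3.5)}.get(subcat, (0.8, 2.0))
    pufa = _trunc(rng, *pufa)
    fiber = {"legume": (5.0, 8.0), "vegetarian_other": (3.0, 5.0)}.get(
        subcat, (1.5, 3.5))
    fiber = _trunc(rng, *fiber)
    calcium = _trunc(rng, *((250.0, 400.0) if subcat == "cheese"
                            else (80.0, 220.0)))
    iron = _trunc(rng, *((2.5, 4.5) if subcat in ("beef", "legume")
                         else (1.0, 3.0)))
    hei = {
        "whole_grains": _trunc(rng, 1.4, 2.2),
        "total_protein": _trunc(rng, 1.6, 2.4),
        "refined_grains": 0.0,   # the district serves whole-grain-rich only
    }
    if subcat == "fish":
        hei["seafood_plant_protein"] = _trunc(rng, 1.6, 2.4)
    elif subcat == "legume":
        hei["seafood_plant_protein"] = _trunc(rng, 1.4, 2.2)
        hei["greens_beans"] = _trunc(rng, 0.3, 0.6)   # legumes count twice
    elif subcat == "vegetarian_other":
        hei["seafood_plant_protein"] = _trunc(rng, 0.3, 1.0)
    if subcat == "cheese":
        hei["dairy"] = _trunc(rng, 0.3, 0.7)
    serving = _trunc(rng, 200.0, 300.0)
    return MenuItem(
        item_id=f"E{idx:03d}", name=f"{subcat} entree {idx}",
        category="entree", protein_subcategory=subcat,
        flavor_subcategory=f"flavor_{idx % N_FLAVORS}",
        cost=round(cost, 4), serving_weight=round(serving, 1),
        consumed_weight=round(frac * serving, 1),
        nutrients={
            "energy_kcal": round(energy, 1), "sodium_mg": round(sodium, 1),
            "saturated_fat_g": round(sfa, 2),
            "added_sugar_tsp": round(_trunc(rng, 0.2, 1.2), 2),
            "fiber_g": round(fiber, 2), "calcium_mg": round(calcium, 1),
            "iron_mg": round(iron, 2), "mufa_g": round(mufa, 2),
            "pufa_g": round(pufa, 2), "sfa_g": round(sfa, 2),
        },
        hei_components={k: round(v, 3) for k, v in hei.items()},
        gwp=round(gwp, 3), water_scarcity=round(water, 3),
        max_weekly_repeats=1,
    )


def _fruit(rng, idx: int) -> MenuItem:
    cups = _trunc(rng, 0.40, 0.62)
    juice = idx % 6 == 0          # a minority of offerings are 100 % juice
    energy = _trunc(rng, 55.0, 110.0)
    serving = _trunc(rng, 100.0, 150.0)
    frac = _trunc(rng, 0.40, 0.68)
    return MenuItem(
        item_id=f"F{idx:03d}", name=f"fruit side {idx}", category="fruit",
        cost=round(_trunc(rng, 0.10, 0.30), 4),
        serving_weight=round(serving, 1),
        consumed_weight=round(frac * serving, 1),
        nutrients={
            "energy_kcal": round(energy, 1),
            "sodium_mg": round(_trunc(rng, 0.0, 10.0), 1),
            "saturated_fat_g": 0.0, "added_sugar_tsp": 0.0,
            "fiber_g": round(_trunc(rng, 0.5, 3.0), 2),
            "calcium_mg": round(_trunc(rng, 5.0, 30.0), 1),
            "iron_mg": round(_trunc(rng, 0.1, 0.6), 2),
            "mufa_g": 0.0, "pufa_g": 0.0, "sfa_g": 0.0,
        },
        hei_components={"total_fruit": round(cups, 3),
                        "whole_fruit": 0.0 if juice else round(cups, 3)},
        gwp=round(_trunc(rng, 0.05, 0.18), 3),
        water_scarcity=round(_trunc(rng, 0.02, 0.12), 3),
        max_weekly_repeats=2,
    )


def _vegetable(rng, idx: int, subgroup: str) -> MenuItem:
    cups = _trunc(rng, 0.38, 0.65)
    energy = (_trunc(rng, 70.0, 130.0) if subgroup == "starchy"
              else _trunc(rng, 20.0, 70.0))
    serving = _trunc(rng, 80.0, 130.0)
    frac = _trunc(rng, 0.28, 0.50)    # vegetables are poorly consumed
    hei = {"total_veg": round(cups, 3)}
    if subgroup in ("dark_green", "beans_peas"):
        hei["greens_beans"] = round(cups, 3)
    if subgroup == "beans_peas":
        hei["seafood_plant_protein"] = round(_trunc(rng, 0.3, 0.7), 3)
    return MenuItem(
        item_id=f"V{idx:03d}", name=f"{subgroup} vegetable {idx}",
        category="vegetable", vegetable_subgroup=subgroup,
        cost=round(_trunc(rng, 0.07, 0.22), 4),
        serving_weight=round(serving, 1),
        consumed_weight=round(frac * serving, 1),
        nutrients={
            "energy_kcal": round(energy, 1),
            "sodium_mg": round(_trunc(rng, 30.0, 200.0), 1),
            "saturated_fat_g": round(_trunc(rng, 0.0, 0.4), 2),
            "added_sugar_tsp": 0.0,
            "fiber_g": round(_trunc(rng, 1.5, 4.0), 2),
            "calcium_mg": round(_trunc(rng, 15.0, 60.0), 1),
            "iron_mg": round(_trunc(rng, 0.3, 1.5), 2),
            "mufa_g": round(_trunc(rng, 0.0, 0.8), 2),
            "pufa_g": round(_trunc(rng, 0.0, 0.8), 2),
            "sfa_g": round(_trunc(rng, 0.0, 0.4), 2),
        },
        hei_components=hei,
        gwp=round(_trunc(rng, 0.04, 0.20), 3),
        water_scarcity=round(_trunc(rng, 0.03, 0.15), 3),
        max_weekly_repeats=2,
    )


_MILK_OPTIONS = [
    ("skim plain milk", 90.0, 0.0, 0.1),
    ("low-fat plain milk", 110.0, 0.0, 1.5),
    ("skim chocolate milk", 130.0, 2.5, 0.1),
    ("low-fat chocolate milk", 150.0, 2.5, 1.5),
]


def _milk(rng, idx: int) -> MenuItem:
    name, energy, sugar_tsp, sat = _MILK_OPTIONS[(idx - 1) % 4]
    frac = _trunc(rng, 0.45, 0.70)
    return MenuItem(
        item_id=f"M{idx:03d}", name=name, category="milk",
        cost=round(_trunc(rng, 0.12, 0.20), 4),
        serving_weight=244.0, consumed_weight=round(frac * 244.0, 1),
        nutrients={
            "energy_kcal": energy,
            "sodium_mg": round(_trunc(rng, 100.0, 140.0), 1),
            "saturated_fat_g": sat, "added_sugar_tsp": sugar_tsp,
            "fiber_g": 0.0,
            "calcium_mg": round(_trunc(rng, 280.0, 320.0), 1),
            "iron_mg": 0.0,
            "mufa_g": round(sat * 0.3, 2), "pufa_g": 0.0, "sfa_g": sat,
        },
        hei_components={"dairy": 1.0},
        gwp=round(_trunc(rng, 0.20, 0.32), 3),
        water_scarcity=round(_trunc(rng, 0.06, 0.14), 3),
        max_weekly_repeats=5,
    )


def generate_pool(recipe: PoolRecipe | None = None) -> list[MenuItem]:
    """Generate a validated menu-item pool; deterministic under the seed."""
    if recipe is None:
        recipe = PoolRecipe()
    rng = np.random.default_rng(recipe.seed)
    pool: list[MenuItem] = []
    idx = 0
    for subcat in PROTEIN_ORDER:
        for _ in range(recipe.protein_counts()[subcat]):
            idx += 1
            pool.append(_entree(rng, idx, subcat))
    for k in range(1, recipe.n_fruits + 1):
        pool.append(_fruit(rng, k))
    idx = 0
    for subgroup, n in recipe.veg_subgroup_counts.items():
        for _ in range(n):
            idx += 1
            pool.append(_vegetable(rng, idx, subgroup))
    for k in range(1, recipe.n_milks + 1):
        pool.append(_milk(rng, k))
    return pool


def generate_baseline_menus(pool: list[MenuItem], n_weeks: int,
                            seed: int = 0, week_length: int = 5,
                            limits: RepetitionLimits | None = None,
                            protein_weights: dict[str, float] | None = None,
                            ) -> list[WeeklyMenu]:
    """Sample structurally valid baseline weeks.

    Entrée protein types follow the baseline mixture in expectation; every
    week satisfies the category counts and repetition limits (the baseline
    is NOT constrained to the budget or nutrient bounds — real baseline
    weeks ran slightly over budget).
    """
    if limits is None:
        limits = RepetitionLimits()
    if protein_weights is None:
        protein_weights = dict(DEFAULT_PROTEIN_WEIGHTS)
    rng = np.random.default_rng(seed)
    by_cat: dict[str, list[MenuItem]] = {}
    for it in pool:
        by_cat.setdefault(it.category, []).append(it)
    for cat in ("entree", "fruit", "vegetable", "milk"):
        if cat not in by_cat:
            raise ValueError(f"pool has no {cat} items")
    by_protein: dict[str, list[MenuItem]] = {}
    for it in by_cat["entree"]:
        by_protein.setdefault(it.protein_subcategory, []).append(it)
    subcats = [s for s in PROTEIN_ORDER if s in by_protein]
    weights = np.array([protein_weights.get(s, 0.0) for s in subcats])
    weights = weights / weights.sum()

    by_subgroup: dict[str, list[MenuItem]] = {}
    for it in by_cat["vegetable"]:
        by_subgroup.setdefault(it.vegetable_subgroup, []).append(it)

    def sample_capped(items: list[MenuItem], n: int, cap_fn) -> dict[str, int]:
        chosen: dict[str, int] = {}
        for _ in range(n):
            for _ in range(256):
                it = items[rng.integers(len(items))]
                if chosen.get(it.item_id, 0) < cap_fn(it):
                    chosen[it.item_id] = chosen.get(it.item_id, 0) + 1
                    break
            else:
                raise ValueError("could not satisfy repetition caps")
        return chosen

    menus = []
    for _ in range(n_weeks):
        servings: dict[str, int] = {}
        # entrées: protein mixture with protein & flavour caps, distinct items
        protein_used: dict[str, int] = {}
        flavor_used: dict[str, int] = {}
        picked: set[str] = set()
        for _ in range(week_length):
            for _ in range(512):
                s = subcats[rng.choice(len(subcats), p=weights)]
                if protein_used.get(s, 0) >= limits.protein_subcategory_limit:
                    continue
                it = by_protein[s][rng.integers(len(by_protein[s]))]
                fl = it.flavor_subcategory
                if it.item_id in picked:
                    continue
                if (fl and flavor_used.get(fl, 0)
                        >= limits.flavor_subcategory_limit):
                    continue
                picked.add(it.item_id)
                protein_used[s] = protein_used.get(s, 0) + 1
                if fl:
                    flavor_used[fl] = flavor_used.get(fl, 0) + 1
                servings[it.item_id] = 1
                break
            else:
                raise ValueError("entrée sampling failed under caps")
        servings.update(sample_capped(by_cat["fruit"], week_length,
                                      limits.item_limit))
        # vegetables: one per subgroup, then two more at random
        veg: dict[str, int] = {}
        for subgroup, items in by_subgroup.items():
            it = items[rng.integers(len(items))]
            veg[it.item_id] = veg.get(it.item_id, 0) + 1
        extra = sample_capped(by_cat["vegetable"],
                              max(0, week_length + 2 - len(veg)),
                              lambda it: limits.item_limit(it)
                              - veg.get(it.item_id, 0))
        for k, v in extra.items():
            veg[k] = veg.get(k, 0) + v
        servings.update(veg)
        milk_counts = rng.multinomial(week_length,
                                      np.ones(len(by_cat["milk"]))
                                      / len(by_cat["milk"]))
        for it, c in zip(by_cat["milk"], milk_counts):
            if c:
                servings[it.item_id] = int(c)
        menus.append(WeeklyMenu(servings=servings, week_length=week_length))
    return menus


def tiny_recipe(seed: int = 0) -> PoolRecipe:
    """A pool recipe small enough for the exhaustive enumeration oracle
    (used with 3-day weeks): 6 entrées, 3 fruits, 4 vegetables, 2 milks."""
    return PoolRecipe(
        n_entrees=6, n_fruits=3, n_vegetables=4, n_milks=2,
        protein_weights={"beef": 2 / 6, "chicken": 1 / 6, "fish": 1 / 6,
                         "legume": 1 / 6, "vegetarian_other": 1 / 6},
        veg_subgroup_counts={"dark_green": 1, "red_orange": 1,
                             "starchy": 1, "other": 1},
        seed=seed,
    )
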