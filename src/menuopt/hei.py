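"""Healthy Eating Index 2015 (HEI-2015) scoring of weekly menus.

HEI-2015 scores diet quality on 100 points across 13 components: 9 adequacy
components (more is better) and 4 moderation components (less is better).
Each component is scored on a density basis — amount per 1000 kcal, percent
of energy, or the (PUFA+MUFA)/SFA ratio — with linear interpolation between
a minimum and maximum standard and clamping at the ends.

The "consumed" scoring basis uses the component amounts actually consumed
(offered amount x per-item consumption fraction) over the energy OFFERED,
so it reflects how much of the offered quality students realised.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import yaml

from .items import (MenuItem, WeeklyMenu, consumption_fraction, pool_index)

ADEQUACY = "adequacy"
MODERATION = "moderation"

#: kcal per teaspoon-equivalent of added sugar (4.2 g sugar x 4 kcal/g)
KCAL_PER_TSP_ADDED_SUGAR = 16.0
KCAL_PER_G_FAT = 9.0


class HEIError(ValueError):
    pass


@dataclass(frozen=True)
class ComponentStandard:
    """Scoring standard for one HEI component.

    ``min_standard``/``max_standard`` are in the component's density units:
    amount per 1000 kcal for food-group components, percent of energy for
    added sugars and saturated fat, and a unitless ratio for fatty acids.
    For adequacy components the score rises from 0 at ``min_standard`` to
    ``max_score`` at ``max_standard``; for moderation components it falls
    from ``max_score`` at ``min_standard`` to 0 at ``max_standard``.
    """

    name: str
    max_score: float
    min_standard: float
    max_standard: float
    direction: str            # adequacy | moderation
    kind: str = "density"     # density | percent_energy | fat_ratio
    units: str = ""

    def __post_init__(self):
        if self.direction not in (ADEQUACY, MODERATION):
            raise HEIError(f"{self.name}: bad direction {self.direction}")
        if self.direction == ADEQUACY and not (
                0 <= self.min_standard <= self.max_standard):
            raise HEIError(f"{self.name}: adequacy standards out of order")
        if self.direction == MODERATION and not (
                self.min_standard < self.max_standard):
            raise HEIError(f"{self.name}: moderation standards out of order")


# Published HEI-2015 cut-points.  Density standards are per 1000 kcal;
# added sugars and saturated fat are % of energy; fatty acids is the
# (PUFA+MUFA)/SFA ratio.
DEFAULT_HEI2015: dict[str, ComponentStandard] = {s.name: s for s in [
    ComponentStandard("total_fruit", 5, 0.0, 0.8, ADEQUACY,
                      units="cup eq per 1000 kcal"),
    ComponentStandard("whole_fruit", 5, 0.0, 0.4, ADEQUACY,
                      units="cup eq per 1000 kcal"),
    ComponentStandard("total_veg", 5, 0.0, 1.1, ADEQUACY,
                      units="cup eq per 1000 kcal"),
    ComponentStandard("greens_beans", 5, 0.0, 0.2, ADEQUACY,
                      units="cup eq per 1000 kcal"),
    ComponentStandard("whole_grains", 10, 0.0, 1.5, ADEQUACY,
                      units="oz eq per 1000 kcal"),
    ComponentStandard("dairy", 10, 0.0, 1.3, ADEQUACY,
                      units="cup eq per 1000 kcal"),
    ComponentStandard("total_protein", 5, 0.0, 2.5, ADEQUACY,
                      units="oz eq per 1000 kcal"),
    ComponentStandard("seafood_plant_protein", 5, 0.0, 0.8, ADEQUACY,
                      units="oz eq per 1000 kcal"),
    ComponentStandard("fatty_acids", 10, 1.2, 2.5, ADEQUACY,
                      kind="fat_ratio", units="(PUFA+MUFA)/SFA"),
    ComponentStandard("refined_grains", 10, 1.8, 4.3, MODERATION,
                      units="oz eq per 1000 kcal"),
    ComponentStandard("sodium", 10, 1.1, 2.0, MODERATION,
                      units="g per 1000 kcal"),
    ComponentStandard("added_sugars", 10, 6.5, 26.0, MODERATION,
                      kind="percent_energy", units="% of energy"),
    ComponentStandard("saturated_fats", 10, 8.0, 16.0, MODERATION,
                      kind="percent_energy", units="% of energy"),
]}


@dataclass
class HEIStandards:
    """The 13-component standard set; total of max scores must be 100."""

    components: dict[str, ComponentStandard]

    def __post_init__(self):
        total = sum(c.max_score for c in self.components.values())
        if abs(total - 100.0) > 1e-9:
            raise HEIError(f"component max scores sum to {total}, not 100")

    @classmethod
    def hei2015(cls) -> "HEIStandards":
        return cls(components=dict(DEFAULT_HEI2015))

    @classmethod
    def from_yaml(cls, text: str) -> "HEIStandards":
        """Load a `hei:` config section (one block per component)."""
        raw = yaml.safe_load(text)
        raw = raw.get("hei", raw)
        comps = {}
        for name, block in raw.items():
            comps[name] = ComponentStandard(
                name=name,
                max_score=float(block["max_score"]),
                min_standard=float(block["min_standard"]),
                max_standard=float(block["max_standard"]),
                direction=block["direction"],
                kind=block.get("kind", "density"),
                units=block.get("units", ""),
            )
        return cls(components=comps)


@dataclass
class HEIScore:
    component_scores: dict[str, float]

    @property
    def total(self) -> float:
        return sum(self.component_scores.values())


def component_density(amount: float, energy: float,
                      standard: ComponentStandard,
                      sfa: float | None = None,
                      unsat: float | None = None) -> float:
    """Density of a component for scoring.

    For plain components this is amount per 1000 kcal; percent-energy
    components return (kcal from component / total kcal) x 100 where
    ``amount`` is already in kcal; the fatty-acid component returns
    (PUFA+MUFA)/SFA from ``unsat`` and ``sfa`` grams.
    """
    if standard.kind == "fat_ratio":
        if sfa is None or unsat is None:
            raise HEIError("fatty-acid density needs sfa and unsat grams")
        if sfa <= 0:
            # limit behaviour of the ratio: any unsaturated fat over zero
            # SFA earns the cap; no fat at all earns nothing
            return standard.max_standard if unsat > 0 else 0.0
        return unsat / sfa
    if energy <= 0:
        raise HEIError(f"density undefined for energy {energy} kcal")
    if standard.kind == "percent_energy":
        return amount / energy * 100.0
    return amount / (energy / 1000.0)


def score_component(density: float, standard: ComponentStandard) -> float:
    """Linear score for one component, clamped to [0, max_score].

    Densities between the minimum and maximum standards score
    proportionately.
    """
    lo, hi = standard.min_standard, standard.max_standard
    if standard.direction == ADEQUACY:
        if hi == lo:
            return standard.max_score if density >= hi else 0.0
        frac = (density - lo) / (hi - lo)
    else:
        frac = (hi - density) / (hi - lo)
    return standard.max_score * min(1.0, max(0.0, frac))


def menu_component_amounts(menu: WeeklyMenu, pool: Iterable[MenuItem],
                           basis: Literal["offered", "consumed"] = "offered",
                           ) -> tuple[dict[str, float], float]:
    """Aggregate HEI inputs over a weekly menu.

    Returns (amounts, energy_offered).  ``amounts`` holds cup/oz-eq totals
    per food-group component plus the kcal from added sugars and saturated
    fat, sodium in grams, and total PUFA+MUFA and SFA grams.  On the
    consumed basis every amount is scaled by the item's consumption
    fraction; the energy denominator is always the energy OFFERED.
    """
    index = pool_index(pool)
    amounts: dict[str, float] = {}
    energy_offered = 0.0
    for item_id, count in menu.servings.items():
        if count == 0:
            continue
        it = index[item_id]
        frac = 1.0 if basis == "offered" else consumption_fraction(it)
        w = count * frac
        energy_offered += count * it.nutrients.get("energy_kcal", 0.0)
        for key, value in it.hei_components.items():
            amounts[key] = amounts.get(key, 0.0) + w * value
        n = it.nutrients
        amounts["sodium_g"] = (amounts.get("sodium_g", 0.0)
                               + w * n.get("sodium_mg", 0.0) / 1000.0)
        amounts["added_sugar_kcal"] = (
            amounts.get("added_sugar_kcal", 0.0)
            + w * n.get("added_sugar_tsp", 0.0) * KCAL_PER_TSP_ADDED_SUGAR)
        amounts["saturated_fat_kcal"] = (
            amounts.get("saturated_fat_kcal", 0.0)
            + w * n.get("saturated_fat_g", 0.0) * KCAL_PER_G_FAT)
        amounts["sfa_g"] = amounts.get("sfa_g", 0.0) + w * n.get("sfa_g", 0.0)
        amounts["unsat_g"] = (amounts.get("unsat_g", 0.0)
                              + w * (n.get("mufa_g", 0.0)
                                     + n.get("pufa_g", 0.0)))
    return amounts, energy_offered


#: maps a component name to the key in menu_component_amounts output
_AMOUNT_KEY = {
    "sodium": "sodium_g",
    "added_sugars": "added_sugar_kcal",
    "saturated_fats": "saturated_fat_kcal",
}


def score_menu(menu: WeeklyMenu, pool: Iterable[MenuItem],
               standards: HEIStandards | None = None,
               basis: Literal["offered", "consumed"] = "offered") -> HEIScore:
    """Score a weekly menu with HEI-2015 on the offered or consumed basis.

    The total is the sum of the 13 component scores and lies in [0, 100].
    """
    if standards is None:
        standards = HEIStandards.hei2015()
    if not any(menu.servings.values()):
        raise HEIError("cannot score an empty menu")
    amounts, energy = menu_component_amounts(menu, pool, basis)
    if energy <= 0:
        raise HEIError("cannot score a menu offering zero energy")
    scores: dict[str, float] = {}
    for name, std in standards.components.items():
        if std.kind == "fat_ratio":
            density = component_density(0.0, energy, std,
                                        sfa=amounts.get("sfa_g", 0.0),
                                        unsat=amounts.get("unsat_g", 0.0))
        else:
            amount = amounts.get(_AMOUNT_KEY.get(name, name), 0.0)
            density = component_density(amount, energy, std)
        scores[name] = score_component(density, std)
    return HEIScore(component_scores=scores)
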