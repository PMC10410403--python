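"""Menu metrics: offered vs consumed energy/value, HEI, footprints,
protein composition, baseline averaging and annual cost extrapolation."""

from __future__ import annotations

from typing import Iterable, Sequence

from .hei import HEIStandards, score_menu
from .items import (EvaluationMetrics, MenuDataError, MenuItem, WeeklyMenu,
                    NUTRIENT_KEYS, consumption_fraction, pool_index)


def evaluate_menu(menu: WeeklyMenu, pool: Sequence[MenuItem],
                  hei_standards: HEIStandards | None = None,
                  ) -> EvaluationMetrics:
    """All reported quantities for one weekly menu.

    Consumed quantities weight each serving by the item's plate-waste
    consumption fraction; HEI-consumed uses consumed components over the
    energy offered.
    """
    if not any(menu.servings.values()):
        raise MenuDataError("cannot evaluate an empty menu")
    index = pool_index(pool)
    m = EvaluationMetrics()
    m.nutrients_offered = {k: 0.0 for k in NUTRIENT_KEYS}
    m.nutrients_consumed = {k: 0.0 for k in NUTRIENT_KEYS}
    for item_id, count in menu.servings.items():
        if count == 0:
            continue
        it = index[item_id]
        frac = consumption_fraction(it)
        m.cost_offered += count * it.cost
        m.value_consumed += count * it.cost * frac
        m.energy_offered += count * it.nutrients.get("energy_kcal", 0.0)
        m.energy_consumed += (count * it.nutrients.get("energy_kcal", 0.0)
                              * frac)
        m.gwp += count * it.gwp
        m.water_scarcity += count * it.water_scarcity
        for k in NUTRIENT_KEYS:
            v = it.nutrients.get(k, 0.0)
            m.nutrients_offered[k] += count * v
            m.nutrients_consumed[k] += count * v * frac
    m.hei_offered = score_menu(menu, pool, hei_standards, "offered").total
    m.hei_consumed = score_menu(menu, pool, hei_standards, "consumed").total
    m.protein_composition = composition_by_protein(menu, pool)
    return m


def composition_by_protein(menu: WeeklyMenu, pool: Sequence[MenuItem],
                           ) -> dict[str, float]:
    """Proportion of entrée servings by protein type; sums to 1."""
    index = pool_index(pool)
    counts: dict[str, int] = {}
    total = 0
    for item_id, count in menu.servings.items():
        it = index[item_id]
        if it.category == "entree" and count > 0:
            counts[it.protein_subcategory] = (
                counts.get(it.protein_subcategory, 0) + count)
            total += count
    if total == 0:
        raise MenuDataError("menu has no entrée servings")
    return {sub: c / total for sub, c in sorted(counts.items())}


def compare_to_baseline(optimised: EvaluationMetrics,
                        baseline: EvaluationMetrics,
                        ) -> dict[str, float]:
    """Signed percent change (optimised - baseline)/baseline per metric."""
    out = {}
    for key in ("cost_offered", "value_consumed", "energy_offered",
                "energy_consumed", "hei_offered", "hei_consumed",
                "gwp", "water_scarcity"):
        b = getattr(baseline, key)
        o = getattr(optimised, key)
        if b is None or o is None:
            continue
        if b == 0:
            if o == 0:      # quantity absent on both sides
                continue
            raise MenuDataError(f"baseline {key} is zero; relative change "
                                f"undefined")
        out[key] = (o - b) / b * 100.0
    return out


def baseline_weekly_average(menus: Sequence[WeeklyMenu],
                            pool: Sequence[MenuItem],
                            hei_standards: HEIStandards | None = None,
                            hei_mode: str = "pooled",
                            ) -> EvaluationMetrics:
    """Arithmetic mean of each metric over baseline weeks.

    HEI is by default the score of the average week (component amounts and
    energy pooled across weeks, scored once), since the index is a ratio
    score; ``hei_mode="mean"`` instead averages the weekly scores.
    """
    if not menus:
        raise MenuDataError("no baseline weeks supplied")
    per_week = [evaluate_menu(m, pool, hei_standards) for m in menus]
    n = len(menus)
    avg = EvaluationMetrics()
    for key in ("cost_offered", "value_consumed", "energy_offered",
                "energy_consumed", "gwp", "water_scarcity"):
        setattr(avg, key, sum(getattr(w, key) for w in per_week) / n)
    avg.nutrients_offered = {
        k: sum(w.nutrients_offered[k] for w in per_week) / n
        for k in NUTRIENT_KEYS}
    avg.nutrients_consumed = {
        k: sum(w.nutrients_consumed[k] for w in per_week) / n
        for k in NUTRIENT_KEYS}
    if hei_mode == "mean":
        avg.hei_offered = sum(w.hei_offered for w in per_week) / n
        avg.hei_consumed = sum(w.hei_consumed for w in per_week) / n
    else:
        pooled: dict[str, int] = {}
        for m in menus:
            for item_id, count in m.servings.items():
                pooled[item_id] = pooled.get(item_id, 0) + count
        pooled_menu = WeeklyMenu(servings=pooled,
                                 week_length=menus[0].week_length)
        avg.hei_offered = score_menu(pooled_menu, pool, hei_standards,
                                     "offered").total
        avg.hei_consumed = score_menu(pooled_menu, pool, hei_standards,
                                      "consumed").total
    # entrée composition pooled over all weeks
    totals: dict[str, float] = {}
    for w in per_week:
        for sub, p in w.protein_composition.items():
            totals[sub] = totals.get(sub, 0.0) + p
    avg.protein_composition = {sub: v / n for sub, v in sorted(totals.items())}
    return avg


def annual_extrapolation(weekly_saving: float, weeks_per_year: int = 36,
                         enrollment: int = 50_000,
                         ) -> dict[str, float]:
    """Extrapolate a weekly per-student saving to the school year and the
    district (default: 36-week year, 50 000-student district)."""
    if weeks_per_year <= 0:
        raise MenuDataError("weeks_per_year must be positive")
    per_student = weekly_saving * weeks_per_year
    return {"per_student": per_student,
            "district": per_student * enrollment}
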