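"""End-to-end orchestration: solve all seven models, evaluate, compare.

The seven models are (acronyms used throughout the results):

==========  =================================================
MAX-CALCON  maximise kcal consumed
MAX-COSTCON maximise USD of food value consumed
MIN-COST    minimise weekly food cost
MAX-HEI     drive HEI components to their max-score standards
MIN-DEV     minimise equally-weighted relative goal deviations
MIN-DEV10   as MIN-DEV with weight 10 on the kcal-consumed goal
MIN-DEV30   as MIN-DEV with weight 30 on the kcal-consumed goal
==========  =================================================
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field

from .constraints import build_all_constraints, check_feasibility
from .evaluation import compare_to_baseline, evaluate_menu
from .hei import HEIStandards
from .items import (EvaluationMetrics, MenuItem, NutritionStandards,
                    RepetitionLimits)
from .objectives import (MODEL_NAMES, build_goal_program,
                         multiobjective_goals, objective_max_hei,
                         objective_max_kcal_consumed,
                         objective_max_value_consumed, objective_min_cost,
                         objective_min_footprint, reference_energy)
from .solver import (OPTIMAL, SolveResult, assemble_model, solve)

log = logging.getLogger(__name__)


@dataclass
class ModelRun:
    name: str
    result: SolveResult
    metrics: EvaluationMetrics | None = None
    violations: list = field(default_factory=list)


def run_all_models(pool: list[MenuItem],
                   nutrition: NutritionStandards | None = None,
                   hei_standards: HEIStandards | None = None,
                   limits: RepetitionLimits | None = None,
                   goal_overrides: dict | None = None,
                   ) -> dict[str, ModelRun]:
    """Solve the seven models over one pool under common constraints.

    An infeasible model is reported with its hint; the remaining models
    still run.  Multi-objective goal values default to the ideal point
    (each single objective's own optimum), overridable per goal.
    """
    if nutrition is None:
        nutrition = NutritionStandards()
    if hei_standards is None:
        hei_standards = HEIStandards.hei2015()
    if limits is None:
        limits = RepetitionLimits()
    constraints = build_all_constraints(pool, nutrition, limits)
    week = nutrition.week_length
    e_ref = reference_energy(nutrition)

    def run(objective, name=None) -> ModelRun:
        model = assemble_model(pool, nutrition, objective, limits=limits,
                               constraints=constraints, name=name)
        t0 = time.perf_counter()
        res = solve(model, week_length=week)
        log.info("%s: %s, objective=%s (%.2fs)", model.name, res.status,
                 res.objective_value, time.perf_counter() - t0)
        runrec = ModelRun(model.name, res)
        if res.status == OPTIMAL:
            runrec.metrics = evaluate_menu(res.menu, pool, hei_standards)
            runrec.violations = check_feasibility(res.menu, constraints)
        return runrec

    out: dict[str, ModelRun] = {}
    out["MAX-CALCON"] = run(objective_max_kcal_consumed(pool))
    out["MAX-COSTCON"] = run(objective_max_value_consumed(pool))
    out["MIN-COST"] = run(objective_min_cost(pool))
    out["MAX-HEI"] = run(objective_max_hei(pool, hei_standards, e_ref))

    # ideal point for the multi-objective goals; gwp/water need two extra
    # single-objective solves
    aux = {"gwp": run(objective_min_footprint(pool, "gwp")),
           "water_scarcity": run(objective_min_footprint(pool, "water"))}
    anchors_ok = (out["MAX-CALCON"].result.status == OPTIMAL
                  and out["MIN-COST"].result.status == OPTIMAL
                  and all(a.result.status == OPTIMAL for a in aux.values()))
    if anchors_ok:
        ideal = {
            "kcal_consumed": out["MAX-CALCON"].result.objective_value,
            "cost": out["MIN-COST"].result.objective_value,
            "gwp": aux["gwp"].result.objective_value,
            "water_scarcity": aux["water_scarcity"].result.objective_value,
        }
        for key, override in (goal_overrides or {}).items():
            if key in ideal and "value" in override:
                ideal[key] = float(override["value"])
        for name, w in [("MIN-DEV", 1.0), ("MIN-DEV10", 10.0),
                        ("MIN-DEV30", 30.0)]:
            goals = multiobjective_goals(pool, nutrition, hei_standards,
                                         ideal, kcal_weight=w)
            out[name] = run(build_goal_program(name, goals))
    else:
        bad = [n for n, r in out.items() if r.result.status != OPTIMAL]
        log.warning("skipping multi-objective models: infeasible anchors %s",
                    bad)
        for name in ("MIN-DEV", "MIN-DEV10", "MIN-DEV30"):
            out[name] = ModelRun(name, SolveResult(
                "error", solver_log=f"goal anchors unavailable: {bad}"))
    return {name: out[name] for name in MODEL_NAMES}


def report(results: dict[str, ModelRun],
           baseline: EvaluationMetrics | None = None) -> tuple[str, dict]:
    """Human-readable table plus a structured (JSON-serialisable) summary.

    Percent-vs-baseline columns appear only when a baseline is supplied.
    Identical inputs give byte-identical structured output.
    """
    structured: dict = {"models": {}}
    if baseline is not None:
        structured["baseline"] = baseline.to_dict()
    lines = []
    header = (f"{'model':<12}{'status':<11}{'objective':>11}{'cost':>7}"
              f"{'kcal_off':>9}{'kcal_con':>9}{'HEI_off':>8}{'HEI_con':>8}"
              f"{'GWP':>7}{'water':>7}")
    lines.append(header)
    lines.append("-" * len(header))
    for name, run in results.items():
        rec: dict = {"status": run.result.status,
                     "objective_value": run.result.objective_value}
        if run.result.status != OPTIMAL:
            rec["hint"] = run.result.solver_log
            lines.append(f"{name:<12}{run.result.status:<11}"
                         f"{'-':>11}  {run.result.solver_log}")
            structured["models"][name] = rec
            continue
        m = run.metrics
        rec["servings"] = run.result.menu.nonzero()
        rec["deviations"] = run.result.deviations
        rec["metrics"] = m.to_dict()
        rec["violations"] = [str(v) for v in run.violations]
        if baseline is not None:
            rec["pct_vs_baseline"] = compare_to_baseline(m, baseline)
        lines.append(
            f"{name:<12}{run.result.status:<11}"
            f"{run.result.objective_value:>11.3f}{m.cost_offered:>7.2f}"
            f"{m.energy_offered:>9.0f}{m.energy_consumed:>9.0f}"
            f"{m.hei_offered:>8.1f}{m.hei_consumed:>8.1f}"
            f"{m.gwp:>7.2f}{m.water_scarcity:>7.2f}")
        structured["models"][name] = rec
    if baseline is not None:
        lines.append("-" * len(header))
        lines.append(
            f"{'baseline':<12}{'':<11}{'':>11}{baseline.cost_offered:>7.2f}"
            f"{baseline.energy_offered:>9.0f}"
            f"{baseline.energy_consumed:>9.0f}"
            f"{baseline.hei_offered:>8.1f}{baseline.hei_consumed:>8.1f}"
            f"{baseline.gwp:>7.2f}{baseline.water_scarcity:>7.2f}")
    return "\n".join(lines) + "\n", structured


def report_to_json(structured: dict) -> str:
    return json.dumps(structured, indent=2, sort_keys=True) + "\n"
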