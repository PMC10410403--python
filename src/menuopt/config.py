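"""Config-file plumbing: nutrition standards, repetition limits, HEI
cut-points and goal overrides from one YAML document.

Any subset of keys may be supplied; missing keys keep the shipped K-5 /
HEI-2015 defaults.  Sections: ``nutrition:``, ``budget:``, ``repetition:``,
``hei:``, ``goals:``.
"""

from __future__ import annotations

from dataclasses import fields, replace
from pathlib import Path

import yaml

from .hei import HEIStandards
from .items import NutritionStandards, RepetitionLimits


def load_config(path: str | Path | None = None, text: str | None = None,
                ) -> dict:
    """Parse a config file into standards objects.

    Returns a dict with keys ``nutrition`` (NutritionStandards),
    ``repetition`` (RepetitionLimits), ``hei`` (HEIStandards) and ``goals``
    (per-goal override mapping, possibly empty).
    """
    raw = {}
    if text is not None:
        raw = yaml.safe_load(text) or {}
    elif path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}

    nutrition = NutritionStandards()
    nut_raw = dict(raw.get("nutrition", {}))
    if "budget" in raw:
        nut_raw["budget"] = raw["budget"]
    known = {f.name for f in fields(NutritionStandards)}
    unknown = set(nut_raw) - known
    if unknown:
        raise ValueError(f"unknown nutrition keys: {sorted(unknown)}")
    if nut_raw:
        nutrition = replace(nutrition, **nut_raw)

    repetition = RepetitionLimits()
    rep_raw = raw.get("repetition", {})
    if rep_raw:
        repetition = RepetitionLimits(
            per_item_default={**repetition.per_item_default,
                              **rep_raw.get("per_item", {})},
            protein_subcategory_limit=rep_raw.get(
                "protein_subcategory_limit",
                repetition.protein_subcategory_limit),
            flavor_subcategory_limit=rep_raw.get(
                "flavor_subcategory_limit",
                repetition.flavor_subcategory_limit),
        )

    hei = HEIStandards.hei2015()
    if raw.get("hei"):
        hei = HEIStandards.from_yaml(yaml.safe_dump({"hei": raw["hei"]}))

    return {"nutrition": nutrition, "repetition": repetition, "hei": hei,
            "goals": raw.get("goals", {})}


def dump_config(nutrition: NutritionStandards,
                repetition: RepetitionLimits,
                hei: HEIStandards) -> str:
    """Serialise resolved standards back to YAML (run provenance)."""
    doc = {
        "nutrition": {f.name: getattr(nutrition, f.name)
                      for f in fields(NutritionStandards)},
        "repetition": {
            "per_item": repetition.per_item_default,
            "protein_subcategory_limit": repetition.protein_subcategory_limit,
            "flavor_subcategory_limit": repetition.flavor_subcategory_limit,
        },
        "hei": {name: {
            "max_score": c.max_score, "min_standard": c.min_standard,
            "max_standard": c.max_standard, "direction": c.direction,
            "kind": c.kind, "units": c.units,
        } for name, c in hei.components.items()},
    }
    return yaml.safe_dump(doc, sort_keys=True)
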