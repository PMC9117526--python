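"""Cradle-to-consumption footprint calculators.

The multiplicative core, shared by all three indicators, converts a
cradle-to-farm-gate value (per kg as produced) to a value per kg as consumed:

    total = farm_gate * edible_factor * 1 / (1 - loss) + stage_addition

``edible_factor`` >= 1 undoes inedible mass (peel, bone: 1/edible portion or
1/boneless ratio); ``1/(1 - loss)`` charges the footprint of food produced
but lost along the supply chain to the kg actually eaten; ``stage_addition``
is the post-farm-gate GHGE sum and is zero for water and land use, whose
post-farm-gate increases are negligible.

Dividing by the *surviving* fraction (1 - loss) is the physically meaningful
reading of a "loss correction": the produced mass behind 1 kg consumed is
1/(1 - loss) kg.  An audit-only mode dividing by the loss proportion itself
is provided for traceability but is dimensionally absurd for normal use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import INDICATORS
from .registry import FoodItem, LossProfile, Registry

__all__ = [
    "FootprintResult",
    "loss_total",
    "total_footprint",
    "impute_proxy",
    "proxy_donor",
    "direct_map",
    "resolve_mapping",
    "UnmappedError",
    "DEFAULT_PROXY_RULES",
    "build_footprint_table",
    "provenance_counts",
]


class UnmappedError(KeyError):
    """A food could not be resolved to any footprint value."""


@dataclass(frozen=True)
class FootprintResult:
    """One food x indicator cradle-to-consumption value with its audit trail."""

    food_code: str
    indicator: str
    farm_gate_value: float
    loss_total: float
    edible_factor: float
    stage_addition: float
    total: float
    provenance: str
    trail: tuple[str, ...] = field(default_factory=tuple)


def loss_total(profile: LossProfile, mode: str = "additive") -> float:
    """Total supply-chain loss proportion for one profile.

    Stage proportions combine additively by default (this reproduces every
    printed total of the source loss table); ``mode="multiplicative"``
    combines surviving fractions, 1 - prod(1 - l_i), for sensitivity
    analysis.  Profiles carrying only a printed total return it directly.
    """
    stages = profile.stages
    if not stages:
        if profile.printed_total is None:
            raise ValueError(f"{profile.key}: no loss information at all")
        return profile.printed_total
    if mode == "additive":
        total = sum(stages.values())
    elif mode == "multiplicative":
        total = 1.0 - float(np.prod([1.0 - v for v in stages.values()]))
    else:
        raise ValueError("mode must be 'additive' or 'multiplicative'")
    if total >= 1.0:
        raise ValueError(f"{profile.key}: total loss {total} >= 1")
    return total


def total_footprint(
    farm_gate: float,
    indicator: str,
    edible_factor: float = 1.0,
    loss: float = 0.0,
    stage_addition: float = 0.0,
    food_code: str = "",
    provenance: str = "literature",
    loss_interpretation: str = "surviving_fraction",
) -> FootprintResult:
    """Apply the cradle-to-consumption formula for one food x indicator.

    Water- and land-use totals never include stage additions; a nonzero
    ``stage_addition`` passed for those indicators is forced to zero and the
    coercion is recorded in the trail.
    """
    if indicator not in INDICATORS:
        raise ValueError(f"unknown indicator {indicator!r}")
    if farm_gate < 0:
        raise ValueError("farm_gate must be >= 0")
    if edible_factor < 1.0:
        raise ValueError("edible_factor must be >= 1")
    if not (0.0 <= loss < 1.0):
        raise ValueError(f"loss must be in [0, 1), got {loss}")
    if stage_addition < 0:
        raise ValueError("stage_addition must be >= 0")

    trail = [f"farm_gate={farm_gate:g}"]
    if indicator != "GHGE" and stage_addition != 0.0:
        trail.append("stage_addition_forced_zero_for_non_ghge")
        stage_addition = 0.0

    if loss_interpretation == "surviving_fraction":
        loss_factor = 1.0 / (1.0 - loss)
    elif loss_interpretation == "loss_proportion":  # audit only
        loss_factor = 1.0 / loss if loss > 0 else 1.0
        trail.append("audit_mode_division_by_loss_proportion")
    else:
        raise ValueError("loss_interpretation must be 'surviving_fraction' or 'loss_proportion'")

    trail += [
        f"edible_factor={edible_factor:g}",
        f"loss={loss:g}",
        f"stage_addition={stage_addition:g}",
    ]
    total = farm_gate * edible_factor * loss_factor + stage_addition
    return FootprintResult(
        food_code=food_code,
        indicator=indicator,
        farm_gate_value=farm_gate,
        loss_total=loss,
        edible_factor=edible_factor,
        stage_addition=stage_addition,
        total=total,
        provenance=provenance,
        trail=tuple(trail),
    )


# -- proxy imputation ----------------------------------------------------

#: Donor groups for foods with no published value: tubers and fungi borrow
#: the vegetables average, nuts the fruits average (similar cultivation).
DEFAULT_PROXY_RULES: dict[tuple[str, str], str] = {
    ("Tubers and starches", "LU"): "Vegetables",
    ("Fungi and algae", "LU"): "Vegetables",
    ("Nuts and seeds", "LU"): "Fruits",
}


def proxy_donor(
    group: str,
    indicator: str,
    rules: Mapping[tuple[str, str], str] | None = None,
) -> str:
    rules = DEFAULT_PROXY_RULES if rules is None else rules
    try:
        return rules[(group, indicator)]
    except KeyError:
        raise UnmappedError(f"no proxy rule for ({group!r}, {indicator!r})") from None


def impute_proxy(
    food: FoodItem,
    registry: Registry,
    group_summaries: pd.DataFrame,
    indicator: str,
    rules: Mapping[tuple[str, str], str] | None = None,
    has_literature: bool = False,
    **kwargs,
) -> FootprintResult:
    """Impute a missing farm-gate value from a donor group's mean.

    Refuses to overwrite a food that does have a literature value; raises
    :class:`UnmappedError` when no proxy rule exists (never a silent zero).
    The donor group is recorded in the provenance trail.
    """
    if has_literature:
        raise ValueError(f"{food.code}: has a literature value; proxy refused")
    donor = proxy_donor(food.group, indicator, rules)
    sel = group_summaries[
        (group_summaries["group"] == donor) & (group_summaries["indicator"] == indicator)
    ]
    if sel.empty:
        raise UnmappedError(f"donor group {donor!r} has no {indicator} summary")
    farm_gate = float(sel["mean"].iloc[0])
    res = _item_footprint(food, registry, indicator, farm_gate, provenance="proxy", **kwargs)
    return FootprintResult(
        **{**res.__dict__, "trail": res.trail + (f"proxy_donor={donor}",)}
    )


# -- direct mapping ------------------------------------------------------


def resolve_mapping(code: str, mapping: Mapping[str, str]) -> str:
    """Follow variant -> base links to the terminal base code.

    Chains are allowed (a mapping of two hops equals one); cycles raise.
    """
    seen = [code]
    while code in mapping:
        code = mapping[code]
        if code in seen:
            raise ValueError(f"cyclic direct mapping: {' -> '.join(seen + [code])}")
        seen.append(code)
    return code


def direct_map(base_result: FootprintResult, variant_code: str) -> FootprintResult:
    """Copy a base food's footprint onto an equivalent variant.

    The value is identical irrespective of form (raw, boiled, dried, graded,
    branded); only the provenance differs.
    """
    return FootprintResult(
        **{
            **base_result.__dict__,
            "food_code": variant_code,
            "provenance": "direct_mapping",
            "trail": base_result.trail + (f"direct_mapping_from={base_result.food_code}",),
        }
    )


# -- full-table assembly -------------------------------------------------


def _item_footprint(
    item: FoodItem,
    registry: Registry,
    indicator: str,
    farm_gate: float,
    provenance: str,
    totals: str = "computed",
    loss_mode: str = "additive",
) -> FootprintResult:
    """Apply the item's own conversion chain to a farm-gate value."""
    from .stages import stage_total  # local import to avoid a cycle

    profile = registry.loss_profile(item.group, item.commodity)
    if profile is not None:
        loss = loss_total(profile, mode=loss_mode)
    else:
        commodities = registry.commodity_profiles(item.group)
        if commodities:
            loss = float(np.mean([loss_total(p, mode=loss_mode) for p in commodities]))
        else:
            loss = 0.0
    stage_add = 0.0
    if indicator == "GHGE":
        sp = registry.stage_parameters(item.group)
        if sp is not None:
            stage_add = stage_total(sp, totals=totals)
    return total_footprint(
        farm_gate,
        indicator,
        edible_factor=registry.edible_factor(item.code),
        loss=loss,
        stage_addition=stage_add,
        food_code=item.code,
        provenance=provenance,
    )


def build_footprint_table(
    registry: Registry,
    item_means: pd.DataFrame,
    group_summaries: pd.DataFrame,
    recipes: Mapping[str, "object"] | None = None,
    mapping: Mapping[str, str] | None = None,
    processed_map: Mapping[str, str] | None = None,
    proxy_rules: Mapping[tuple[str, str], str] | None = None,
    totals: str = "computed",
    loss_mode: str = "additive",
) -> tuple[pd.DataFrame, list[str]]:
    """Assemble the per-food x indicator cradle-to-consumption table.

    Resolution order per food: own literature value -> direct mapping to an
    equivalent base food -> processing variant (base total plus the group's
    processing-stage addition) -> recipe disaggregation -> proxy donor
    group.  Foods resolvable by none of these are returned in the unmapped
    list, never written as zeros.

    ``item_means`` has columns (food_code, indicator, mean) of screened
    farm-gate literature values; ``group_summaries`` the per-group means used
    by proxy rules.  Returns (table, unmapped codes) where the table has one
    row per food x indicator with value, provenance and audit trail.
    """
    from .recipes import recipe_footprint  # local import to avoid a cycle

    mapping = dict(mapping or {})
    processed_map = dict(processed_map or {})
    recipes = dict(recipes or {})
    lit: dict[tuple[str, str], float] = {
        (str(r.food_code), str(r.indicator)): float(r.mean)
        for r in item_means.itertuples(index=False)
    }

    rows: list[dict] = []
    unmapped: list[str] = []
    results: dict[tuple[str, str], FootprintResult] = {}

    def resolve(code: str, indicator: str, pending: frozenset[str]) -> FootprintResult:
        key = (code, indicator)
        if key in results:
            return results[key]
        if code in pending:
            raise ValueError(f"cyclic resolution at {code}")
        pending = pending | {code}
        if key in lit:
            res = _item_footprint(
                registry[code], registry, indicator, lit[key], "literature",
                totals=totals, loss_mode=loss_mode,
            )
        elif code in mapping:
            base = resolve_mapping(code, mapping)
            res = direct_map(resolve(base, indicator, pending), code)
        elif code in processed_map:
            base_res = resolve(processed_map[code], indicator, pending)
            add = 0.0
            if indicator == "GHGE":
                sp = registry.stage_parameters(registry[code].group)
                if sp is not None and sp.processing is not None:
                    add = sp.processing
            res = FootprintResult(
                **{
                    **base_res.__dict__,
                    "food_code": code,
                    "total": base_res.total + add,
                    "stage_addition": base_res.stage_addition + add,
                    "provenance": "processing",
                    "trail": base_res.trail
                    + (f"processing_from={base_res.food_code}", f"processing_addition={add:g}"),
                }
            )
        elif code in recipes:
            value = recipe_footprint(
                recipes[code],
                lambda c: resolve(c, indicator, pending).total,
            )
            res = FootprintResult(
                food_code=code,
                indicator=indicator,
                farm_gate_value=float("nan"),
                loss_total=0.0,
                edible_factor=1.0,
                stage_addition=0.0,
                total=value,
                provenance="recipe",
                trail=(f"recipe_ingredients={len(recipes[code].ingredients)}",),
            )
        elif code in registry:
            res = impute_proxy(
                registry[code], registry, group_summaries, indicator,
                rules=proxy_rules, totals=totals, loss_mode=loss_mode,
            )
        else:
            raise UnmappedError(f"{code}: not in registry, no recipe or mapping")
        results[key] = res
        return res

    codes = list(registry.items) + [c for c in recipes if c not in registry]
    for code in codes:
        if code in registry:
            name, group = registry[code].name, registry[code].group
        else:
            name, group = code, "Fast foods"  # recipe composite outside the registry
        for indicator in INDICATORS:
            try:
                res = resolve(code, indicator, frozenset())
            except UnmappedError:
                unmapped.append(f"{code}:{indicator}")
                continue
            rows.append(
                {
                    "food_code": code,
                    "food_name": name,
                    "group": group,
                    "indicator": res.indicator,
                    "total": res.total,
                    "farm_gate_value": res.farm_gate_value,
                    "loss_total": res.loss_total,
                    "edible_factor": res.edible_factor,
                    "stage_addition": res.stage_addition,
                    "provenance": res.provenance,
                    "trail": ";".join(res.trail),
                }
            )
    cols = [
        "food_code", "food_name", "group", "indicator", "total", "farm_gate_value",
        "loss_total", "edible_factor", "stage_addition", "provenance", "trail",
    ]
    return pd.DataFrame(rows, columns=cols), unmapped


def provenance_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Per group x indicator breakdown of how values were obtained.

    Columns: from_literature, direct_mapping, processing, recipe, proxy and
    their total — the shape of the source-accounting table of the database.
    """
    if table.empty:
        return pd.DataFrame(
            columns=["group", "indicator", "literature", "direct_mapping", "processing", "recipe", "proxy", "total"]
        )
    counts = (
        table.groupby(["group", "indicator", "provenance"]).size().unstack(fill_value=0)
    )
    for col in ("literature", "direct_mapping", "processing", "recipe", "proxy"):
        if col not in counts.columns:
            counts[col] = 0
    counts = counts[["literature", "direct_mapping", "processing", "recipe", "proxy"]]
    counts["total"] = counts.sum(axis=1)
    return counts.reset_index()
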