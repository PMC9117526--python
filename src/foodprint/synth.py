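"""Synthetic data with known ground truth for every pipeline stage.

Generates literature corpora, food registries, recipes and intake surveys
that exercise the full build-and-link workflow without any downloads.
Literature values are drawn from lognormal distributions (LCA footprints
are non-negative and right-skewed) whose first two moments match the
per-group targets — by default the published per-group means and standard
deviations of the literature summary — so corpus -> screen -> summarize can
be checked for parameter recovery.  A small fraction of records deliberately
violates the screening rules (out-of-window years, missing boundary) to
exercise the screen.

All randomness flows from one root seed; the same seed yields byte-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .corpus import INDICATORS, LCARecord
from .diets import IntakeRecord
from .recipes import Ingredient, Recipe
from .registry import (
    ANIMAL_GROUPS,
    FOOD_GROUPS,
    FoodItem,
    Registry,
    load_default_tables,
    normalize_group,
)

__all__ = ["SynthesisConfig", "generate_registry", "generate_corpus", "generate_recipes", "generate_survey"]

_MEAT_COMMODITIES = ("Pork", "Beef", "Mutton")
_CEREAL_COMMODITIES = ("Rice", "Wheat", "Corn")
_SPECIES_FOR_COMMODITY = {"Pork": "pork", "Beef": "beef", "Mutton": "sheep"}


@dataclass(frozen=True)
class SynthesisConfig:
    """Knobs of the generator; defaults emulate the published corpus.

    ``group_targets`` has columns (group, indicator, n_items, n_values,
    mean, stdev); absent stdev means a single-observation row.  ``n_persons``
    sizes the intake survey; ``recipe_depth`` the nesting of composite
    recipes; ``violation_rate`` the fraction of corpus records that break a
    screening rule on purpose.
    """

    seed: int = 0
    group_targets: pd.DataFrame = field(default_factory=lambda: load_default_tables().literature_summary)
    n_persons: int = 20
    recipe_depth: int = 2
    violation_rate: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 <= self.violation_rate < 1.0):
            raise ValueError("violation_rate must be in [0, 1)")

    @staticmethod
    def single(
        group: str, indicator: str, mean: float, stdev: float, n_values: int,
        n_items: int = 1, seed: int = 0, **kw,
    ) -> "SynthesisConfig":
        """Config targeting a single (group, indicator) cell."""
        targets = pd.DataFrame(
            [{"group": group, "indicator": indicator, "n_items": n_items,
              "n_studies": max(1, n_values // 4), "n_values": n_values,
              "mean": mean, "stdev": stdev}]
        )
        return SynthesisConfig(seed=seed, group_targets=targets, **kw)


def _rng(config: SynthesisConfig, stream: int) -> np.random.Generator:
    # independent, reproducible stream per generator stage
    return np.random.default_rng([config.seed, stream])


def generate_registry(config: SynthesisConfig) -> Registry:
    """Food registry with composition-table-style codes covering the targets.

    Codes are opaque zero-padded strings ``GGIII`` (group index, item index).
    Animal-group items carry a species and a live boneless basis; meat and
    cereal items carry a commodity tag so commodity-level loss rows apply.
    Plant edible portions are drawn in [0.6, 1.0].
    """
    rng = _rng(config, 1)
    items: list[FoodItem] = []
    n_items_per_group: dict[str, int] = {}
    for _, row in config.group_targets.iterrows():
        g = normalize_group(str(row["group"]))
        n_items_per_group[g] = max(n_items_per_group.get(g, 0), int(row["n_items"]))
    for g in n_items_per_group:
        gi = FOOD_GROUPS.index(g) + 1
        for ii in range(n_items_per_group[g]):
            code = f"{gi:02d}{ii + 1:03d}"
            commodity = None
            species = None
            basis = "none"
            edible = 1.0
            if g in ANIMAL_GROUPS:
                basis = "live"
                if g == "Meat":
                    commodity = _MEAT_COMMODITIES[ii % 3]
                    species = _SPECIES_FOR_COMMODITY[commodity]
                elif g == "Poultry":
                    species = "chicken"
                else:
                    species = "fish"
            else:
                edible = float(np.round(rng.uniform(0.6, 1.0), 3))
                if g == "Cereals":
                    commodity = _CEREAL_COMMODITIES[ii % 3]
            items.append(
                FoodItem(
                    code=code,
                    name=f"{g.lower()} item {ii + 1}",
                    group=g,
                    edible_portion=edible,
                    boneless_basis=basis,
                    species=species,
                    commodity=commodity,
                )
            )
    return Registry(items=items)


def _lognormal_params(mean: float, stdev: float) -> tuple[float, float]:
    """Moment-matched (mu, sigma) of the underlying normal."""
    if mean <= 0:
        raise ValueError("lognormal moment matching needs mean > 0")
    var = stdev**2
    sigma2 = np.log1p(var / mean**2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def generate_corpus(config: SynthesisConfig, registry: Registry | None = None) -> list[LCARecord]:
    """Literature records matching the per-group moment targets.

    Values: lognormal with mean/stdev equal to the target (degenerate
    constant when stdev is 0 or missing); years uniform on 2005-2020;
    boundary cradle-to-farm-gate; sources cycle within each group.  A
    ``violation_rate`` fraction of records is corrupted (year outside the
    window or boundary ``other``) to exercise screening.
    """
    if registry is None:
        registry = generate_registry(config)
    rng = _rng(config, 2)
    records: list[LCARecord] = []
    by_group: dict[str, list[str]] = {}
    for code, item in registry.items.items():
        by_group.setdefault(item.group, []).append(code)
    for _, row in config.group_targets.sort_values(["indicator", "group"]).iterrows():
        g, ind = normalize_group(str(row["group"])), str(row["indicator"])
        n = int(row["n_values"])
        mean = float(row["mean"])
        stdev = float(row["stdev"]) if pd.notna(row["stdev"]) else 0.0
        if stdev > 0 and mean == 0:
            raise ValueError(f"{g}/{ind}: stdev > 0 with mean 0 is unsatisfiable")
        if stdev > 0:
            mu, sigma = _lognormal_params(mean, stdev)
            values = rng.lognormal(mu, sigma, size=n)
        else:
            values = np.full(n, mean)
        years = rng.integers(2005, 2021, size=n)
        codes = [c for c in by_group.get(g, [])][: int(row["n_items"])] or [f"unregistered-{g}"]
        n_studies = max(1, int(row.get("n_studies", max(1, n // 4))))
        for k in range(n):
            rec = LCARecord(
                food_code=codes[k % len(codes)],
                indicator=ind,
                value=float(values[k]),
                year=int(years[k]),
                boundary="cradle_to_farm_gate",
                method="process",
                weight_basis="live" if g in ANIMAL_GROUPS else "as_purchased",
                source_id=f"{g[:3].lower()}-{ind.lower()}-src{k % n_studies:03d}",
            )
            records.append(rec)
    # corrupt a deterministic fraction to exercise the screen
    n_bad = int(round(config.violation_rate * len(records)))
    if n_bad:
        bad_idx = rng.choice(len(records), size=n_bad, replace=False)
        for j, idx in enumerate(sorted(bad_idx)):
            r = records[idx]
            if j % 2 == 0:
                records[idx] = replace(r, year=int(rng.choice([1999, 2003, 2022, 2024])))
            else:
                records[idx] = replace(r, boundary="other")
    return records


def generate_recipes(config: SynthesisConfig, registry: Registry) -> dict[str, Recipe]:
    """Composite recipes over registry items, nested up to ``recipe_depth``.

    Composites get fresh codes (prefix ``90``); level-k composites may
    include level-(k-1) composites as ingredients, so flattening and cycle
    handling are exercised.
    """
    rng = _rng(config, 3)
    base_codes = [c for c, it in registry.items.items() if it.group != "Fast foods"]
    if not base_codes:
        raise ValueError("registry has no base items to build recipes from")
    recipes: dict[str, Recipe] = {}
    prev_level: list[str] = []
    counter = 0
    for depth in range(max(1, config.recipe_depth)):
        level: list[str] = []
        for _ in range(2):
            counter += 1
            code = f"90{counter:03d}"
            pool = list(prev_level) + list(base_codes)
            k = int(rng.integers(2, 4))
            chosen = rng.choice(len(pool), size=min(k, len(pool)), replace=False)
            ingredients = tuple(
                Ingredient(pool[i], float(np.round(rng.uniform(0.05, 0.6), 3))) for i in chosen
            )
            recipes[code] = Recipe(
                composite_code=code,
                ingredients=ingredients,
                yield_factor=float(np.round(rng.uniform(1.0, 3.0), 2)),
                source="FCT",
            )
            level.append(code)
        prev_level = level
    return recipes


def generate_survey(
    config: SynthesisConfig,
    registry: Registry,
    footprint_table: pd.DataFrame,
) -> tuple[list[IntakeRecord], pd.DataFrame]:
    """Intake records plus their analytically expected per-person footprints.

    Each person eats 3-8 foods drawn from the footprint table at gamma-
    distributed daily amounts (mean ~150 g/day).  The expected footprint is
    computed in closed form during generation, per person and indicator, so
    the diet-linkage pipeline can be verified end to end.
    """
    if not registry.items:
        raise ValueError("registry is empty")
    rng = _rng(config, 4)
    per_kg: dict[str, dict[str, float]] = {}
    for r in footprint_table.itertuples(index=False):
        per_kg.setdefault(str(r.indicator), {})[str(r.food_code)] = float(r.total)
    codes = sorted(set(footprint_table["food_code"].astype(str)))
    if not codes:
        raise ValueError("footprint table is empty")
    intakes: list[IntakeRecord] = []
    expected_rows: list[dict] = []
    for p in range(config.n_persons):
        pid = f"P{p + 1:04d}"
        n_foods = int(rng.integers(3, 9))
        chosen = rng.choice(len(codes), size=min(n_foods, len(codes)), replace=False)
        exp = {ind: 0.0 for ind in INDICATORS}
        for i in chosen:
            grams = float(np.round(rng.gamma(shape=2.0, scale=75.0), 1))
            intakes.append(IntakeRecord(pid, codes[i], grams))
            for ind in INDICATORS:
                if codes[i] in per_kg.get(ind, {}):
                    exp[ind] += grams / 1000.0 * per_kg[ind][codes[i]]
        for ind in INDICATORS:
            expected_rows.append({"person_id": pid, "indicator": ind, "expected": exp[ind]})
    return intakes, pd.DataFrame(expected_rows)
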