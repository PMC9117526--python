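"""Recipe disaggregation: composite foods to raw-ingredient quantities.

A recipe expresses one kg of composite food as consumed in terms of raw
ingredient masses.  Cooked portions convert to raw via a yield factor
(cooked mass / raw mass); recipe footprints are the raw-mass-weighted sum of
ingredient footprints.  Nested recipes (a composite ingredient inside
another composite) flatten fully; cyclic recipe graphs are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import pandas as pd

__all__ = ["Ingredient", "Recipe", "to_raw", "flatten_recipe", "recipe_footprint", "read_recipes", "write_recipes"]


@dataclass(frozen=True)
class Ingredient:
    food_code: str
    raw_kg_per_kg: float  # raw ingredient mass per kg of composite as consumed

    def __post_init__(self) -> None:
        if self.raw_kg_per_kg <= 0:
            raise ValueError(f"{self.food_code}: ingredient weight must be > 0")


@dataclass(frozen=True)
class Recipe:
    composite_code: str
    ingredients: tuple[Ingredient, ...]
    yield_factor: float = 1.0  # cooked mass / raw mass
    source: str = "FCT"  # FCT | internet_first_hit | user

    def __post_init__(self) -> None:
        if not self.ingredients:
            raise ValueError(f"{self.composite_code}: recipe needs at least one ingredient")
        if self.yield_factor <= 0:
            raise ValueError(f"{self.composite_code}: yield factor must be > 0")
        if self.source not in ("FCT", "internet_first_hit", "user"):
            raise ValueError(f"{self.composite_code}: unknown recipe source {self.source!r}")


def to_raw(cooked_g: float, yield_factor: float) -> float:
    """Convert a cooked portion to the raw mass that produced it."""
    if yield_factor <= 0:
        raise ValueError("yield factor must be > 0")
    if cooked_g < 0:
        raise ValueError("cooked mass must be >= 0")
    return cooked_g / yield_factor


def flatten_recipe(
    code: str,
    recipes: Mapping[str, Recipe],
    _pending: frozenset[str] = frozenset(),
) -> dict[str, float]:
    """Expand nested recipes into primary-ingredient raw kg per kg composite.

    An ingredient that is itself a recipe contributes its own flattened
    ingredients scaled by its raw weight in the parent.  Cycles raise.
    """
    if code in _pending:
        raise ValueError(f"cyclic recipe graph at {code!r}")
    recipe = recipes[code]
    pending = _pending | {code}
    flat: dict[str, float] = {}
    for ing in recipe.ingredients:
        if ing.food_code in recipes:
            for sub_code, sub_kg in flatten_recipe(ing.food_code, recipes, pending).items():
                flat[sub_code] = flat.get(sub_code, 0.0) + ing.raw_kg_per_kg * sub_kg
        else:
            flat[ing.food_code] = flat.get(ing.food_code, 0.0) + ing.raw_kg_per_kg
    return flat


def recipe_footprint(recipe: Recipe, footprint_of: Callable[[str], float]) -> float:
    """Indicator value per kg of composite as consumed.

    ``footprint_of`` maps an ingredient code to its per-kg as-consumed
    footprint; resolution failures propagate so unresolvable ingredients are
    reported, never zeroed.
    """
    return sum(ing.raw_kg_per_kg * footprint_of(ing.food_code) for ing in recipe.ingredients)


# -- delimited IO --------------------------------------------------------


def read_recipes(path) -> dict[str, Recipe]:
    """Read recipes from delimited text, one row per composite x ingredient."""
    df = pd.read_csv(path, dtype={"composite_code": str, "ingredient_code": str})
    out: dict[str, Recipe] = {}
    for code, grp in df.groupby("composite_code", sort=True):
        out[str(code)] = Recipe(
            composite_code=str(code),
            ingredients=tuple(
                Ingredient(str(r.ingredient_code), float(r.raw_g_per_kg) / 1000.0)
                for r in grp.itertuples(index=False)
            ),
            yield_factor=float(grp["yield_factor"].iloc[0]),
            source=str(grp["source"].iloc[0]),
        )
    return out


def write_recipes(recipes: Mapping[str, Recipe], path) -> None:
    rows = [
        {
            "composite_code": rec.composite_code,
            "ingredient_code": ing.food_code,
            "raw_g_per_kg": ing.raw_kg_per_kg * 1000.0,
            "yield_factor": rec.yield_factor,
            "source": rec.source,
        }
        for rec in recipes.values()
        for ing in rec.ingredients
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
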