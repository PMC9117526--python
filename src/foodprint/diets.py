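"""Linkage of dietary-intake records to the footprint table.

Each intake record is (person, food code, grams/day).  A person's daily
footprint for one indicator is the intake-weighted sum of per-kg
cradle-to-consumption values.  Intake of foods absent from the footprint
table is excluded and itemized — never silently imputed as zero — and the
report accounts for 100% of intake mass as mapped + unmapped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["IntakeRecord", "PersonFootprints", "person_footprint", "read_intake", "write_intake"]


@dataclass(frozen=True)
class IntakeRecord:
    person_id: str
    food_code: str
    grams_per_day: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.grams_per_day) or self.grams_per_day < 0:
            raise ValueError(f"{self.person_id}/{self.food_code}: bad intake {self.grams_per_day}")


@dataclass
class PersonFootprints:
    """Per-person daily totals plus the unmapped-intake accounting."""

    totals: pd.DataFrame  # person_id, indicator units per day
    unmapped_foods: list[str]
    mapped_mass_pct: float
    unmapped_mass_pct: float


def person_footprint(
    intakes: Sequence[IntakeRecord],
    footprint_table: pd.DataFrame,
    indicator: str,
    group_fallback: pd.DataFrame | None = None,
) -> PersonFootprints:
    """Daily footprint per person for one indicator.

    value = sum over foods of grams/1000 * footprint per kg as consumed.
    ``group_fallback`` (columns food_code, value) optionally substitutes a
    group-mean footprint for unmapped codes; by default they are excluded
    with a warning entry in the report.
    """
    fp = footprint_table[footprint_table["indicator"] == indicator]
    per_kg = dict(zip(fp["food_code"].astype(str), fp["total"].astype(float)))
    if group_fallback is not None:
        for r in group_fallback.itertuples(index=False):
            per_kg.setdefault(str(r.food_code), float(r.value))

    rows = []
    unmapped: set[str] = set()
    mapped_mass = 0.0
    unmapped_mass = 0.0
    persons: dict[str, float] = {}
    for rec in intakes:
        persons.setdefault(rec.person_id, 0.0)
        if rec.food_code in per_kg:
            persons[rec.person_id] += rec.grams_per_day / 1000.0 * per_kg[rec.food_code]
            mapped_mass += rec.grams_per_day
        else:
            unmapped.add(rec.food_code)
            unmapped_mass += rec.grams_per_day
    totals = pd.DataFrame(
        {"person_id": list(persons.keys()), "value": list(persons.values())}
    ).sort_values("person_id", ignore_index=True)
    totals["indicator"] = indicator
    mass = mapped_mass + unmapped_mass
    mapped_pct = 100.0 * mapped_mass / mass if mass > 0 else 100.0
    return PersonFootprints(
        totals=totals,
        unmapped_foods=sorted(unmapped),
        mapped_mass_pct=mapped_pct,
        unmapped_mass_pct=100.0 - mapped_pct,
    )


def read_intake(path) -> list[IntakeRecord]:
    df = pd.read_csv(path, dtype={"person_id": str, "food_code": str})
    return [
        IntakeRecord(str(r.person_id), str(r.food_code), float(r.grams_per_day))
        for r in df.itertuples(index=False)
    ]


def write_intake(intakes: Iterable[IntakeRecord], path) -> None:
    pd.DataFrame(
        [
            {"person_id": r.person_id, "food_code": r.food_code, "grams_per_day": r.grams_per_day}
            for r in intakes
        ]
    ).to_csv(path, index=False)
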