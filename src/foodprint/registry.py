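"""Food registry and parameter tables.

The registry holds the coded food list (food composition table style codes,
17 food groups, edible portions / boneless bases) together with the three
parameter tables that drive the cradle-to-consumption conversion:

* post-farm-gate GHGE stage additions per food type (kg CO2-eq/kg as produced),
* supply-chain loss proportions per food group or commodity,
* boneless-weight conversion ratios for animal species.

Loading validates every invariant and produces a validation report comparing
each table's printed total against the recomputed stage sum, so transcription
or source inconsistencies are flagged instead of silently propagated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "FOOD_GROUPS",
    "ANIMAL_GROUPS",
    "FoodItem",
    "StageParameters",
    "LossProfile",
    "BonelessRatios",
    "ValidationIssue",
    "Registry",
    "load_registry",
    "load_default_tables",
    "normalize_group",
    "boneless_factor",
]

#: The 17 food groups of the database, as named in the food composition table.
FOOD_GROUPS: tuple[str, ...] = (
    "Vegetables",
    "Cereals",
    "Fast foods",
    "Aquatic products",
    "Fruits",
    "Legumes",
    "Meat",
    "Sugars and preserves",
    "Beverages",
    "Liquor and alcohol",
    "Poultry",
    "Dairy",
    "Eggs",
    "Nuts and seeds",
    "Tubers and starches",
    "Fungi and algae",
    "Fats and oils",
)

#: Groups whose items are corrected with boneless ratios instead of an
#: edible-portion fraction (same correction, different mass basis).
ANIMAL_GROUPS = frozenset({"Meat", "Poultry", "Aquatic products"})

_GROUP_ALIASES = {
    "tubers, starches": "Tubers and starches",
    "tubers/starches": "Tubers and starches",
    "tubers": "Tubers and starches",
    "aquatic": "Aquatic products",
    "nuts": "Nuts and seeds",
    "fungi": "Fungi and algae",
}

#: Table rows pool some groups ("Vegetables and fungi", "Fruits and nuts");
#: this maps each registry group to the pooled stage/loss table key.
GROUP_TO_TABLE_KEY: dict[str, str] = {
    "Vegetables": "Vegetables and fungi",
    "Fungi and algae": "Vegetables and fungi",
    "Fruits": "Fruits and nuts",
    "Nuts and seeds": "Fruits and nuts",
    "Tubers and starches": "Tubers, starches",
    "Cereals": "Cereals",
    "Legumes": "Legumes",
    "Aquatic products": "Aquatic products",
    "Meat": "Meat",
    "Dairy": "Dairy",
    "Poultry": "Poultry",
    "Eggs": "Eggs",
    "Beverages": "Beverages",
    "Sugars and preserves": "Sugars and preserves",
    "Liquor and alcohol": "Liquor and alcohol",
    "Fats and oils": "Fats and oils",
    # Fast foods are recipe composites; no direct stage/loss row exists.
}

STAGE_FIELDS = ("processing", "storage", "transportation", "package", "preparation_at_home")
LOSS_FIELDS = ("production", "postharvest", "storage", "processing", "transportation")

#: Absolute tolerance, on the printed scale, for printed-vs-recomputed totals.
PRINTED_TOTAL_TOL = 0.01


def normalize_group(name: str) -> str:
    """Return the canonical group name, accepting common aliases."""
    name = name.strip()
    if name in FOOD_GROUPS:
        return name
    key = name.lower()
    if key in _GROUP_ALIASES:
        return _GROUP_ALIASES[key]
    for g in FOOD_GROUPS:
        if g.lower() == key:
            return g
    raise ValueError(f"unknown food group: {name!r}")


@dataclass(frozen=True)
class FoodItem:
    """One coded entry of the food registry.

    ``edible_portion`` is the eaten fraction of purchased mass for plant
    foods; animal foods instead carry a ``boneless_basis`` (live or carcass)
    and a ``species`` used to look up the boneless conversion ratio.
    """

    code: str
    name: str
    group: str
    edible_portion: float = 1.0
    boneless_basis: str = "none"  # live | carcass | none
    species: str | None = None
    commodity: str | None = None  # loss-table commodity (Rice, Pork, ...)
    provenance: str = "literature"

    def __post_init__(self) -> None:
        object.__setattr__(self, "group", normalize_group(self.group))
        if not (0.0 < self.edible_portion <= 1.0):
            raise ValueError(
                f"{self.code}: edible_portion must be in (0, 1], got {self.edible_portion}"
            )
        if self.boneless_basis not in ("live", "carcass", "none"):
            raise ValueError(f"{self.code}: bad boneless_basis {self.boneless_basis!r}")
        if self.group in ANIMAL_GROUPS and self.boneless_basis == "none":
            raise ValueError(
                f"{self.code}: items in group {self.group!r} must carry a boneless basis"
            )


@dataclass(frozen=True)
class StageParameters:
    """Post-farm-gate GHGE additions for one food type (kg CO2-eq/kg as produced)."""

    key: str
    processing: float | None = None
    storage: float | None = None
    transportation: float | None = None
    package: float | None = None
    preparation_at_home: float | None = None
    printed_total: float | None = None

    def __post_init__(self) -> None:
        for f in STAGE_FIELDS:
            v = getattr(self, f)
            if v is not None and v < 0:
                raise ValueError(f"{self.key}: negative stage value {f}={v}")

    @property
    def stages(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in STAGE_FIELDS if getattr(self, f) is not None}

    @property
    def computed_total(self) -> float | None:
        vals = self.stages
        return sum(vals.values()) if vals else None


@dataclass(frozen=True)
class LossProfile:
    """Supply-chain loss proportions (fractions of produced mass) for one key.

    Stage fields are fractions in [0, 1); ``printed_total`` is the source
    table's total, also as a fraction.  Keys are either food groups or
    commodities (Rice, Wheat, Corn, Pork, Beef, Mutton) nested under a
    ``parent_group``.  Rows carrying only a printed total (Eggs, Beverages,
    Liquor and alcohol) are permitted.
    """

    key: str
    parent_group: str | None = None
    production: float | None = None
    postharvest: float | None = None
    storage: float | None = None
    processing: float | None = None
    transportation: float | None = None
    printed_total: float | None = None

    def __post_init__(self) -> None:
        for f in LOSS_FIELDS:
            v = getattr(self, f)
            if v is not None and not (0.0 <= v < 1.0):
                raise ValueError(f"{self.key}: loss proportion {f}={v} outside [0, 1)")
        ct = self.computed_total
        if ct is not None and ct >= 1.0:
            raise ValueError(f"{self.key}: stage losses sum to {ct} >= 1")

    @property
    def stages(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in LOSS_FIELDS if getattr(self, f) is not None}

    @property
    def computed_total(self) -> float | None:
        vals = self.stages
        return sum(vals.values()) if vals else None


@dataclass(frozen=True)
class BonelessRatios:
    """Boneless-weight mass ratios for one animal species."""

    species: str
    boneless_per_live: float
    boneless_per_carcass: float | None = None

    def __post_init__(self) -> None:
        for r in (self.boneless_per_live, self.boneless_per_carcass):
            if r is not None and not (0.0 < r <= 1.0):
                raise ValueError(f"{self.species}: ratio {r} outside (0, 1]")


@dataclass(frozen=True)
class ValidationIssue:
    """One printed-vs-recomputed total comparison from table validation."""

    table: str
    key: str
    computed_total: float | None
    printed_total: float | None
    delta: float | None
    status: str  # ok | rounding | inconsistent | no_stage_detail

    @property
    def flagged(self) -> bool:
        return self.status in ("rounding", "inconsistent")


def boneless_factor(
    species: str, basis: str, ratios: Mapping[str, BonelessRatios] | None = None
) -> float:
    """Multiplicative factor converting per-kg-as-produced to per-kg-boneless.

    Returns ``1 / ratio`` for the requested mass basis; always >= 1.
    Fish are reported whole, so a carcass basis is invalid for fish.
    """
    if ratios is None:
        ratios = load_default_tables().boneless
    try:
        row = ratios[species.lower()]
    except KeyError:
        raise KeyError(f"unknown species {species!r}") from None
    if basis == "live":
        return 1.0 / row.boneless_per_live
    if basis == "carcass":
        if row.boneless_per_carcass is None:
            raise ValueError(f"no carcass-basis ratio exists for {species!r}")
        return 1.0 / row.boneless_per_carcass
    raise ValueError(f"basis must be 'live' or 'carcass', got {basis!r}")


class Registry:
    """Validated food registry plus parameter tables."""

    def __init__(
        self,
        items: Iterable[FoodItem] = (),
        stage_table: Mapping[str, StageParameters] | None = None,
        loss_table: Mapping[str, LossProfile] | None = None,
        boneless: Mapping[str, BonelessRatios] | None = None,
    ) -> None:
        self.items: dict[str, FoodItem] = {}
        for it in items:
            if it.code in self.items:
                raise ValueError(f"duplicate food code {it.code!r}")
            self.items[it.code] = it
        defaults = None
        if stage_table is None or loss_table is None or boneless is None:
            defaults = load_default_tables()
        self.stage_table = dict(stage_table if stage_table is not None else defaults.stage_table)
        self.loss_table = dict(loss_table if loss_table is not None else defaults.loss_table)
        self.boneless = dict(boneless if boneless is not None else defaults.boneless)

    def __len__(self) -> int:
        return len(self.items)

    def __contains__(self, code: str) -> bool:
        return code in self.items

    def __getitem__(self, code: str) -> FoodItem:
        return self.items[code]

    def group_of(self, code: str) -> str:
        return self.items[code].group

    # -- parameter lookup ------------------------------------------------

    def stage_parameters(self, group: str) -> StageParameters | None:
        """Stage additions for a registry group; None if no table row exists."""
        key = GROUP_TO_TABLE_KEY.get(normalize_group(group))
        return self.stage_table.get(key) if key else None

    def loss_profile(self, group: str, commodity: str | None = None) -> LossProfile | None:
        """Loss profile for a group, with commodity rows taking precedence."""
        if commodity:
            prof = self.loss_table.get(commodity)
            if prof is not None:
                return prof
        key = GROUP_TO_TABLE_KEY.get(normalize_group(group))
        if key and key in self.loss_table:
            return self.loss_table[key]
        return None

    def commodity_profiles(self, group: str) -> list[LossProfile]:
        key = GROUP_TO_TABLE_KEY.get(normalize_group(group))
        return [p for p in self.loss_table.values() if p.parent_group == key]

    def edible_factor(self, code: str) -> float:
        """The >= 1 factor inflating per-produced-kg values to per-eaten-kg.

        Animal items use 1/boneless ratio on their recorded basis; all other
        items use 1/edible_portion.  The two are never combined.
        """
        item = self.items[code]
        if item.group in ANIMAL_GROUPS and item.boneless_basis != "none":
            species = item.species or _default_species(item.group)
            return boneless_factor(species, item.boneless_basis, self.boneless)
        return 1.0 / item.edible_portion

    # -- validation ------------------------------------------------------

    def validate(self, tol: float = PRINTED_TOTAL_TOL) -> list[ValidationIssue]:
        """Compare printed vs recomputed totals for every parameter row.

        Rows whose recomputed stage sum differs from the printed total by
        more than ``tol`` (absolute, on the printed scale: kg CO2-eq/kg for
        stage additions, percentage points for losses) are ``inconsistent``;
        differences within tolerance but nonzero at printed precision are
        ``rounding``; rows with no stage detail are ``no_stage_detail``.
        """
        report: list[ValidationIssue] = []
        for key, sp in self.stage_table.items():
            report.append(_check_totals("stage_ghge", key, sp.computed_total, sp.printed_total, tol))
        for key, lp in self.loss_table.items():
            ct = lp.computed_total
            pt = lp.printed_total
            report.append(
                _check_totals(
                    "loss",
                    key,
                    None if ct is None else 100.0 * ct,
                    None if pt is None else 100.0 * pt,
                    tol,
                )
            )
        return report


def _check_totals(
    table: str, key: str, computed: float | None, printed: float | None, tol: float
) -> ValidationIssue:
    if computed is None or printed is None:
        return ValidationIssue(table, key, computed, printed, None, "no_stage_detail")
    delta = computed - printed
    if abs(delta) <= 1e-12:
        status = "ok"
    elif abs(delta) <= tol + 1e-9:
        status = "rounding"
    else:
        status = "inconsistent"
    return ValidationIssue(table, key, computed, printed, delta, status)


def _default_species(group: str) -> str:
    if group == "Poultry":
        return "chicken"
    if group == "Aquatic products":
        return "fish"
    return "pork"  # dominant meat in the target food supply


# -- table IO ------------------------------------------------------------


@dataclass
class ParameterTables:
    stage_table: dict[str, StageParameters]
    loss_table: dict[str, LossProfile]
    boneless: dict[str, BonelessRatios]
    literature_summary: pd.DataFrame = field(default_factory=pd.DataFrame)


def _opt(v) -> float | None:
    return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)


def read_stage_table(path) -> dict[str, StageParameters]:
    df = pd.read_csv(path)
    out = {}
    for _, r in df.iterrows():
        sp = StageParameters(
            key=str(r["food_type"]),
            **{f: _opt(r[f]) for f in STAGE_FIELDS},
            printed_total=_opt(r.get("printed_total")),
        )
        if sp.key in out:
            raise ValueError(f"duplicate stage row {sp.key!r}")
        out[sp.key] = sp
    return out


def read_loss_table(path) -> dict[str, LossProfile]:
    """Read the loss table; file values are percentages, stored as fractions."""
    df = pd.read_csv(path)
    out = {}
    for _, r in df.iterrows():
        pg = r.get("parent_group")
        lp = LossProfile(
            key=str(r["key"]),
            parent_group=None if pd.isna(pg) else str(pg),
            **{f: _pct(r[f]) for f in LOSS_FIELDS},
            printed_total=_pct(r.get("printed_total")),
        )
        if lp.key in out:
            raise ValueError(f"duplicate loss row {lp.key!r}")
        out[lp.key] = lp
    return out


def _pct(v) -> float | None:
    v = _opt(v)
    return None if v is None else v / 100.0


def read_boneless_table(path) -> dict[str, BonelessRatios]:
    df = pd.read_csv(path)
    return {
        str(r["species"]).lower(): BonelessRatios(
            species=str(r["species"]).lower(),
            boneless_per_live=float(r["boneless_per_live"]),
            boneless_per_carcass=_opt(r["boneless_per_carcass"]),
        )
        for _, r in df.iterrows()
    }


def _data_path(name: str):
    return resources.files("foodprint.data") / name


def load_default_tables() -> ParameterTables:
    """Load the packaged parameter tables (stage additions, losses, ratios)."""
    return ParameterTables(
        stage_table=read_stage_table(_data_path("stage_ghge.csv")),
        loss_table=read_loss_table(_data_path("loss_proportions.csv")),
        boneless=read_boneless_table(_data_path("boneless_ratios.csv")),
        literature_summary=pd.read_csv(_data_path("literature_summary.csv")),
    )


def read_registry_items(path) -> list[FoodItem]:
    df = pd.read_csv(path, dtype={"code": str})
    items = []
    for _, r in df.iterrows():
        items.append(
            FoodItem(
                code=str(r["code"]),
                name=str(r["name"]),
                group=str(r["group"]),
                edible_portion=float(r.get("edible_portion", 1.0) if not pd.isna(r.get("edible_portion")) else 1.0),
                boneless_basis=str(r["boneless_basis"]) if not pd.isna(r.get("boneless_basis")) else "none",
                species=None if pd.isna(r.get("species")) else str(r["species"]),
                commodity=None if pd.isna(r.get("commodity")) else str(r["commodity"]),
                provenance=str(r["provenance"]) if not pd.isna(r.get("provenance")) else "literature",
            )
        )
    return items


def write_registry_items(registry: Registry, path) -> None:
    rows = [
        {
            "code": it.code,
            "name": it.name,
            "group": it.group,
            "edible_portion": it.edible_portion,
            "boneless_basis": it.boneless_basis,
            "species": it.species,
            "commodity": it.commodity,
            "provenance": it.provenance,
        }
        for it in registry.items.values()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_registry(
    items_path: str | Path | None = None,
    stage_path: str | Path | None = None,
    loss_path: str | Path | None = None,
    boneless_path: str | Path | None = None,
) -> Registry:
    """Build a validated :class:`Registry` from delimited files.

    Any path left as None falls back to the packaged default table; an
    items_path of None yields an empty item list (tables-only registry).
    """
    defaults = load_default_tables()
    return Registry(
        items=read_registry_items(items_path) if items_path else (),
        stage_table=read_stage_table(stage_path) if stage_path else defaults.stage_table,
        loss_table=read_loss_table(loss_path) if loss_path else defaults.loss_table,
        boneless=read_boneless_table(boneless_path) if boneless_path else defaults.boneless,
    )
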