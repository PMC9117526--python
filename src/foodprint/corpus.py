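"""Literature corpus: screening and summary statistics.

One :class:`LCARecord` is a single published observation of one indicator
(GHGE in kg CO2-eq/kg, water use in m3/kg, land use in m2/kg) for one coded
food at a stated system boundary.  ``screen`` applies the inclusion rules
(publication window 2005-2020, a stated boundary of at least
cradle-to-farm-gate); ``summarize`` aggregates kept records into per-group
counts, means and standard deviations plus per-item means.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .registry import Registry

__all__ = ["INDICATORS", "LCARecord", "Rejection", "screen", "summarize", "records_to_frame", "frame_to_records"]

INDICATORS = ("GHGE", "WU", "LU")
INDICATOR_UNITS = {"GHGE": "kg CO2-eq/kg", "WU": "m3/kg", "LU": "m2/kg"}

YEAR_MIN, YEAR_MAX = 2005, 2020

BOUNDARIES = ("cradle_to_farm_gate", "cradle_to_processing", "other")
METHODS = ("process", "EIO", "hybrid", "unknown")
WEIGHT_BASES = ("live", "carcass", "edible", "as_purchased")


@dataclass(frozen=True)
class LCARecord:
    food_code: str
    indicator: str
    value: float
    year: int
    boundary: str
    method: str = "unknown"
    weight_basis: str = "as_purchased"
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.indicator not in INDICATORS:
            raise ValueError(f"indicator must be one of {INDICATORS}, got {self.indicator!r}")
        if self.boundary not in BOUNDARIES:
            raise ValueError(f"boundary must be one of {BOUNDARIES}, got {self.boundary!r}")
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")


@dataclass(frozen=True)
class Rejection:
    record: LCARecord
    reason: str


def screen(records: Iterable[LCARecord]) -> tuple[list[LCARecord], list[Rejection]]:
    """Apply the inclusion screen; never hard-fails.

    Rules: publication year within [2005, 2020]; a stated system boundary
    (records tagged ``other`` had none and are dropped); non-negative value
    in the indicator's unit.  Every rejection carries a machine-readable
    reason so screening decisions are auditable.
    """
    kept: list[LCARecord] = []
    rejected: list[Rejection] = []
    for r in records:
        if r.boundary == "other":
            rejected.append(Rejection(r, "no_system_boundary"))
        elif not (YEAR_MIN <= r.year <= YEAR_MAX):
            rejected.append(Rejection(r, "year_out_of_range"))
        elif not np.isfinite(r.value) or r.value < 0:
            rejected.append(Rejection(r, "invalid_value"))
        else:
            kept.append(r)
    return kept, rejected


def summarize(
    records: Sequence[LCARecord],
    registry: Registry,
    across: str = "values",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group summary statistics and per-item means.

    Counts per (group, indicator): ``n_items`` distinct food codes,
    ``n_studies`` distinct source ids, ``n_values`` record count.  The group
    mean/stdev are unweighted across individual values (``across="values"``,
    the default) or across item-level means (``across="items"``); stdev uses
    the n-1 sample denominator and is NaN for a single observation.

    Raises KeyError listing every food code not resolvable to a group.
    """
    if across not in ("values", "items"):
        raise ValueError("across must be 'values' or 'items'")
    unresolved = sorted({r.food_code for r in records if r.food_code not in registry})
    if unresolved:
        raise KeyError(f"food codes not in registry: {unresolved}")

    df = records_to_frame(records)
    if df.empty:
        empty_g = pd.DataFrame(
            columns=["group", "indicator", "n_items", "n_studies", "n_values", "mean", "stdev"]
        )
        empty_i = pd.DataFrame(columns=["food_code", "group", "indicator", "n_values", "mean"])
        return empty_g, empty_i
    df["group"] = df["food_code"].map(lambda c: registry.group_of(c))

    item = (
        df.groupby(["group", "food_code", "indicator"], sort=True)["value"]
        .agg(n_values="size", mean="mean")
        .reset_index()
    )

    basis = df if across == "values" else item.rename(columns={"mean": "value"})
    stats = (
        basis.groupby(["group", "indicator"], sort=True)["value"]
        .agg(mean="mean", stdev=lambda v: v.std(ddof=1))
        .reset_index()
    )
    counts = (
        df.groupby(["group", "indicator"], sort=True)
        .agg(
            n_items=("food_code", "nunique"),
            n_studies=("source_id", "nunique"),
            n_values=("value", "size"),
        )
        .reset_index()
    )
    group = counts.merge(stats, on=["group", "indicator"])
    return group, item


def records_to_frame(records: Iterable[LCARecord]) -> pd.DataFrame:
    rows = [asdict(r) for r in records]
    if not rows:
        return pd.DataFrame(
            columns=["food_code", "indicator", "value", "year", "boundary", "method", "weight_basis", "source_id"]
        )
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> list[LCARecord]:
    return [
        LCARecord(
            food_code=str(r.food_code),
            indicator=str(r.indicator),
            value=float(r.value),
            year=int(r.year),
            boundary=str(r.boundary),
            method=str(getattr(r, "method", "unknown")),
            weight_basis=str(getattr(r, "weight_basis", "as_purchased")),
            source_id=str(getattr(r, "source_id", "")),
        )
        for r in df.itertuples(index=False)
    ]
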