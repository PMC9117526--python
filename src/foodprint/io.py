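"""Delimited-text and workbook IO plus the two end-to-end workflows.

Canonical formats are UTF-8 delimited text (diff-able and testable); the
three-indicator database can additionally be read from or written to an
xlsx workbook with one sheet per indicator and the columns
reference/source, year, data type, LCA method, food code, food item,
food group, value.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from .corpus import INDICATORS, LCARecord, frame_to_records, records_to_frame, screen, summarize
from .footprint import build_footprint_table, provenance_counts
from .recipes import Recipe
from .registry import Registry

__all__ = [
    "read_corpus",
    "write_corpus",
    "read_workbook_corpus",
    "write_database",
    "write_database_workbook",
    "build_database",
    "BuildResult",
]

DATABASE_COLUMNS = [
    "reference", "year", "data_type", "lca_method",
    "food_code", "food_item", "food_group", "value",
]


def read_corpus(path) -> list[LCARecord]:
    df = pd.read_csv(path, dtype={"food_code": str, "source_id": str})
    records = []
    for i in range(len(df)):
        try:
            records.extend(frame_to_records(df.iloc[[i]]))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: corrupt corpus row {i + 2}: {exc}") from exc
    return records


def write_corpus(records, path) -> None:
    records_to_frame(records).to_csv(path, index=False, encoding="utf-8")


def read_workbook_corpus(path) -> list[LCARecord]:
    """Read literature records from a three-sheet xlsx workbook.

    Expects one sheet per indicator named GHGE/WU/LU with at least food
    code, value, year and reference columns; missing boundary/method
    columns default to cradle-to-farm-gate / unknown.
    """
    records: list[LCARecord] = []
    sheets = pd.read_excel(path, sheet_name=None, dtype={"food_code": str})
    for name, df in sheets.items():
        ind = name.strip().upper()
        if ind not in INDICATORS:
            continue
        df = df.rename(columns=lambda c: str(c).strip().lower().replace(" ", "_"))
        for r in df.itertuples(index=False):
            records.append(
                LCARecord(
                    food_code=str(r.food_code),
                    indicator=ind,
                    value=float(r.value),
                    year=int(r.year),
                    boundary=str(getattr(r, "boundary", "cradle_to_farm_gate")),
                    method=str(getattr(r, "lca_method", "unknown")),
                    source_id=str(getattr(r, "reference", "")),
                )
            )
    return records


def _database_frames(table: pd.DataFrame, registry: Registry) -> dict[str, pd.DataFrame]:
    frames = {}
    for ind in INDICATORS:
        sub = table[table["indicator"] == ind]
        frames[ind] = pd.DataFrame(
            {
                "reference": sub["provenance"],
                "year": pd.NA,
                "data_type": sub["provenance"],
                "lca_method": "process",
                "food_code": sub["food_code"],
                "food_item": sub["food_name"],
                "food_group": sub["group"],
                "value": sub["total"],
            },
            columns=DATABASE_COLUMNS,
        ).reset_index(drop=True)
    return frames


def write_database(table: pd.DataFrame, registry: Registry, out_dir) -> dict[str, Path]:
    """Write one delimited table per indicator in the workbook-sheet layout."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for ind, frame in _database_frames(table, registry).items():
        p = out_dir / f"database_{ind.lower()}.csv"
        frame.to_csv(p, index=False, encoding="utf-8")
        paths[ind] = p
    return paths


def write_database_workbook(table: pd.DataFrame, registry: Registry, path) -> None:
    """Optional xlsx emission: one sheet per indicator."""
    with pd.ExcelWriter(path, engine="openpyxl") as xl:
        for ind, frame in _database_frames(table, registry).items():
            frame.to_excel(xl, sheet_name=ind, index=False)


class BuildResult:
    """Everything the build workflow produces, kept for inspection."""

    def __init__(self, table, unmapped, group_summary, item_means, validation, rejections):
        self.table = table
        self.unmapped = unmapped
        self.group_summary = group_summary
        self.item_means = item_means
        self.validation = validation
        self.rejections = rejections

    @property
    def provenance_breakdown(self) -> pd.DataFrame:
        return provenance_counts(self.table)


def build_database(
    records,
    registry: Registry,
    recipes: Mapping[str, Recipe] | None = None,
    mapping: Mapping[str, str] | None = None,
    processed_map: Mapping[str, str] | None = None,
    totals: str = "computed",
    loss_mode: str = "additive",
    across: str = "values",
) -> BuildResult:
    """Screen a corpus, summarize it, and assemble the footprint database."""
    kept, rejections = screen(records)
    group_summary, item_means = summarize(kept, registry, across=across)
    table, unmapped = build_footprint_table(
        registry,
        item_means.rename(columns={"mean": "mean"}),
        group_summary,
        recipes=recipes,
        mapping=mapping,
        processed_map=processed_map,
        totals=totals,
        loss_mode=loss_mode,
    )
    return BuildResult(table, unmapped, group_summary, item_means, registry.validate(), rejections)
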