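"""Registry, parameter tables and conversion-ratio lookups."""

import math

import pytest

import foodprint as fp
from foodprint.registry import (
    FOOD_GROUPS,
    BonelessRatios,
    FoodItem,
    LossProfile,
    Registry,
    StageParameters,
    boneless_factor,
    normalize_group,
    read_registry_items,
    write_registry_items,
)


class TestFoodItem:
    def test_group_names_are_unique(self):
        assert len(set(FOOD_GROUPS)) == len(FOOD_GROUPS)

    def test_aliases_normalize(self):
        assert normalize_group("Tubers, starches") == "Tubers and starches"
        assert normalize_group("Tubers/starches") == "Tubers and starches"
        with pytest.raises(ValueError, match="unknown food group"):
            normalize_group("Snacks")

    def test_edible_portion_bounds(self):
        with pytest.raises(ValueError, match="edible_portion"):
            FoodItem("x1", "bad", "Vegetables", edible_portion=0.0)
        with pytest.raises(ValueError, match="edible_portion"):
            FoodItem("x1", "bad", "Vegetables", edible_portion=1.2)

    def test_animal_items_need_boneless_basis(self):
        with pytest.raises(ValueError, match="boneless basis"):
            FoodItem("m1", "pork cut", "Meat")
        # allowed when basis stated
        FoodItem("m1", "pork cut", "Meat", boneless_basis="live", species="pork")

    def test_duplicate_codes_rejected(self):
        items = [
            FoodItem("v1", "cabbage", "Vegetables"),
            FoodItem("v1", "spinach", "Vegetables"),
        ]
        with pytest.raises(ValueError, match="duplicate food code"):
            Registry(items)


class TestParameterTables:
    def test_cereals_stage_sum_matches_printed_total(self, tables):
        sp = tables.stage_table["Cereals"]
        assert sp.computed_total == pytest.approx(sp.printed_total, abs=1e-12)

    def test_meat_row_flagged_not_rejected(self, registry_tables_only):
        """Inconsistent printed totals are reported, not hard errors."""
        sp = registry_tables_only.stage_table["Meat"]
        assert sp.computed_total == pytest.approx(0.300)
        assert sp.printed_total == pytest.approx(0.603)
        report = {(i.table, i.key): i for i in registry_tables_only.validate()}
        assert report[("stage_ghge", "Meat")].status == "inconsistent"

    def test_printed_only_loss_rows_accepted(self, tables):
        eggs = tables.loss_table["Eggs"]
        assert eggs.computed_total is None
        assert eggs.printed_total == pytest.approx(0.105)

    def test_negative_stage_value_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            StageParameters("bad", storage=-0.01)

    def test_loss_stage_sum_must_stay_below_one(self):
        with pytest.raises(ValueError, match=">= 1"):
            LossProfile("bad", production=0.6, storage=0.5)

    def test_validation_tolerance_classes(self, registry_tables_only):
        """Within-0.01 rounding differences never escalate to inconsistent."""
        report = {(i.table, i.key): i for i in registry_tables_only.validate()}
        assert report[("loss", "Vegetables and fungi")].status == "rounding"
        assert report[("loss", "Corn")].status == "rounding"
        assert report[("loss", "Rice")].status == "ok"


class TestBonelessFactor:
    @pytest.mark.parametrize(
        "species,basis,expected",
        [
            ("pork", "live", 1 / 0.43),
            ("chicken", "carcass", 1 / 0.75),
            ("sheep", "live", 1 / 0.33),
            ("beef", "carcass", 1 / 0.83),
            ("fish", "live", 1 / 0.54),
        ],
    )
    def test_factor_is_inverse_ratio(self, tables, species, basis, expected):
        assert boneless_factor(species, basis, tables.boneless) == pytest.approx(expected)

    def test_factor_at_least_one(self, tables):
        for sp in tables.boneless.values():
            assert boneless_factor(sp.species, "live", tables.boneless) >= 1.0

    def test_ratio_one_gives_identity(self):
        ratios = {"ideal": BonelessRatios("ideal", 1.0, 1.0)}
        assert boneless_factor("ideal", "live", ratios) == 1.0

    def test_fish_has_no_carcass_basis(self, tables):
        with pytest.raises(ValueError, match="carcass"):
            boneless_factor("fish", "carcass", tables.boneless)

    def test_unknown_species(self, tables):
        with pytest.raises(KeyError):
            boneless_factor("yak", "live", tables.boneless)

    def test_monotone_decreasing_in_ratio(self):
        ratios = {
            f"s{i}": BonelessRatios(f"s{i}", r) for i, r in enumerate([0.2, 0.4, 0.6, 0.8, 1.0])
        }
        factors = [boneless_factor(s, "live", ratios) for s in sorted(ratios)]
        assert factors == sorted(factors, reverse=True)


class TestRoundTrip:
    def test_registry_round_trips_through_csv(self, tmp_path, synth_registry):
        path = tmp_path / "registry.csv"
        write_registry_items(synth_registry, path)
        reloaded = Registry(read_registry_items(path))
        assert set(reloaded.items) == set(synth_registry.items)
        for code, item in synth_registry.items.items():
            back = reloaded[code]
            assert back.group == item.group
            assert math.isclose(back.edible_portion, item.edible_portion)
            assert back.boneless_basis == item.boneless_basis
            assert back.commodity == item.commodity

    def test_chinese_names_round_trip(self, tmp_path):
        reg = Registry([FoodItem("011101", "小麦粉", "Cereals", commodity="Wheat")])
        path = tmp_path / "reg.csv"
        write_registry_items(reg, path)
        assert Registry(read_registry_items(path))["011101"].name == "小麦粉"


class TestEdibleFactor:
    def test_plant_items_use_edible_portion(self):
        reg = Registry([FoodItem("v1", "apple", "Fruits", edible_portion=0.8)])
        assert reg.edible_factor("v1") == pytest.approx(1.25)

    def test_animal_items_use_boneless_ratio_not_edible_portion(self):
        item = FoodItem(
            "m1", "pork", "Meat", edible_portion=0.5, boneless_basis="live", species="pork"
        )
        reg = Registry([item])
        # 1/0.43 from the ratio table; the edible_portion column is ignored
        assert reg.edible_factor("m1") == pytest.approx(1 / 0.43)

    def test_commodity_loss_precedence(self, synth_registry):
        prof = synth_registry.loss_profile("Cereals", commodity="Rice")
        assert prof.key == "Rice"
        pooled = synth_registry.loss_profile("Vegetables")
        assert pooled.key == "Vegetables and fungi"
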