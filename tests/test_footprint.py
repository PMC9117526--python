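"""Loss cascade, cradle-to-consumption formula, proxy and direct mapping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import foodprint as fp
from foodprint.footprint import (
    DEFAULT_PROXY_RULES,
    UnmappedError,
    direct_map,
    impute_proxy,
    loss_total,
    provenance_counts,
    proxy_donor,
    resolve_mapping,
    total_footprint,
)
from foodprint.registry import FoodItem, LossProfile, Registry


class TestLossTotal:
    def test_commodity_totals(self, tables):
        assert loss_total(tables.loss_table["Rice"]) == pytest.approx(0.1522)
        assert loss_total(tables.loss_table["Pork"]) == pytest.approx(0.1486)

    def test_printed_only_row(self, tables):
        assert loss_total(tables.loss_table["Eggs"]) == pytest.approx(0.105)

    def test_all_zero_profile(self):
        prof = LossProfile("none", production=0.0, storage=0.0)
        assert loss_total(prof) == 0.0

    def test_no_information_at_all(self):
        with pytest.raises(ValueError, match="no loss information"):
            loss_total(LossProfile("empty"))

    def test_multiplicative_mode_is_smaller(self, tables):
        for key in ("Rice", "Pork", "Vegetables and fungi"):
            prof = tables.loss_table[key]
            assert loss_total(prof, "multiplicative") < loss_total(prof, "additive")

    @given(st.lists(st.floats(0.0, 0.15), min_size=2, max_size=5))
    def test_multiplicative_matches_survival_product(self, losses):
        fields = ["production", "postharvest", "storage", "processing", "transportation"]
        prof = LossProfile("p", **dict(zip(fields, losses)))
        expect = 1.0 - np.prod([1.0 - l for l in losses])
        assert loss_total(prof, "multiplicative") == pytest.approx(expect, rel=1e-12)


class TestTotalFootprint:
    def test_rice_like_hand_oracle(self):
        """1.0 at farm gate, 15.22% loss, 0.184 stage add -> 1.3635."""
        res = total_footprint(1.0, "GHGE", edible_factor=1.0, loss=0.1522, stage_addition=0.184)
        assert res.total == pytest.approx(1.0 / (1 - 0.1522) + 0.184, rel=1e-12)
        assert res.total == pytest.approx(1.3635, abs=5e-5)

    def test_identity_when_no_corrections(self):
        assert total_footprint(2.5, "GHGE").total == pytest.approx(2.5)

    def test_water_use_never_gets_stage_additions(self):
        res = total_footprint(2.0, "WU", edible_factor=1.25, loss=0.2, stage_addition=0.184)
        assert res.stage_addition == 0.0
        assert res.total == pytest.approx(2.0 * 1.25 * 1.25, rel=1e-12)
        assert "stage_addition_forced_zero_for_non_ghge" in res.trail

    def test_loss_at_or_above_one_rejected(self):
        with pytest.raises(ValueError, match="loss"):
            total_footprint(1.0, "GHGE", loss=1.0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            total_footprint(-1.0, "GHGE")
        with pytest.raises(ValueError):
            total_footprint(1.0, "GHGE", stage_addition=-0.1)

    @given(
        farm=st.floats(0.01, 50),
        edible=st.floats(1.0, 3.0),
        loss=st.floats(0.0, 0.6),
        stage=st.floats(0.0, 1.0),
        bump=st.floats(0.01, 0.3),
    )
    def test_strictly_increasing_in_every_argument(self, farm, edible, loss, stage, bump):
        base = total_footprint(farm, "GHGE", edible, loss, stage).total
        assert total_footprint(farm + bump, "GHGE", edible, loss, stage).total > base
        assert total_footprint(farm, "GHGE", edible + bump, loss, stage).total > base
        assert total_footprint(farm, "GHGE", edible, min(0.99, loss + bump), stage).total > base
        assert total_footprint(farm, "GHGE", edible, loss, stage + bump).total > base

    def test_indicators_share_multiplicative_core(self):
        for ind in ("GHGE", "WU", "LU"):
            res = total_footprint(3.0, ind, edible_factor=1.5, loss=0.25)
            assert res.total == pytest.approx(3.0 * 1.5 / 0.75, rel=1e-12)


class TestProxy:
    def test_tubers_and_nuts_land_use_donors(self, tables):
        summaries = tables.literature_summary
        donor = proxy_donor("Tubers and starches", "LU")
        mean = summaries.query("group == @donor and indicator == 'LU'")["mean"].iloc[0]
        assert donor == "Vegetables" and mean == pytest.approx(0.402)
        donor = proxy_donor("Nuts and seeds", "LU")
        mean = summaries.query("group == @donor and indicator == 'LU'")["mean"].iloc[0]
        assert donor == "Fruits" and mean == pytest.approx(0.640)

    def test_imputed_result_carries_donor_provenance(self, tables):
        reg = Registry([FoodItem("t1", "potato", "Tubers and starches", edible_portion=0.9)])
        res = impute_proxy(reg["t1"], reg, tables.literature_summary, "LU")
        assert res.provenance == "proxy"
        assert res.farm_gate_value == pytest.approx(0.402)
        assert any("proxy_donor=Vegetables" in t for t in res.trail)

    def test_proxy_refused_when_literature_exists(self, tables):
        reg = Registry([FoodItem("t1", "potato", "Tubers and starches")])
        with pytest.raises(ValueError, match="refused"):
            impute_proxy(reg["t1"], reg, tables.literature_summary, "LU", has_literature=True)

    def test_missing_rule_is_explicit_unmapped(self):
        with pytest.raises(UnmappedError):
            proxy_donor("Beverages", "LU", rules=DEFAULT_PROXY_RULES)


class TestDirectMapping:
    def test_variant_copies_value_with_new_provenance(self):
        base = total_footprint(1.8, "GHGE", food_code="wheat-flour")
        variant = direct_map(base, "wheat-flour-special-grade-1")
        assert variant.total == base.total
        assert variant.provenance == "direct_mapping"
        assert variant.food_code == "wheat-flour-special-grade-1"

    def test_identity_and_chain_resolution(self):
        mapping = {"a": "b", "b": "c"}
        assert resolve_mapping("c", mapping) == "c"
        assert resolve_mapping("a", mapping) == resolve_mapping("b", mapping) == "c"

    def test_cyclic_mapping_rejected(self):
        with pytest.raises(ValueError, match="cyclic"):
            resolve_mapping("a", {"a": "b", "b": "a"})


class TestOracleEquivalence:
    def test_thousand_random_draws_match_one_line_formula(self):
        rng = np.random.default_rng(20240917)
        for _ in range(1000):
            farm = rng.uniform(0.01, 20)
            edible = rng.uniform(1.0, 2.5)
            loss = rng.uniform(0.0, 0.6)
            stage = rng.uniform(0.0, 0.8)
            expect = farm * edible / (1.0 - loss) + stage  # independent one-liner
            got = total_footprint(farm, "GHGE", edible, loss, stage).total
            assert got == pytest.approx(expect, rel=1e-12)


class TestBuildTable:
    def test_provenance_counts_sum_to_total(self, synth_registry, synth_corpus, synth_recipes):
        kept, _ = fp.screen(synth_corpus)
        group, items = fp.summarize(kept, synth_registry)
        table, unmapped = fp.build_footprint_table(synth_registry, items, group, recipes=synth_recipes)
        counts = provenance_counts(table)
        parts = counts[["literature", "direct_mapping", "processing", "recipe", "proxy"]].sum(axis=1)
        assert (parts == counts["total"]).all()
        assert counts["total"].sum() == len(table)
        # nothing is both mapped and unmapped
        mapped = {(r.food_code, r.indicator) for r in table.itertuples(index=False)}
        assert all(tuple(u.split(":")) not in mapped for u in unmapped)

    def test_direct_mapping_inherits_base_total(self, synth_registry, synth_corpus):
        kept, _ = fp.screen(synth_corpus)
        group, items = fp.summarize(kept, synth_registry)
        base_code = items["food_code"].iloc[0]
        reg = Registry(
            list(synth_registry.items.values())
            + [FoodItem("variant1", "variant", synth_registry[base_code].group,
                        edible_portion=synth_registry[base_code].edible_portion,
                        boneless_basis=synth_registry[base_code].boneless_basis,
                        species=synth_registry[base_code].species)]
        )
        table, _ = fp.build_footprint_table(reg, items, group, mapping={"variant1": base_code})
        t = table.set_index(["food_code", "indicator"])["total"]
        for ind in fp.INDICATORS:
            if (base_code, ind) in t.index:
                assert t[("variant1", ind)] == pytest.approx(t[(base_code, ind)])
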