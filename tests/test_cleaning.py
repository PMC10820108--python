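"""Deduplication, dual-label averaging, imputation and screening rules."""

from datetime import date

import pytest

from snackprofiler.cleaning import (
    CleaningConfig,
    average_dual_labels,
    clean,
    dedupe,
    filter_complete,
    impute_censored,
    normalize_serving,
)
from snackprofiler.gnpd_io import CodedValue, ProductRecord


def rec(record_id="R1", brand="B", name="Dried Apple", **kwargs):
    return ProductRecord(record_id=record_id, brand=brand, name=name, **kwargs)


class TestDedupe:
    def test_exact_duplicates_keep_first(self):
        records = [rec("A"), rec("A"), rec("B")]
        kept, removed = dedupe(records)
        assert [r.record_id for r in kept] == ["A", "B"] and removed == 1

    def test_distinct_records_untouched(self):
        kept, removed = dedupe([rec("A"), rec("B", name="Dried Pear")])
        assert len(kept) == 2 and removed == 0

    def test_triplicate_removes_two(self):
        kept, removed = dedupe([rec("A")] * 3)
        assert len(kept) == 1 and removed == 2


class TestDualLabelAveraging:
    def test_mean_of_two_panels(self):
        a = rec("A", panel={"energy": CodedValue.numeric(100.0)})
        b = rec("B", panel={"energy": CodedValue.numeric(120.0)})
        merged = average_dual_labels([a, b])
        assert merged.panel["energy"] == CodedValue.numeric(110.0)
        assert merged.record_id == "A"  # metadata from first record

    def test_single_panel_identity(self):
        a = rec("A", panel={"energy": CodedValue.numeric(90.0)})
        assert average_dual_labels([a]).panel["energy"] == a.panel["energy"]

    def test_missing_in_any_panel_propagates(self):
        a = rec("A", panel={"added_sugar": CodedValue.numeric(5.0)})
        b = rec("B", panel={"added_sugar": CodedValue.missing()})
        assert average_dual_labels([a, b]).panel["added_sugar"].is_missing

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            average_dual_labels([])


class TestImputation:
    def test_fiber_below_one_uses_printed_percent_dv(self):
        r = rec(panel={"fiber": CodedValue.censored(1.0, "<1")}, percent_dv={"fiber": 3.0})
        out = impute_censored(r)
        assert out.panel["fiber"].value == pytest.approx(0.84)  # 3% of 28 g

    def test_fiber_below_one_without_dv_falls_back_to_half_bound(self):
        r = rec(panel={"fiber": CodedValue.censored(1.0, "<1")})
        assert impute_censored(r).panel["fiber"].value == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "nutrient,cell,expected",
        [
            ("saturated_fat", "<0.1", 0.1),
            ("sodium", "<5", 5.0),
            ("cholesterol", "<5", 5.0),
            ("protein", "<1", 0.75),
            ("fiber", "<2", 1.0),  # unenumerated code: bound/2
        ],
    )
    def test_enumerated_substitutions(self, nutrient, cell, expected):
        from snackprofiler.gnpd_io import parse_coded_cell

        r = rec(panel={nutrient: parse_coded_cell(cell, nutrient)})
        assert impute_censored(r).panel[nutrient].value == pytest.approx(expected)

    def test_numeric_and_missing_untouched(self):
        r = rec(panel={"fiber": CodedValue.numeric(2.0), "added_sugar": CodedValue.missing()})
        out = impute_censored(r)
        assert out.panel["fiber"] == CodedValue.numeric(2.0)
        assert out.panel["added_sugar"].is_missing


class TestFilterComplete:
    def test_missing_required_nutrient_removes_record(self):
        r = rec(panel={"vitamin_d": CodedValue.missing()})
        kept, removed = filter_complete([r])
        assert kept == [] and removed == 1

    def test_zero_is_a_value(self):
        r = rec(
            panel={
                n: CodedValue.numeric(0.0)
                for n in ("added_sugar", "vitamin_d", "calcium", "iron")
            }
        )
        kept, removed = filter_complete([r])
        assert len(kept) == 1 and removed == 0

    def test_empty_input(self):
        assert filter_complete([]) == ([], 0)


class TestServingNormalization:
    def test_gram_field_passthrough(self):
        assert normalize_serving(rec(serving_g=40.0)).serving_g == 40.0

    def test_parse_from_text(self):
        assert normalize_serving(rec(serving_size_text="30 g")).serving_g == 30.0

    def test_unparseable_text_flags_exclusion(self):
        assert normalize_serving(rec(serving_size_text="1 pouch")) is None


class TestFullPass:
    def _records(self):
        shared = dict(
            panel={
                "energy": CodedValue.numeric(100.0),
                "added_sugar": CodedValue.numeric(5.0),
                "vitamin_d": CodedValue.numeric(0.0),
                "calcium": CodedValue.numeric(20.0),
                "iron": CodedValue.numeric(0.5),
            },
            serving_g=40.0,
            launch_date=date(2020, 1, 1),
        )
        a = rec("A", **shared)
        a_dup = rec("A", **{**shared})
        b1 = rec("B1", name="Dried Pear", **shared)
        b2 = rec("B2", name="Dried Pear", **shared)  # dual label of b1
        c = rec("C", name="Dried Fig", panel={}, serving_g=40.0)  # no label
        d = rec(
            "D", name="Dried Plum",
            panel={**shared["panel"], "vitamin_d": CodedValue.missing()},
            serving_g=40.0,
        )
        return [a, a_dup, b1, b2, c, d]

    def test_ledger_counts_and_conservation(self):
        result = clean(self._records())
        ledger = {s.label: s.n_removed for s in result.ledger.steps}
        assert ledger["no_nutrition_label"] == 1
        assert ledger["duplicate"] == 2  # exact duplicate + dual-label collapse
        assert ledger["missing_new_label_nutrients"] == 1
        result.ledger.check_conservation()
        assert {r.record_id for r in result.records} == {"A", "B1"}

    def test_idempotence(self):
        once = clean(self._records())
        twice = clean(once.records)
        assert len(twice.records) == len(once.records)
        for r1, r2 in zip(once.records, twice.records):
            assert r1.record_id == r2.record_id
            assert r1.panel == r2.panel
        assert all(s.n_removed == 0 for s in twice.ledger.steps)

    def test_imputation_preserves_states(self):
        r = rec(
            panel={
                "fiber": CodedValue.censored(1.0, "<1"),
                "added_sugar": CodedValue.missing(),
                "energy": CodedValue.numeric(120.0),
            },
            percent_dv={"fiber": 7.0},
        )
        out = impute_censored(r)
        assert out.panel["fiber"].is_numeric  # censored resolved
        assert out.panel["added_sugar"].is_missing  # missing never invented
        assert out.panel["energy"] == CodedValue.numeric(120.0)


class TestCleaningConfig:
    def test_nonpositive_constant_rejected(self):
        with pytest.raises(ValueError):
            CleaningConfig(fiber_dv_g=0)

    def test_empty_required_rejected(self):
        with pytest.raises(ValueError):
            CleaningConfig(required_nutrients=())
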