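"""Data model: CSV I/O, scaling, filters, missing-property handling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sussol.errors import (
    DegenerateDataError,
    MissingDataError,
    ParseError,
    SchemaError,
)
from sussol.schema import PROPERTY_NAMES
from sussol.synthetic import BlobSpec, inject_missing, make_blob_table
from sussol.table import (
    FilterCriterion,
    SolventRecord,
    SolventTable,
    apply_filters,
    feature_matrix,
    read_solvent_table,
    select_feature_columns,
    write_solvent_table,
)

from conftest import make_csv


class TestReadWrite:
    def test_full_schema_fixture(self, three_solvent_table):
        table = three_solvent_table
        assert len(table) == 3
        assert len(PROPERTY_NAMES) == 22
        for rec in table:
            assert sum(rec.has(p) for p in PROPERTY_NAMES) == 22
        assert table.get("heptane").cas == "142-82-5"  # case-insensitive lookup

    def test_empty_cell_becomes_missing(self, tmp_path):
        path = make_csv(
            tmp_path,
            [["A", "", 100, -50, *[""] * 20]],
        )
        table = read_solvent_table(path)
        rec = table.get("A")
        assert rec.has("Boiling_point")
        assert not rec.has("Viscosity")
        assert math.isnan(rec.get("Viscosity"))

    def test_header_without_name_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("Solvent_id,Boiling_point\nA,100\n")
        with pytest.raises(SchemaError, match="Name"):
            read_solvent_table(path)

    def test_non_numeric_token_names_row_and_column(self, tmp_path):
        path = make_csv(tmp_path, [["A", "", "hot", *[""] * 21]])
        with pytest.raises(ParseError, match="Boiling_point"):
            read_solvent_table(path)

    def test_duplicate_names_rejected(self, tmp_path):
        path = make_csv(
            tmp_path,
            [["A", "", 100, *[""] * 21], ["a", "", 110, *[""] * 21]],
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_solvent_table(path)

    def test_round_trip_preserves_values(self, three_solvent_table, tmp_path):
        out = tmp_path / "out.csv"
        write_solvent_table(three_solvent_table, out)
        again = read_solvent_table(out)
        assert again.names == three_solvent_table.names
        for rec in three_solvent_table:
            rt = again.get(rec.name)
            for prop in PROPERTY_NAMES:
                assert rt.get(prop) == pytest.approx(rec.get(prop), rel=1e-12)

    def test_round_trip_keeps_missing_and_hazards(self, three_solvent_table, tmp_path):
        masked = inject_missing(three_solvent_table, "Viscosity", 1 / 3, seed=3)
        out = tmp_path / "masked.csv"
        write_solvent_table(masked, out)
        again = read_solvent_table(out)
        assert sum(not r.has("Viscosity") for r in again) == 1

    def test_empty_table_not_writable(self, tmp_path):
        table = SolventTable([])
        with pytest.raises(ValueError, match="empty"):
            write_solvent_table(table, tmp_path / "never.csv")

    def test_unknown_columns_pass_through(self, tmp_path):
        path = make_csv(
            tmp_path,
            [["A", "", 100, *[""] * 21, "note-1"]],
            header=["Name", "CAS", *PROPERTY_NAMES, "Comment"],
        )
        table = read_solvent_table(path)
        assert table.get("A").extra["Comment"] == "note-1"


class TestRecordInvariants:
    def test_negative_hansen_rejected(self):
        with pytest.raises(ValueError, match="Hansen"):
            SolventTable([SolventRecord("X", properties={"Hansen_delta_P": -1.0})])

    def test_boiling_below_melting_rejected(self):
        with pytest.raises(ValueError, match="boiling"):
            SolventTable(
                [SolventRecord("X", properties={"Boiling_point": 10.0, "Melting_point": 50.0})]
            )

    def test_unknown_property_rejected(self):
        with pytest.raises(SchemaError):
            SolventTable([SolventRecord("X", properties={"Color": 1.0})])


class TestFeatureMatrix:
    def _tiny(self, values, name="Boiling_point"):
        recs = [SolventRecord(f"s{i}", properties={name: v}) for i, v in enumerate(values)]
        return SolventTable(recs)

    def test_minmax_maps_min_to_0_and_max_to_1(self):
        fm = feature_matrix(self._tiny([10.0, 20.0, 30.0]), columns=["Boiling_point"])
        assert fm.values[:, 0] == pytest.approx([0.0, 0.5, 1.0])

    def test_weight_scales_column(self):
        fm = feature_matrix(
            self._tiny([10.0, 20.0, 30.0]),
            columns=["Boiling_point"],
            weights={"Boiling_point": 3.0},
        )
        assert fm.values[:, 0] == pytest.approx([0.0, 1.5, 3.0])

    def test_constant_column_maps_to_half(self):
        fm = feature_matrix(self._tiny([5.0, 5.0, 5.0]), columns=["Boiling_point"])
        assert fm.values[:, 0] == pytest.approx([0.5, 0.5, 0.5])

    def test_missing_value_is_an_error(self, three_solvent_table):
        masked = inject_missing(three_solvent_table, "Viscosity", 1.0, seed=0)
        with pytest.raises(MissingDataError, match="select_feature_columns"):
            feature_matrix(masked, columns=["Viscosity"])

    def test_unknown_column_is_schema_error(self, three_solvent_table):
        with pytest.raises(SchemaError):
            feature_matrix(three_solvent_table, columns=["Chakra"])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        values=st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=2,
            max_size=12,
        ),
        weight=st.floats(min_value=0.1, max_value=10.0),
    )
    def test_values_bounded_by_weight(self, values, weight):
        fm = feature_matrix(
            self._tiny(values),
            columns=["Boiling_point"],
            weights={"Boiling_point": weight},
        )
        col = fm.values[:, 0]
        assert (col >= -1e-12).all() and (col <= weight + 1e-12).all()
        if max(values) > min(values):
            assert col.min() == pytest.approx(0.0, abs=1e-9)
            assert col.max() == pytest.approx(weight, rel=1e-9)


class TestFilters:
    def _bp_table(self):
        recs = [
            SolventRecord(f"s{v}", properties={"Boiling_point": float(v)})
            for v in (60, 100, 150)
        ]
        return SolventTable(recs)

    def test_empty_criteria_is_identity(self):
        table = self._bp_table()
        assert apply_filters(table, []).names == table.names

    def test_ideal_boiling_range_keeps_one(self):
        kept = apply_filters(
            self._bp_table(), [FilterCriterion("Boiling_point", 70, 139)]
        )
        assert kept.names == ["s100"]

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            FilterCriterion("Boiling_point", 5, 1)

    def test_missing_value_is_excluded(self):
        table = SolventTable(
            [
                SolventRecord("known", properties={"Boiling_point": 100.0}),
                SolventRecord("unknown", properties={}),
            ]
        )
        kept = apply_filters(table, [FilterCriterion("Boiling_point", 0, 200)])
        assert kept.names == ["known"]

    def test_unknown_property_is_schema_error(self):
        with pytest.raises(SchemaError):
            apply_filters(self._bp_table(), [FilterCriterion("Vibe", 0, 1)])

    def test_idempotent_and_order_independent(self):
        table, _ = make_blob_table(BlobSpec(k=3, n_per=5, seed=2))
        crits = [
            FilterCriterion("Boiling_point", 70, 139),
            FilterCriterion("Solubility_in_water", 0, 500),
        ]
        once = apply_filters(table, crits)
        twice = apply_filters(once, crits)
        swapped = apply_filters(table, crits[::-1])
        assert once.names == twice.names == swapped.names

    def test_parse_criterion_spec(self):
        c = FilterCriterion.parse("Boiling_point:70:139")
        assert (c.property, c.low, c.high) == ("Boiling_point", 70.0, 139.0)
        assert FilterCriterion.parse("Density::1.0").low == -math.inf


class TestSelectFeatureColumns:
    def test_query_missingness_drops_columns(self, three_solvent_table):
        table = three_solvent_table
        # mask 9 of 22 properties for one solvent, leave others complete
        masked = table
        for col in PROPERTY_NAMES[:9]:
            recs = []
            for rec in masked:
                props = dict(rec.properties)
                if rec.name == "Heptane":
                    props[col] = float("nan")
                recs.append(SolventRecord(rec.name, rec.cas, props))
            masked = SolventTable(recs)
        cols = select_feature_columns(masked, query="Heptane")
        assert len(cols) == 13
        assert cols == [c for c in PROPERTY_NAMES if c in cols]  # order preserved

    def test_complete_table_keeps_all(self, three_solvent_table):
        assert select_feature_columns(three_solvent_table) == list(PROPERTY_NAMES)

    def test_all_columns_incomplete_is_degenerate(self):
        recs = [
            SolventRecord("a", properties={"Boiling_point": float("nan"), "Density": 1.0}),
            SolventRecord("b", properties={"Boiling_point": 50.0, "Density": float("nan")}),
        ]
        with pytest.raises(DegenerateDataError):
            select_feature_columns(SolventTable(recs))
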