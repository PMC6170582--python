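"""Measurement schemes, specimen records and table round-trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aepymorph.datamodel import (
    Dataset,
    SchemaError,
    SpecimenRecord,
    missing_fraction,
    read_specimen_table,
    write_results,
    write_specimen_table,
)
from aepymorph.scheme import UNKNOWN_DEFINITION, Element, get_scheme


class TestScheme:
    @pytest.mark.parametrize(
        "element,count",
        [(Element.FEMUR, 20), (Element.TIBIOTARSUS, 21), (Element.TARSOMETATARSUS, 44)],
    )
    def test_code_counts_fixed(self, element, count):
        scheme = get_scheme(element)
        assert scheme.n_codes == count
        assert len(set(scheme.codes)) == count

    def test_undescribed_codes_flagged_not_guessed(self):
        # F15 and Tt21 appear in published per-taxon tables but have no
        # anatomical definition in the measurement diagram
        assert get_scheme("femur").describe("F15") == UNKNOWN_DEFINITION
        assert get_scheme("tibiotarsus").describe("Tt21") == UNKNOWN_DEFINITION
        assert get_scheme("femur").describe("F3") != UNKNOWN_DEFINITION

    def test_breakage_blocks_partition_sensibly(self):
        for element in Element:
            blocks = get_scheme(element).breakage_blocks()
            all_codes = [c for group in blocks.values() for c in group]
            assert len(all_codes) == len(set(all_codes))
            assert set(all_codes) == set(get_scheme(element).codes)


class TestRecords:
    def test_rejects_foreign_code(self):
        with pytest.raises(SchemaError):
            SpecimenRecord("x", Element.FEMUR, {"Tmt5": 100.0})

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError, match="F3"):
            SpecimenRecord("x", Element.FEMUR, {"F3": -10.0})

    @pytest.mark.parametrize(
        "n_missing,total,expected",
        [(0, 20, 0.0), (5, 20, 0.25), (11, 44, 0.25), (12, 44, 12 / 44)],
    )
    def test_missing_fraction(self, n_missing, total, expected):
        element = Element.FEMUR if total == 20 else Element.TARSOMETATARSUS
        codes = get_scheme(element).codes
        meas = {c: 100.0 for c in codes[: total - n_missing]}
        rec = SpecimenRecord("x", element, meas)
        assert missing_fraction(rec) == pytest.approx(expected)

    @given(perm=st.permutations(list(range(20))))
    @settings(max_examples=25, deadline=None)
    def test_missing_fraction_invariant_to_insertion_order(self, perm):
        codes = get_scheme(Element.FEMUR).codes
        kept = [codes[i] for i in perm[:12]]
        rec = SpecimenRecord("x", Element.FEMUR, {c: 50.0 for c in kept})
        assert missing_fraction(rec) == pytest.approx(8 / 20)


class TestTables:
    def test_read_complete_table(self, femur_csv):
        ds = read_specimen_table(femur_csv, Element.FEMUR)
        assert len(ds) == 3
        assert (ds.missing_fractions() == 0.0).all()

    def test_read_partial_row(self, femur_csv, tmp_path):
        df = pd.read_csv(femur_csv)
        for code in ["F1", "F2", "F3", "F4", "F5"]:
            df.loc[0, code] = np.nan
        path = tmp_path / "partial.csv"
        df.to_csv(path, index=False)
        ds = read_specimen_table(path, Element.FEMUR)
        assert ds.missing_fractions().iloc[0] == pytest.approx(0.25)

    def test_negative_value_names_row_and_column(self, femur_csv, tmp_path):
        df = pd.read_csv(femur_csv)
        df.loc[1, "F3"] = -10
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="F3"):
            read_specimen_table(path, Element.FEMUR)

    def test_unknown_measurement_code_is_schema_error(self, femur_csv, tmp_path):
        df = pd.read_csv(femur_csv)
        df["F99"] = 1.0
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="F99"):
            read_specimen_table(path, Element.FEMUR)

    def test_metadata_columns_preserved(self, femur_csv, tmp_path):
        df = pd.read_csv(femur_csv)
        df["excavation_year"] = [1901, 1902, 1903]
        path = tmp_path / "meta.csv"
        df.to_csv(path, index=False)
        ds = read_specimen_table(path, Element.FEMUR)
        assert ds.records[0].extra["excavation_year"] == 1901

    def test_na_literal_and_empty_cell_both_missing(self, tmp_path):
        codes = ",".join(f"F{i}" for i in range(1, 21))
        vals = ",".join(["100"] * 18)
        path = tmp_path / "na.csv"
        path.write_text(f"specimen_id,{codes}\nA,NA,,{vals}\n")
        ds = read_specimen_table(path, Element.FEMUR)
        assert ds.missing_fractions().iloc[0] == pytest.approx(2 / 20)

    def test_roundtrip_bit_exact(self, femur_csv, tmp_path):
        ds = read_specimen_table(femur_csv, Element.FEMUR)
        # knock out a few cells to carry a missing mask through the trip
        del ds.records[1].measurements["F7"]
        out = tmp_path / "out.csv"
        write_specimen_table(ds, out)
        ds2 = read_specimen_table(out, Element.FEMUR)
        pd.testing.assert_frame_equal(ds.matrix(), ds2.matrix())
        assert ds2.records[1].measurements == ds.records[1].measurements

    def test_type_status_roundtrip(self, tmp_path):
        codes = get_scheme(Element.FEMUR).codes
        rec = SpecimenRecord(
            "HOLO-1", Element.FEMUR, {c: 100.0 for c in codes},
            type_status=__import__("aepymorph").TypeStatus("titan", 1894, 1, "syntype"),
        )
        path = tmp_path / "t.csv"
        write_specimen_table(Dataset(Element.FEMUR, [rec]), path)
        ds = read_specimen_table(path, Element.FEMUR)
        ts = ds.records[0].type_status
        assert (ts.taxon_name, ts.pub_year, ts.pub_month, ts.role) == (
            "titan", 1894, 1, "syntype",
        )


class TestWriteResults:
    def test_bundle_files(self, tmp_path):
        bundle = {
            "labels": pd.DataFrame(
                {"specimen_id": [f"s{i}" for i in range(10)], "label": [0] * 10}
            ),
            "report": {"K": 4, "seed": 0},
            "cluster_ranges": pd.DataFrame({"code": ["F1"], "1_min": [100.0]}),
        }
        files = write_results(bundle, tmp_path / "out")
        assert len(files) == 3
        import json

        json.loads((tmp_path / "out" / "run_report.json").read_text())
        labels = pd.read_csv(tmp_path / "out" / "labels.csv")
        assert len(labels) == 10

    def test_missing_pieces_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_results({"labels": pd.DataFrame()}, tmp_path)
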