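"""Source-table reading, consistency checks and curated CSV round trips."""

import math

import pandas as pd
import pytest

from bbbcurate import (
    CuratedRow,
    SourceRecord,
    consistency_check,
    normalize_label,
    read_curated,
    read_source_table,
    write_curated,
)

SCHEMA = {"name": "compound_name", "smiles": "smiles_raw", "logBB": "logbb"}


def _write_csv(path, rows, columns=("name", "smiles", "logBB")):
    pd.DataFrame(rows, columns=list(columns)).to_csv(path, index=False)
    return str(path)


def test_direct_mapping_produces_one_record_per_row(tmp_path):
    path = _write_csv(
        tmp_path / "t.csv",
        [("ethanol", "CCO", -0.1), ("benzene", "c1ccccc1", 0.37), ("glycine", "NCC(=O)O", -1.2)],
    )
    records, rejects = read_source_table(path, SCHEMA, "R1")
    assert len(records) == 3 and not rejects
    assert all(r.label is None for r in records)
    assert records[0].compound_name == "ethanol"
    assert records[1].logbb == pytest.approx(0.37)


@pytest.mark.parametrize(
    "row, reason_part",
    [
        (("x", "CCO", "n/a"), "unparsable numeric"),
        ((None, None, 0.3), "no identity"),
        (("y", "CCO", None), "no datum"),
    ],
)
def test_invalid_rows_become_rejects_with_reasons(tmp_path, row, reason_part):
    path = _write_csv(tmp_path / "t.csv", [row])
    records, rejects = read_source_table(path, SCHEMA, "R1")
    assert not records and len(rejects) == 1
    assert reason_part in rejects[0].reason


def test_conservation_rows_in_equals_records_plus_rejects(tmp_path):
    rows = [("a", "CCO", 0.1), ("b", None, None), ("c", "CCN", "bad"), ("d", "CCC", -0.5)]
    path = _write_csv(tmp_path / "t.csv", rows)
    records, rejects = read_source_table(path, SCHEMA, "R1")
    assert len(records) + len(rejects) == len(rows)


def test_unmappable_column_is_fatal(tmp_path):
    path = _write_csv(tmp_path / "t.csv", [("a", "CCO", 0.1)])
    with pytest.raises(ValueError, match="not found"):
        read_source_table(path, {"missing_col": "logbb"}, "R1")


def test_xlsx_tables_are_supported(tmp_path):
    frame = pd.DataFrame({"name": ["ethanol"], "smiles": ["CCO"], "logBB": [0.2]})
    path = tmp_path / "t.xlsx"
    frame.to_excel(path, index=False)
    records, rejects = read_source_table(str(path), SCHEMA, "R2")
    assert len(records) == 1 and not rejects
    assert records[0].logbb == pytest.approx(0.2)


def test_label_and_threshold_columns_with_source_default(tmp_path):
    frame = pd.DataFrame({"smiles": ["CCO", "CCC"], "call": ["BBB+", "BBB−"]})
    path = tmp_path / "t.csv"
    frame.to_csv(path, index=False)
    records, _ = read_source_table(
        str(path), {"smiles": "smiles_raw", "call": "label"}, "R3", default_threshold=-1.0
    )
    assert [r.label for r in records] == ["BBB+", "BBB-"]  # Unicode minus normalized
    assert all(r.threshold == -1.0 for r in records)


def test_consistency_check_counts():
    records = [
        SourceRecord("R1", smiles_raw="CCO", logbb=0.1),
        SourceRecord("R1", smiles_raw="CCO", logbb=0.1),  # exact duplicate
        SourceRecord("R1", smiles_raw="CCN", logbb=math.inf),
    ]
    report = consistency_check(records)
    assert report["duplicate_rows_within_source"] == 1
    assert report["non_finite_logbb"] == 1
    assert consistency_check([])["duplicate_rows_within_source"] == 0


def _rows():
    return [
        CuratedRow(compound_name="ethanol", smiles="CCO", inchi="InChI=1S/C2H6O/c1-2-3/h3H,2H2,1H3",
                   logbb=-0.123456, reference="R1; R2", group="B", comment="ok"),
        CuratedRow(compound_name="x", smiles="CCC", inchi="InChI=x", logbb=0.5, group="A"),
    ]


def test_curated_roundtrip_is_value_identical(tmp_path):
    path = tmp_path / "num.csv"
    write_curated(_rows(), path, "numeric")
    back = read_curated(path)
    assert [r.logbb for r in back] == pytest.approx([-0.123456, 0.5])
    assert [r.group for r in back] == ["B", "A"]
    assert back[0].reference == "R1; R2"
    header = path.read_text().splitlines()[0]
    assert "BBB+/BBB-" not in header and "threshold" not in header


def test_categorical_layout_includes_label_and_threshold(tmp_path):
    rows = [CuratedRow(compound_name="a", smiles="CCO", inchi="I", label="BBB+",
                       threshold=-1.0, group="B")]
    path = tmp_path / "cat.csv"
    write_curated(rows, path, "categorical")
    header = path.read_text().splitlines()[0]
    assert "BBB+/BBB-" in header and "threshold" in header
    assert read_curated(path)[0].label == "BBB+"


def test_empty_write_produces_header_only(tmp_path):
    path = tmp_path / "empty.csv"
    write_curated([], path, "numeric")
    lines = path.read_text().splitlines()
    assert len(lines) == 1
    assert read_curated(path) == []


def test_mixed_track_write_is_fatal(tmp_path):
    rows = [CuratedRow(smiles="CCO", inchi="I", label="BBB+", group="B")]
    with pytest.raises(ValueError):
        write_curated(rows, tmp_path / "x.csv", "numeric")
    with pytest.raises(ValueError):
        write_curated(rows, tmp_path / "x.csv", "both")


def test_label_normalization_accepts_unicode_minus():
    assert normalize_label("BBB−") == "BBB-"
    assert normalize_label("bbb+") == "BBB+"
    with pytest.raises(ValueError):
        normalize_label("maybe")
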