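"""Reading tables, layout detection and column binding."""

import pytest

from miread.errors import (
    AmbiguousLayout,
    MissingConceptColumn,
    NotMachineReadable,
    RaggedTable,
)
from miread.ingest import (
    FieldMapping,
    bind_columns,
    detect_layout,
    parse_taxon_header,
    read_table,
    read_table_text,
    resolve_bindings,
)
from miread.schema import AbsencePolicy, LifeStage, ResourceMetadata, Sex

LONG_CSV = """Date,Latitude,Longitude,Species,Sex,Life Stage,Count,Unit
2017-06-04,41.5868,-93.6250,Aedes aegypti,female,adult,7,individuals
2017-06-04,41.5868,-93.6250,Culex pipiens,female,adult,0,individuals
2017-06-11,41.5868,-93.6250,Aedes aegypti,female,adult,12,individuals
"""

WIDE_CSV = """Date,sub-location,"Aedes aegypti, female, adult (individuals)","Culex pipiens, female, adult (individuals)"
2017-06-04,cattle shed,7,0
2017-06-11,school yard,3,
"""


def test_read_table_parses_csv_and_sniffs_delimiters(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text("a;b;c\n1;2;3\n", encoding="utf-8")
    t = read_table(p)
    assert t.header == ["a", "b", "c"] and t.rows == [["1", "2", "3"]]
    assert t.dialect.delimiter == ";"


def test_read_table_refuses_binary(tmp_path):
    p = tmp_path / "t.pdf"
    p.write_bytes(b"%PDF-1.4 not a table")
    with pytest.raises(NotMachineReadable):
        read_table(p)
    p2 = tmp_path / "t.xlsx"
    p2.write_bytes(b"PK\x03\x04zipzip")
    with pytest.raises(NotMachineReadable):
        read_table(p2)


def test_ragged_rows_rejected():
    with pytest.raises(RaggedTable):
        read_table_text("a,b,c\n1,2,3\n1,2,3,4\n")


def test_blank_row_delimited_second_block_is_a_structure_finding():
    t = read_table_text("a,b\n1,2\n\nx,y\n3,4\n")
    assert any(n["rule_id"] == "R4_FORMAT" and n["severity"] == "error"
               for n in t.notes)


def test_encoding_fallback_recorded(tmp_path):
    p = tmp_path / "t.csv"
    p.write_bytes("Date,Site\n2017-06-04,Neuch\xe2tel\n".encode("latin-1"))
    t = read_table(p)
    assert t.dialect.encoding == "latin-1"
    assert any(n["rule_id"] == "R4_FORMAT" for n in t.notes)


@pytest.mark.parametrize("header, expected", [
    ("Aedes aegypti, female, adult (individuals)",
     ("Aedes aegypti", Sex.female, LifeStage.adult, "individuals")),
    ("Ixodes, unknown, larva (individuals)",
     ("Ixodes", Sex.unknown, LifeStage.larva, "individuals")),
    ("Culex pipiens (individuals)",
     ("Culex pipiens", Sex.unknown, LifeStage.unknown, "individuals")),
    ("Aedes aegypti, adult (individuals)",   # stage without sex
     ("Aedes aegypti", Sex.unknown, LifeStage.adult, "individuals")),
])
def test_parse_taxon_header(header, expected):
    taxon, unit = parse_taxon_header(header)
    assert (taxon.name, taxon.sex, taxon.life_stage, unit) == expected


@pytest.mark.parametrize("header", ["Temp (°C)", "Notes", "sub-location"])
def test_non_taxon_headers_rejected(header):
    assert parse_taxon_header(header) is None


def test_detect_layout():
    assert detect_layout(read_table_text(LONG_CSV), FieldMapping()) == "long"
    assert detect_layout(read_table_text(WIDE_CSV), FieldMapping()) == "wide"
    with pytest.raises(AmbiguousLayout):
        detect_layout(read_table_text("Date,Notes\n2017-06-04,x\n"),
                      FieldMapping())


def test_bind_long_one_record_per_row_events_grouped():
    ds = bind_columns(read_table_text(LONG_CSV))
    assert len(ds.records) == 3
    assert len(ds.events) == 2           # two distinct date keys
    assert ds.records[0].taxon.name == "Aedes aegypti"
    assert ds.records[0].taxon.sex is Sex.female
    assert ds.records[1].value == 0.0
    # auto-generated ids are recorded in the notes
    assert any("auto-generated" in n["message"] for n in ds.notes)


def test_bind_wide_cell_count_matches_brute_force_enumeration():
    """n rows x k taxon columns with no blanks -> n*k records; the oracle is
    direct enumeration of the non-empty cells."""
    header = ("Date,"
              '"Aedes aegypti, female, adult (individuals)",'
              '"Culex pipiens, female, adult (individuals)",'
              '"Anopheles gambiae, female, adult (individuals)"')
    rows = [f"2017-06-{d:02d},{d},{d+1},{d+2}" for d in range(1, 6)]
    text = header + "\n" + "\n".join(rows) + "\n"
    table = read_table_text(text)
    ds = bind_columns(table, metadata=ResourceMetadata(
        absence_policy=AbsencePolicy.explicit_zeros))
    expected_cells = sum(1 for r in table.rows for c in r[1:] if c)
    assert len(ds.records) == 5 * 3 == expected_cells
    assert sum(r.value for r in ds.records) == sum(
        float(c) for r in table.rows for c in r[1:] if c)


def test_bind_wide_empty_cells_follow_absence_policy():
    make = lambda policy: bind_columns(
        read_table_text(WIDE_CSV),
        metadata=ResourceMetadata(absence_policy=policy))
    # absent_means_zero materializes a 0 record for the blank cell
    ds0 = make(AbsencePolicy.absent_means_zero)
    assert len(ds0.records) == 4
    assert sorted(r.value for r in ds0.records) == [0.0, 0.0, 3.0, 7.0]
    # absent_means_unknown leaves the cell out, with a per-cell note
    dsu = make(AbsencePolicy.absent_means_unknown)
    assert len(dsu.records) == 3
    assert any("no record materialized" in n["message"] for n in dsu.notes)
    # no declared policy: cell left out and flagged as uninterpretable
    dsn = bind_columns(read_table_text(WIDE_CSV))
    assert len(dsn.records) == 3
    assert any("meaning unknown" in n["message"] for n in dsn.notes)


def test_unbound_column_is_carried_and_named_in_a_finding():
    text = LONG_CSV.replace("Unit\n", "Unit,Temp (°C)\n").replace(
        "individuals\n", "individuals,21\n")
    ds = bind_columns(read_table_text(text))
    assert any(n.get("column") == "Temp (°C)" and n["severity"] == "warning"
               for n in ds.notes)
    assert ds.events[0].additional_info["Temp (°C)"] == "21"


def test_missing_date_column_raises():
    with pytest.raises(MissingConceptColumn):
        bind_columns(read_table_text("Species,Count\nAedes aegypti,3\n"))


def test_information_conservation_every_cell_reachable_or_named():
    """Every source cell lands in the dataset (event field, record, extra
    info) or is named in a finding."""
    text = LONG_CSV.replace("Unit\n", "Unit,Mystery\n").replace(
        "individuals\n", "individuals,xyz\n")
    table = read_table_text(text)
    ds = bind_columns(table)
    resolved, unbound, _ = resolve_bindings(table, FieldMapping())
    assert unbound == ["Mystery"]
    for col in table.header:
        if col in unbound:
            assert any(n.get("column") == col for n in ds.notes)
            assert any(col in ev.additional_info for ev in ds.events)
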