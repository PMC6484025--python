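"""Darwin Core mapping: routing completeness, field semantics and the
archive writer's self-consistency."""

import datetime as dt
import zipfile

import pytest
from lxml import etree

from miread import ScenarioSpec, corrupt, generate
from miread.dwc_export import (
    DATA_ROUTING,
    EVENT_TERMS,
    METADATA_ROUTING,
    OCCURRENCE_TERMS,
    GbifMetadata,
    build_meta_xml,
    export_rows,
    map_event,
    map_metadata,
    map_occurrence,
    write_dwca,
)
from miread.errors import NotCompliant, UnmappableEvent
from miread.schema import (
    AbsencePolicy,
    AbundanceRecord,
    LifeStage,
    Rank,
    ResourceMetadata,
    SamplingEvent,
    Sex,
    TaxonomicAssignment,
    TimePoint,
)


def test_metadata_routing_table_covers_all_seven_concepts_once():
    assert len(METADATA_ROUTING) == 7
    concepts = [c for c, _ in METADATA_ROUTING]
    assert len(set(concepts)) == 7
    # every routed GBIF target is actually populated by map_metadata
    meta = ResourceMetadata(
        contact="J. Doe, j.doe@x.org", study_description="design",
        citations=["Doe 2018"], identification_method="keys",
        absence_policy=AbsencePolicy.explicit_zeros,
        gps_obfuscation="rounded to 0.1 degree", datum="WGS84",
        usage_rights="CC0")
    mapped = map_metadata(meta)
    for _, targets in METADATA_ROUTING:
        for target in targets:
            assert getattr(mapped, target), target


def test_data_routing_table_covers_all_twelve_concepts():
    assert len(DATA_ROUTING) == 12
    concepts = [c for c, _ in DATA_ROUTING]
    assert len(set(concepts)) == 12
    emitted = set(EVENT_TERMS) | set(OCCURRENCE_TERMS)
    for _, targets in DATA_ROUTING:
        for t in targets:
            assert t in emitted or t == "geodeticDatum", t


def test_map_metadata_routing_semantics():
    meta = ResourceMetadata(
        contact="J. Doe, j.doe@x.org", study_description="weekly traps",
        identification_method="regional keys",
        absence_policy=AbsencePolicy.explicit_zeros,
        absence_note="zeros asserted", usage_rights="CC-BY 4.0",
        citations=[])
    g = map_metadata(meta)
    assert g.contact == "J. Doe, j.doe@x.org"
    assert "weekly traps" in g.designDescription
    assert "regional keys" in g.designDescription     # both land in design
    assert "zeros asserted" in g.samplingDescription
    assert g.intellectualRights == "CC-BY 4.0"
    assert g.citation == ""                           # no empty elements
    assert g.geodeticDatum == "WGS84"                 # datum default


def test_map_event_interval_formatting():
    ev = SamplingEvent(
        sample_id="E1",
        start=TimePoint(date=dt.date(2017, 6, 4), time=dt.time(18, 0)),
        end=TimePoint(date=dt.date(2017, 6, 5), time=dt.time(6, 0)),
        latitude=8.0, longitude=38.0, lat_raw="8.0000", lon_raw="38.0000",
        collection_method="New Jersey light trap", attractants="light",
        additional_info={"sub-location": "cattle shed"})
    row = map_event(ev)
    assert row["eventDate"] == "2017-06-04/2017-06-05"
    assert row["eventTime"] == "18:00/06:00"
    assert row["samplingProtocol"] == "New Jersey light trap; attractant: light"
    assert "sub-location: cattle shed" in row["eventRemarks"]
    assert row["fieldNotes"] == row["eventRemarks"]


def test_map_event_same_day_collapses_date():
    ev = SamplingEvent(
        sample_id="E1",
        start=TimePoint(date=dt.date(2017, 6, 4), time=dt.time(9, 0)),
        end=TimePoint(date=dt.date(2017, 6, 4), time=dt.time(11, 0)),
        collection_method="tick drag")
    row = map_event(ev)
    assert row["eventDate"] == "2017-06-04"
    assert row["eventTime"] == "09:00/11:00"


def test_map_event_requires_a_date():
    ev = SamplingEvent(sample_id="E1", collection_method="x")
    with pytest.raises(UnmappableEvent):
        map_event(ev)


def test_map_occurrence_genus_only_and_absence():
    larva = AbundanceRecord(
        event_ref="E1",
        taxon=TaxonomicAssignment(rank=Rank.genus, name="Ixodes",
                                  life_stage=LifeStage.larva),
        value=40)
    row = map_occurrence(larva, 1)
    assert row["genus"] == "Ixodes" and row["scientificName"] == "Ixodes"
    assert row["specificEpithet"] == "" and row["taxonRank"] == "genus"
    assert row["lifeStage"] == "larva" and row["sampleSizeValue"] == "40"
    assert row["occurrenceStatus"] == "present"
    zero = AbundanceRecord(
        event_ref="E1",
        taxon=TaxonomicAssignment(rank=Rank.species, name="Aedes aegypti",
                                  sex=Sex.female, life_stage=LifeStage.adult),
        value=0)
    row0 = map_occurrence(zero, 2, sample_name="S-1")
    assert row0["occurrenceStatus"] == "absent"
    assert row0["sampleSizeValue"] == "0"
    assert row0["fieldNumber"] == "S-1"
    assert row0["occurrenceID"] == "E1:2"


def test_occurrence_ordinals_are_deterministic(long_trap):
    _, occ1 = export_rows(long_trap)
    _, occ2 = export_rows(long_trap)
    assert [o["occurrenceID"] for o in occ1] == [o["occurrenceID"] for o in occ2]
    per_event = [o["occurrenceID"] for o in occ1 if o["eventID"] == "E0001"]
    assert per_event == ["E0001:1", "E0001:2", "E0001:3"]


def test_archive_row_counts_and_meta_xml_consistency(tmp_path, long_trap):
    path = tmp_path / "a.zip"
    write_dwca(long_trap, path)
    with zipfile.ZipFile(path) as z:
        names = set(z.namelist())
        assert names == {"meta.xml", "eml.xml", "event.txt", "occurrence.txt"}
        event_lines = z.read("event.txt").decode("utf-8").splitlines()
        occ_lines = z.read("occurrence.txt").decode("utf-8").splitlines()
        meta = etree.fromstring(z.read("meta.xml"))
    assert len(event_lines) - 1 == len(long_trap.events)
    assert len(occ_lines) - 1 == len(long_trap.records)
    # meta.xml column declarations agree with the emitted files
    ns = {"dwc": "http://rs.tdwg.org/dwc/text/"}
    core_fields = meta.findall("dwc:core/dwc:field", ns)
    assert [f.get("term").rsplit("/", 1)[1] for f in core_fields] == \
        event_lines[0].split("\t")
    ext_fields = meta.findall("dwc:extension/dwc:field", ns)
    assert [f.get("term").rsplit("/", 1)[1] for f in ext_fields] == \
        occ_lines[0].split("\t")
    coreid = meta.find("dwc:extension/dwc:coreid", ns)
    assert occ_lines[0].split("\t")[int(coreid.get("index"))] == "eventID"


def test_archive_is_byte_stable(tmp_path, long_trap):
    a, b = tmp_path / "a.zip", tmp_path / "b.zip"
    write_dwca(long_trap, a)
    write_dwca(long_trap, b)
    assert a.read_bytes() == b.read_bytes()


def test_archive_refuses_non_compliant_without_force(tmp_path, long_trap):
    bad, _ = corrupt(long_trap, {"M1_CONTACT"})
    with pytest.raises(NotCompliant):
        write_dwca(bad, tmp_path / "x.zip")
    write_dwca(bad, tmp_path / "x.zip", force=True)     # explicit override
    assert (tmp_path / "x.zip").exists()


def test_no_information_loss_every_source_field_lands_in_archive(tmp_path):
    ds = generate(ScenarioSpec(scenario="host_ectoparasite", seed=2,
                               n_events=4))
    path = tmp_path / "h.zip"
    write_dwca(ds, path)
    with zipfile.ZipFile(path) as z:
        event_txt = z.read("event.txt").decode("utf-8")
        eml = z.read("eml.xml").decode("utf-8")
    ev = ds.events[0]
    for value in [ev.sample_id, ev.locality, ev.collection_method,
                  ev.additional_info["host species"],
                  ev.additional_info["host sex"]]:
        assert value in event_txt
    for value in [ds.metadata.contact, ds.metadata.usage_rights]:
        assert value in eml


def test_empty_dataset_archive_has_headers_and_eml(tmp_path):
    from miread.schema import MireadDataset
    meta = ResourceMetadata(
        contact="J. Doe", study_description="none yet",
        identification_method="n/a keys",
        absence_policy=AbsencePolicy.explicit_zeros, usage_rights="CC0")
    ds = MireadDataset(metadata=meta)
    path = tmp_path / "e.zip"
    write_dwca(ds, path)
    with zipfile.ZipFile(path) as z:
        assert z.read("event.txt").decode().splitlines() == ["\t".join(EVENT_TERMS)]
        assert z.read("occurrence.txt").decode().splitlines() == \
            ["\t".join(OCCURRENCE_TERMS)]
        assert b"J. Doe" in z.read("eml.xml")
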