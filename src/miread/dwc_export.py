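"""Darwin Core (event core + occurrence extension) and GBIF metadata export.

An abundance submission is sampling-event-centric, so the archive uses an
event core with occurrence rows as an extension keyed on eventID.  The
routing of every standard concept to its Darwin Core / GBIF metadata target
is declared in :data:`METADATA_ROUTING` and :data:`DATA_ROUTING` — one
implemented routing per concept — so coverage is introspectable.

Archives are byte-stable: fixed file order, fixed zip timestamps, UTF-8,
tab-delimited, Unix newlines.
"""

from __future__ import annotations

import io
import os
import zipfile
from typing import Optional, Union

from lxml import etree
from pydantic import BaseModel

from .errors import NotCompliant, UnmappableEvent
from .normalize import to_canonical
from .schema import (
    AbundanceRecord,
    MireadDataset,
    Rank,
    ResourceMetadata,
    SamplingEvent,
)

# ---------------------------------------------------------------------------
# Routing tables (the documented concept → target map)
# ---------------------------------------------------------------------------

#: Resource-metadata concept → GBIF metadata profile target(s).
METADATA_ROUTING: list[tuple[str, tuple[str, ...]]] = [
    ("Contact details", ("contact",)),
    ("General description of the experiment/collection set", ("designDescription",)),
    ("Citations", ("citation",)),
    ("Species Identification Method", ("designDescription",)),
    ("Not present vs zero information", ("samplingDescription",)),
    ("GPS obfuscation information", ("geographicDescription", "geodeticDatum")),
    ("Data usage information", ("intellectualRights",)),
]

#: Data concept → Darwin Core term(s).
DATA_ROUTING: list[tuple[str, tuple[str, ...]]] = [
    ("Start Time (for collection)", ("eventDate", "eventTime")),
    ("End Time (for collection)", ("eventDate", "eventTime")),
    ("Location", ("decimalLatitude", "decimalLongitude", "locality",
                  "geodeticDatum")),
    ("Collection method", ("samplingProtocol",)),
    ("Collection attractants", ("samplingProtocol",)),
    ("Collection area", ("samplingEffort",)),
    ("Taxonomy", ("scientificName", "taxonRank", "genus", "specificEpithet",
                  "infraspecificEpithet", "sex", "lifeStage")),
    ("Unit(s) of measurement and observation", ("sampleSizeUnit",)),
    ("Value", ("sampleSizeValue",)),
    ("Additional sample information", ("fieldNotes", "eventRemarks")),
    ("SampleID", ("eventID",)),
    ("Sample Name", ("fieldNumber",)),
]

DWC_NS = "http://rs.tdwg.org/dwc/terms/"

EVENT_TERMS = [
    "eventID", "eventDate", "eventTime", "decimalLatitude", "decimalLongitude",
    "geodeticDatum", "locality", "samplingProtocol", "samplingEffort",
    "fieldNotes", "eventRemarks",
]

OCCURRENCE_TERMS = [
    "occurrenceID", "eventID", "scientificName", "taxonRank", "genus",
    "specificEpithet", "infraspecificEpithet", "sex", "lifeStage",
    "sampleSizeValue", "sampleSizeUnit", "organismQuantity",
    "organismQuantityType", "occurrenceStatus", "fieldNumber",
]


class GbifMetadata(BaseModel):
    contact: str = ""
    designDescription: str = ""
    samplingDescription: str = ""
    citation: str = ""
    geographicDescription: str = ""
    geodeticDatum: str = ""
    intellectualRights: str = ""


_ABSENCE_LABEL = {
    "explicit_zeros": "Zeros are reported explicitly; a taxon absent from the "
                      "data was not sampled or not reported.",
    "absent_means_unknown": "A taxon absent from the data was not necessarily "
                            "sought; absence of a record carries no information.",
    "absent_means_zero": "A taxon absent from the data was sought and not "
                         "found (implicit zero).",
}


def map_metadata(meta: ResourceMetadata) -> GbifMetadata:
    """Route resource metadata to the GBIF metadata profile.

    Study description and identification method both land in
    designDescription as labelled subsections; the absence policy goes to
    samplingDescription; GPS obfuscation to geographicDescription plus the
    datum label; usage rights to intellectualRights.
    """
    design_parts = []
    if meta.study_description.strip():
        design_parts.append(f"Study design: {meta.study_description.strip()}")
    if meta.identification_method.strip():
        design_parts.append(
            f"Species identification: {meta.identification_method.strip()}")
    sampling_parts = []
    if meta.absence_policy is not None:
        sampling_parts.append(_ABSENCE_LABEL[meta.absence_policy.value])
    if meta.absence_note.strip():
        sampling_parts.append(meta.absence_note.strip())
    return GbifMetadata(
        contact=meta.contact.strip(),
        designDescription="\n".join(design_parts),
        samplingDescription=" ".join(sampling_parts),
        citation="; ".join(c.strip() for c in meta.citations if c.strip()),
        geographicDescription=meta.gps_obfuscation.strip(),
        geodeticDatum=meta.datum.strip() or "WGS84",
        intellectualRights=meta.usage_rights.strip(),
    )


def map_event(event: SamplingEvent, datum: str = "WGS84") -> dict[str, str]:
    """Map a sampling event to a Darwin Core event row.

    Dates become eventDate (an ISO interval when start and end dates
    differ, collapsed to one date when equal); clock times go to eventTime
    as an interval.  Method and attractants combine into samplingProtocol;
    additional sample information serializes into fieldNotes/eventRemarks.
    """
    if event.start is None:
        raise UnmappableEvent(
            f"event {event.sample_id} has no parseable collection date")
    start, end = event.start, event.end
    if end is None or end.date == start.date:
        event_date = start.date.isoformat()
    else:
        event_date = f"{start.date.isoformat()}/{end.date.isoformat()}"
    times = [t for t in (start.clock(), end.clock() if end else "") if t]
    if start.clock() and end is not None and end.clock():
        event_time = f"{start.clock()}/{end.clock()}"
    else:
        event_time = times[0] if times else ""
    protocol = event.collection_method
    if event.attractants:
        protocol = (f"{protocol}; attractant: {event.attractants}"
                    if protocol else f"attractant: {event.attractants}")
    remarks = "; ".join(f"{k}: {v}" for k, v in event.additional_info.items())
    return {
        "eventID": event.sample_id,
        "eventDate": event_date,
        "eventTime": event_time,
        "decimalLatitude": event.lat_raw or (
            "" if event.latitude is None else repr(event.latitude)),
        "decimalLongitude": event.lon_raw or (
            "" if event.longitude is None else repr(event.longitude)),
        "geodeticDatum": datum,
        "locality": event.locality or "",
        "samplingProtocol": protocol,
        "samplingEffort": event.collection_area or "",
        "fieldNotes": remarks,
        "eventRemarks": remarks,
    }


def map_occurrence(record: AbundanceRecord, ordinal: int,
                   sample_name: Optional[str] = None) -> dict[str, str]:
    """Map an abundance record to a Darwin Core occurrence row.

    Rank-appropriate taxon fields are set (a genus-only assignment fills
    genus and scientificName, leaving the epithets empty); a value of zero
    yields occurrenceStatus "absent".  occurrenceID is the eventID plus a
    deterministic per-event ordinal.
    """
    t = record.taxon
    tokens = t.name.split()
    genus = tokens[0] if tokens else ""
    specific = tokens[1] if t.rank in (Rank.species, Rank.subspecies) and len(tokens) > 1 else ""
    infra = tokens[2] if t.rank is Rank.subspecies and len(tokens) > 2 else ""
    value = record.value
    value_str = str(int(value)) if value == int(value) else repr(value)
    return {
        "occurrenceID": f"{record.event_ref}:{ordinal}",
        "eventID": record.event_ref,
        "scientificName": t.name,
        "taxonRank": t.rank.value,
        "genus": genus if t.rank in (Rank.genus, Rank.species, Rank.subspecies) else "",
        "specificEpithet": specific,
        "infraspecificEpithet": infra,
        "sex": "" if t.sex.value == "unknown" else t.sex.value,
        "lifeStage": "" if t.life_stage.value == "unknown" else t.life_stage.value,
        "sampleSizeValue": value_str,
        "sampleSizeUnit": record.unit,
        "organismQuantity": value_str,
        "organismQuantityType": record.unit,
        "occurrenceStatus": "absent" if value == 0 else "present",
        "fieldNumber": sample_name or "",
    }


# ---------------------------------------------------------------------------
# XML documents
# ---------------------------------------------------------------------------

def build_eml(meta: GbifMetadata, title: str = "Arthropod abundance dataset") -> bytes:
    """Build an EML resource-metadata document (GBIF profile fields).
    Empty fields produce no elements."""
    eml_ns = "eml://ecoinformatics.org/eml-2.1.1"
    root = etree.Element(f"{{{eml_ns}}}eml", nsmap={"eml": eml_ns},
                         attrib={"packageId": "miread-export", "system": "miread"})
    ds = etree.SubElement(root, "dataset")
    etree.SubElement(ds, "title").text = title
    if meta.contact:
        contact = etree.SubElement(ds, "contact")
        etree.SubElement(contact, "organizationName").text = meta.contact
    if meta.intellectualRights:
        rights = etree.SubElement(ds, "intellectualRights")
        etree.SubElement(rights, "para").text = meta.intellectualRights
    if meta.geographicDescription or meta.geodeticDatum:
        cov = etree.SubElement(ds, "coverage")
        geo = etree.SubElement(cov, "geographicCoverage")
        desc = meta.geographicDescription or "Coordinates as collected"
        if meta.geodeticDatum:
            desc += f" (datum: {meta.geodeticDatum})"
        etree.SubElement(geo, "geographicDescription").text = desc
    if meta.designDescription or meta.samplingDescription:
        methods = etree.SubElement(ds, "methods")
        if meta.designDescription:
            step = etree.SubElement(methods, "methodStep")
            d = etree.SubElement(step, "description")
            etree.SubElement(d, "para").text = meta.designDescription
        if meta.samplingDescription:
            sampling = etree.SubElement(methods, "sampling")
            sd = etree.SubElement(sampling, "samplingDescription")
            etree.SubElement(sd, "para").text = meta.samplingDescription
    if meta.citation:
        add = etree.SubElement(root, "additionalMetadata")
        md = etree.SubElement(add, "metadata")
        etree.SubElement(md, "citation").text = meta.citation
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True)


def build_meta_xml() -> bytes:
    """Describe the archive structure: column indices by Darwin Core term URI."""
    ns = "http://rs.tdwg.org/dwc/text/"
    root = etree.Element(f"{{{ns}}}archive", nsmap={None: ns},
                         metadata="eml.xml")
    attrs = {"encoding": "UTF-8", "fieldsTerminatedBy": "\\t",
             "linesTerminatedBy": "\\n", "fieldsEnclosedBy": "",
             "ignoreHeaderLines": "1"}
    core = etree.SubElement(root, "core",
                            rowType="http://rs.tdwg.org/dwc/terms/Event", **attrs)
    files = etree.SubElement(core, "files")
    etree.SubElement(files, "location").text = "event.txt"
    etree.SubElement(core, "id", index="0")
    for i, term in enumerate(EVENT_TERMS):
        etree.SubElement(core, "field", index=str(i), term=DWC_NS + term)
    ext = etree.SubElement(root, "extension",
                           rowType="http://rs.tdwg.org/dwc/terms/Occurrence",
                           **attrs)
    files = etree.SubElement(ext, "files")
    etree.SubElement(files, "location").text = "occurrence.txt"
    etree.SubElement(ext, "coreid",
                     index=str(OCCURRENCE_TERMS.index("eventID")))
    for i, term in enumerate(OCCURRENCE_TERMS):
        etree.SubElement(ext, "field", index=str(i), term=DWC_NS + term)
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True)


# ---------------------------------------------------------------------------
# Archive
# ---------------------------------------------------------------------------

def _tsv(terms: list[str], rows: list[dict[str, str]]) -> str:
    out = ["\t".join(terms)]
    for row in rows:
        out.append("\t".join(row.get(t, "") for t in terms))
    return "\n".join(out) + "\n"


def export_rows(dataset: MireadDataset,
                skip_unmappable: bool = False) -> tuple[list[dict], list[dict]]:
    """Map a dataset to (event rows, occurrence rows) with deterministic
    per-event occurrence ordinals.

    With ``skip_unmappable`` (the forced-export path for non-compliant
    data), events with no parseable date — which cannot become Darwin Core
    event rows — are dropped together with their records; a compliant
    dataset never contains such events.
    """
    dataset = to_canonical(dataset, on_duplicate="keep")
    datum = dataset.metadata.datum.strip() or "WGS84"
    events = []
    exported_ids = set()
    for ev in dataset.events:
        try:
            events.append(map_event(ev, datum=datum))
            exported_ids.add(ev.sample_id)
        except UnmappableEvent:
            if not skip_unmappable:
                raise
    by_id = {ev.sample_id: ev for ev in dataset.events}
    ordinals: dict[str, int] = {}
    occurrences = []
    for rec in dataset.records:
        if rec.event_ref not in exported_ids:
            continue
        ordinals[rec.event_ref] = ordinals.get(rec.event_ref, 0) + 1
        occurrences.append(map_occurrence(
            rec, ordinals[rec.event_ref],
            sample_name=by_id[rec.event_ref].sample_name))
    return events, occurrences


def write_dwca(dataset: MireadDataset, path: Union[str, os.PathLike],
               force: bool = False) -> None:
    """Write a Darwin Core Archive (zip of event.txt, occurrence.txt,
    meta.xml, eml.xml).  Refuses non-compliant datasets unless forced.
    Byte-identical output for a fixed dataset."""
    from .validate import validate
    report = validate(dataset)
    if not report.is_compliant and not force:
        raise NotCompliant(
            "dataset has error-severity findings; fix them or pass force=True:\n"
            + report.to_text())
    events, occurrences = export_rows(dataset, skip_unmappable=force)
    eml = build_eml(map_metadata(dataset.metadata))
    meta_xml = build_meta_xml()
    event_txt = _tsv(EVENT_TERMS, events)
    occ_txt = _tsv(OCCURRENCE_TERMS, occurrences)

    buf = io.BytesIO()
    with zipfile.ZipFile(buf, "w", zipfile.ZIP_DEFLATED) as zf:
        for name, data in [("meta.xml", meta_xml), ("eml.xml", eml),
                           ("event.txt", event_txt.encode("utf-8")),
                           ("occurrence.txt", occ_txt.encode("utf-8"))]:
            info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
            info.compress_type = zipfile.ZIP_DEFLATED
            info.external_attr = 0o644 << 16
            zf.writestr(info, data)
    with open(path, "wb") as f:
        f.write(buf.getvalue())


def export_eml(dataset: MireadDataset, path: Union[str, os.PathLike]) -> None:
    """Standalone EML export."""
    with open(path, "wb") as f:
        f.write(build_eml(map_metadata(dataset.metadata)))
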