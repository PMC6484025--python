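"""Canonical long form, long↔wide pivots and record splitting.

Canonical form is long: one record per (event, taxon, sex, life stage,
unit) cell, unique on :func:`~miread.schema.canonical_key`, with zeros
materialized whenever the source asserted them — the zero-vs-unknown
distinction survives every conversion.  Wide tables are generated with the
column convention ``Taxon name, sex, stage (unit)`` and deterministic
(alphabetical) column order, so a fixed dataset always serializes to the
same bytes.
"""

from __future__ import annotations

import csv
import io
from collections import Counter
from typing import Optional

from .errors import DuplicateKey, MireadError
from .ingest import FieldMapping, RawTable, bind_columns, read_table_text
from .schema import (
    AbundanceRecord,
    LifeStage,
    MireadDataset,
    Rank,
    ResourceMetadata,
    Sex,
    TaxonomicAssignment,
    canonical_key,
    normalize_sex,
    normalize_stage,
)

#: Fixed event-column set of the interchange formats (long and wide).
EVENT_COLUMNS = [
    "SampleID", "Sample Name", "Start Time", "End Time", "Latitude",
    "Longitude", "Locality", "Collection Method", "Attractants",
    "Collection Area",
]

RECORD_COLUMNS = ["Taxon Rank", "Taxon Name", "Sex", "Life Stage", "Value", "Unit"]


def _fmt_value(v: float) -> str:
    return str(int(v)) if v == int(v) else repr(v)


def _event_cells(ev) -> list[str]:
    return [
        ev.sample_id,
        ev.sample_name or "",
        ev.start_raw or (ev.start.iso() if ev.start else ""),
        ev.end_raw or (ev.end.iso() if ev.end else ""),
        ev.lat_raw or ("" if ev.latitude is None else repr(ev.latitude)),
        ev.lon_raw or ("" if ev.longitude is None else repr(ev.longitude)),
        ev.locality or "",
        ev.collection_method,
        ev.attractants or "",
        ev.collection_area or "",
    ]


def _extra_keys(dataset: MireadDataset) -> list[str]:
    keys: list[str] = []
    for ev in dataset.events:
        for k in ev.additional_info:
            if k not in keys:
                keys.append(k)
    return sorted(keys)


def to_canonical(dataset: MireadDataset, on_duplicate: str = "raise") -> MireadDataset:
    """Sort records into deterministic canonical order and enforce key
    uniqueness.  Idempotent: canonicalizing a canonical dataset is a no-op."""
    counts = Counter(canonical_key(r) for r in dataset.records)
    dupes = sorted(k for k, n in counts.items() if n > 1)
    if dupes and on_duplicate == "raise":
        raise DuplicateKey(f"duplicate canonical keys: {dupes[:3]}"
                           + (" ..." if len(dupes) > 3 else ""))
    order = {ev.sample_id: i for i, ev in enumerate(dataset.events)}
    records = sorted(dataset.records,
                     key=lambda r: (order.get(r.event_ref, len(order)),) +
                     canonical_key(r)[1:])
    return dataset.model_copy(update={"records": records})


def taxon_column_header(taxon: TaxonomicAssignment, unit: str) -> str:
    return f"{taxon.name}, {taxon.sex.value}, {taxon.life_stage.value} ({unit})"


def long_to_wide(dataset: MireadDataset) -> RawTable:
    """Pivot a canonical dataset to a wide table: one row per event, one
    column per (taxon, sex, stage, unit) class, cells empty only where no
    record exists."""
    dataset = to_canonical(dataset)
    extra = _extra_keys(dataset)
    classes: dict[tuple, tuple[TaxonomicAssignment, str]] = {}
    for rec in dataset.records:
        key = canonical_key(rec)[1:]
        classes.setdefault(key, (rec.taxon, rec.unit))
    # key = (rank, name, sex, stage, unit); order by name, stage, sex, unit
    ordered = sorted(classes, key=lambda k: (k[1], k[3], k[2], k[4]))
    headers = [taxon_column_header(*classes[k]) for k in ordered]
    col_of = {k: i for i, k in enumerate(ordered)}

    cells: dict[str, list[str]] = {
        ev.sample_id: [""] * len(ordered) for ev in dataset.events}
    for rec in dataset.records:
        cells[rec.event_ref][col_of[canonical_key(rec)[1:]]] = _fmt_value(rec.value)

    rows = []
    for ev in dataset.events:
        rows.append(_event_cells(ev)
                    + [ev.additional_info.get(k, "") for k in extra]
                    + cells[ev.sample_id])
    return RawTable(header=EVENT_COLUMNS + extra + headers, rows=rows)


def wide_to_long(
    table: RawTable,
    metadata: Optional[ResourceMetadata] = None,
    mapping: Optional[FieldMapping] = None,
) -> MireadDataset:
    """Bind a wide table and return it in canonical long form.  Empty cells
    are resolved by the metadata's absence policy (record of 0, declared
    unknown, or a finding when no policy is declared)."""
    mapping = mapping or FieldMapping(layout="wide")
    if mapping.layout == "auto":
        mapping = FieldMapping(bindings=mapping.bindings, layout="wide",
                               vocab=mapping.vocab,
                               absence_policy=mapping.absence_policy)
    ds = bind_columns(table, mapping, metadata)
    return to_canonical(ds)


def write_long_csv(dataset: MireadDataset) -> str:
    """Serialize to the canonical long interchange CSV (UTF-8, comma
    delimited, ISO 8601 dates, fixed documented column set).  Duplicate keys
    serialize as repeated rows — validation, not serialization, is the gate."""
    dataset = to_canonical(dataset, on_duplicate="keep")
    extra = _extra_keys(dataset)
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(EVENT_COLUMNS + extra + RECORD_COLUMNS)
    by_id = {ev.sample_id: ev for ev in dataset.events}
    covered = set()
    for rec in dataset.records:
        ev = by_id[rec.event_ref]
        covered.add(rec.event_ref)
        w.writerow(_event_cells(ev)
                   + [ev.additional_info.get(k, "") for k in extra]
                   + [rec.taxon.rank.value, rec.taxon.name,
                      rec.taxon.sex.value, rec.taxon.life_stage.value,
                      _fmt_value(rec.value), rec.unit])
    for ev in dataset.events:        # record-less events still serialize
        if ev.sample_id not in covered:
            w.writerow(_event_cells(ev)
                       + [ev.additional_info.get(k, "") for k in extra]
                       + [""] * len(RECORD_COLUMNS))
    return buf.getvalue()


def write_wide_csv(dataset: MireadDataset) -> str:
    table = long_to_wide(dataset)
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(table.header)
    w.writerows(table.rows)
    return buf.getvalue()


def read_long_csv(text: str, metadata: Optional[ResourceMetadata] = None) -> MireadDataset:
    table = read_table_text(text)
    return to_canonical(bind_columns(table, FieldMapping(layout="long"), metadata))


def split_linked_records(dataset: MireadDataset) -> MireadDataset:
    """Split composite records carrying per-class component counts into one
    record per class, linked by a shared sample name.

    A component key is a life-stage or sex token (e.g. ``"adult"``,
    ``"female"``).  A composite record with no components cannot be
    apportioned without inventing numbers: it is kept as-is with a note.
    Already-split datasets pass through unchanged (idempotent).
    """
    new_records: list[AbundanceRecord] = []
    notes = list(dataset.notes)
    events = list(dataset.events)
    by_id = {ev.sample_id: i for i, ev in enumerate(events)}
    for j, rec in enumerate(dataset.records):
        if rec.components:
            ev_i = by_id[rec.event_ref]
            if events[ev_i].sample_name is None:
                events[ev_i] = events[ev_i].model_copy(
                    update={"sample_name": events[ev_i].sample_id})
            for token, value in rec.components.items():
                stage = normalize_stage(token)
                sex = normalize_sex(token) if stage is LifeStage.unknown else rec.taxon.sex
                taxon = rec.taxon.model_copy(update={
                    "life_stage": stage if stage is not LifeStage.unknown
                    else rec.taxon.life_stage,
                    "sex": sex,
                })
                new_records.append(rec.model_copy(update={
                    "taxon": taxon, "value": value, "components": None}))
        else:
            if (rec.taxon.sex is Sex.mixed or rec.taxon.life_stage is LifeStage.mixed):
                notes.append({
                    "rule_id": None, "severity": "info", "row": j, "column": None,
                    "message": f"record {j} reports a mixed {'sex' if rec.taxon.sex is Sex.mixed else 'life-stage'} "
                               "pool with no per-class counts; kept composite "
                               "(no apportionment invented)",
                })
            new_records.append(rec)
    return dataset.model_copy(update={
        "records": new_records, "events": events, "notes": notes})


def attach_host_context(
    dataset: MireadDataset, mapping: Optional[FieldMapping] = None
) -> MireadDataset:
    """Ensure host-animal descriptors live in event ``additional_info``,
    never in the arthropod taxon fields.

    With ectoparasite collections the trapped host's attributes (host
    species, host sex) are sample information about the event; a mapping
    that binds a host column onto the arthropod sex/life-stage concepts is
    a structural error and is surfaced rather than silently accepted.
    """
    if mapping is not None:
        for col, concept in mapping.bindings.items():
            if "host" in col.casefold() and concept in ("sex", "life_stage",
                                                        "taxon_name"):
                raise MireadError(
                    f"column {col!r} describes the host animal but is bound to "
                    f"the arthropod concept {concept!r}; bind it to "
                    "additional_info instead")
    return dataset
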