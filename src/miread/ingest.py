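"""Reading delimited tables and binding source columns to standard concepts.

The standard deliberately mandates no field names, so binding works in two
layers: an explicit, user-supplied :class:`FieldMapping`, and case-insensitive
header heuristics for the common vocabulary (date, latitude, species, count,
...).  Layout (long: one row per taxon×event; wide: one column per taxon
class) is detected from the bound columns when not declared.

Date parsing implements the unambiguity grammar of the data-quality rules:
ISO 8601, day-AlphaMonth-year and AlphaMonth day, year parse cleanly;
all-numeric day/month forms parse only when a field > 12 forces the day slot
(with a warning), and two-digit years always fail.
"""

from __future__ import annotations

import csv
import datetime as dt
import io
import os
import re
from dataclasses import dataclass, field
from typing import Optional, Union

import yaml

from .errors import (
    AmbiguousDate,
    AmbiguousLayout,
    DuplicateHeader,
    MireadError,
    MissingConceptColumn,
    NotMachineReadable,
    RaggedTable,
    TwoDigitYear,
    UnparseableDate,
)
from .schema import (
    AbundanceRecord,
    LifeStage,
    MireadDataset,
    Rank,
    ResourceMetadata,
    SamplingEvent,
    Sex,
    TaxonomicAssignment,
    TimePoint,
    normalize_sex,
    normalize_stage,
    resolve_rank,
)

# ---------------------------------------------------------------------------
# Raw tables
# ---------------------------------------------------------------------------


@dataclass
class Dialect:
    delimiter: str = ","
    encoding: str = "utf-8"


@dataclass
class RawTable:
    """A parsed delimited table, cells kept as text.

    ``notes`` carries findings raised while reading (encoding fallback,
    sub-table blocks); ``date_column`` is set by binding so structural checks
    can recognise rows that depend on vertical context for their date.
    """

    header: list[str]
    rows: list[list[str]]
    source_path: str = "<memory>"
    dialect: Dialect = field(default_factory=Dialect)
    notes: list[dict] = field(default_factory=list)
    date_column: Optional[str] = None

    def __post_init__(self) -> None:
        folded = [" ".join(h.split()) for h in self.header]
        if len(set(folded)) != len(folded):
            dupes = sorted({h for h in folded if folded.count(h) > 1})
            raise DuplicateHeader(f"duplicate column names: {dupes}")
        for i, row in enumerate(self.rows):
            if len(row) != len(self.header):
                raise RaggedTable(
                    f"row {i} has {len(row)} cells, header has {len(self.header)}")


_BINARY_MAGIC = (b"%PDF", b"PK\x03\x04", b"\xd0\xcf\x11\xe0")


def _sniff_delimiter(first_line: str) -> str:
    counts = {d: first_line.count(d) for d in (",", "\t", ";")}
    best = max(counts, key=lambda d: counts[d])
    return best if counts[best] > 0 else ","


def read_table_text(
    text: str,
    source_path: str = "<memory>",
    delimiter: Optional[str] = None,
    encoding: str = "utf-8",
    notes: Optional[list[dict]] = None,
) -> RawTable:
    """Parse delimited text already decoded to ``str``."""
    notes = list(notes or [])
    lines = text.splitlines()
    while lines and not lines[0].strip():
        lines.pop(0)
    if not lines:
        raise NotMachineReadable(f"{source_path}: no content")
    delim = delimiter or _sniff_delimiter(lines[0])
    reader = csv.reader(io.StringIO("\n".join(lines)), delimiter=delim)
    raw_rows = [row for row in reader]
    header = [c.strip() for c in raw_rows[0]]

    body: list[list[str]] = []
    blank_seen_at: Optional[int] = None
    for i, row in enumerate(raw_rows[1:]):
        if not any(c.strip() for c in row):
            blank_seen_at = i
            continue
        if blank_seen_at is not None:
            # a second blank-row-delimited block: sub-tables are forbidden
            notes.append({
                "rule_id": "R4_FORMAT", "severity": "error", "row": i,
                "column": None,
                "message": "second table block after a blank row "
                           "(sub-tables in one document are not machine-interpretable)",
            })
            blank_seen_at = None
        body.append([c.strip() for c in row])
    return RawTable(header=header, rows=body, source_path=source_path,
                    dialect=Dialect(delimiter=delim, encoding=encoding),
                    notes=notes)


def read_table(path: Union[str, os.PathLike], dialect_hint: Optional[str] = None) -> RawTable:
    """Read a delimited text file, sniffing delimiter and encoding.

    Binary formats (PDF, zip-based spreadsheets, OLE documents) are refused:
    the standard requires non-proprietary machine-readable text.
    """
    path = os.fspath(path)
    with open(path, "rb") as f:
        data = f.read()
    head = data[:1024]
    if any(head.startswith(m) for m in _BINARY_MAGIC) or b"\x00" in head:
        raise NotMachineReadable(f"{path}: not a machine-readable text table")
    notes: list[dict] = []
    try:
        text = data.decode("utf-8")
        encoding = "utf-8"
    except UnicodeDecodeError:
        text = data.decode("latin-1")
        encoding = "latin-1"
        notes.append({
            "rule_id": "R4_FORMAT", "severity": "warning", "row": None,
            "column": None,
            "message": f"{path}: not valid UTF-8; decoded with latin-1 fallback",
        })
    return read_table_text(text, source_path=path, delimiter=dialect_hint,
                           encoding=encoding, notes=notes)


# ---------------------------------------------------------------------------
# Date grammar
# ---------------------------------------------------------------------------

_MONTHS = {
    m.casefold(): i
    for i, names in enumerate([
        ("jan", "january"), ("feb", "february"), ("mar", "march"),
        ("apr", "april"), ("may",), ("jun", "june"), ("jul", "july"),
        ("aug", "august"), ("sep", "sept", "september"), ("oct", "october"),
        ("nov", "november"), ("dec", "december"),
    ], start=1)
    for m in names
}

_TIME_PART = r"(?:[ T](?P<h>\d{1,2}):(?P<mi>\d{2})(?::(?P<s>\d{2}))?)?"
_RE_ISO = re.compile(r"^(?P<y>\d{4})-(?P<m>\d{2})-(?P<d>\d{2})" + _TIME_PART + r"$")
_RE_D_MON_Y = re.compile(
    r"^(?P<d>\d{1,2})[-/ ](?P<mon>[A-Za-z]{3,9})\.?[-/ ](?P<y>\d{2,4})" + _TIME_PART + r"$")
_RE_MON_D_Y = re.compile(
    r"^(?P<mon>[A-Za-z]{3,9})\.?[ ](?P<d>\d{1,2}),?[ ](?P<y>\d{2,4})" + _TIME_PART + r"$")
_RE_NUMERIC = re.compile(
    r"^(?P<a>\d{1,4})[-/.](?P<b>\d{1,2})[-/.](?P<c>\d{1,4})" + _TIME_PART + r"$")


def _clock(m: re.Match) -> Optional[dt.time]:
    if m.group("h") is None:
        return None
    try:
        return dt.time(int(m.group("h")), int(m.group("mi")), int(m.group("s") or 0))
    except ValueError as e:
        raise UnparseableDate(f"invalid clock time: {e}") from e


def _date(y: int, mo: int, d: int, text: str) -> dt.date:
    try:
        return dt.date(y, mo, d)
    except ValueError as e:
        raise UnparseableDate(f"{text!r}: {e}") from e


def parse_date(text: str) -> tuple[TimePoint, bool]:
    """Parse a date (optionally with a clock time) under the unambiguity rules.

    Returns ``(timepoint, warned)`` where ``warned`` is True for forms that
    parse but are discouraged (numeric months).  Raises :class:`AmbiguousDate`
    when day and month cannot be told apart, :class:`TwoDigitYear` always for
    two-digit years, :class:`UnparseableDate` otherwise.
    """
    s = " ".join(text.strip().split())
    if not s:
        raise UnparseableDate("empty date")

    m = _RE_ISO.match(s)
    if m:
        date = _date(int(m["y"]), int(m["m"]), int(m["d"]), s)
        return TimePoint(date=date, time=_clock(m)), False

    for rx in (_RE_D_MON_Y, _RE_MON_D_Y):
        m = rx.match(s)
        if m:
            mon = _MONTHS.get(m["mon"].casefold())
            if mon is None:
                raise UnparseableDate(f"unknown month name {m['mon']!r} in {s!r}")
            if len(m["y"]) != 4:
                raise TwoDigitYear(f"two-digit year in {s!r}")
            date = _date(int(m["y"]), mon, int(m["d"]), s)
            return TimePoint(date=date, time=_clock(m)), False

    m = _RE_NUMERIC.match(s)
    if m:
        a, b, c = m["a"], m["b"], m["c"]
        if len(a) == 4:                       # year first: Y/M/D order
            date = _date(int(a), int(b), int(c), s)
            return TimePoint(date=date, time=_clock(m)), True
        if len(c) != 4:
            raise TwoDigitYear(f"two-digit year in {s!r}")
        ai, bi, yi = int(a), int(b), int(c)
        if ai <= 12 and bi <= 12:
            if ai == bi:                      # both slot assignments coincide
                date = _date(yi, bi, ai, s)
                return TimePoint(date=date, time=_clock(m)), True
            raise AmbiguousDate(
                f"{s!r}: day and month both ≤ 12 — slot order cannot be inferred")
        if ai > 12 and bi > 12:
            raise UnparseableDate(f"{s!r}: no field can be a month")
        day, mon = (ai, bi) if ai > 12 else (bi, ai)
        if day > 31:
            raise UnparseableDate(f"{s!r}: {day} cannot be a day of month")
        date = _date(yi, mon, day, s)
        return TimePoint(date=date, time=_clock(m)), True

    raise UnparseableDate(f"unrecognised date form {s!r}")


# ---------------------------------------------------------------------------
# Field mapping
# ---------------------------------------------------------------------------

#: Single-valued concepts a column can be bound to.
CONCEPTS = (
    "sample_id", "sample_name", "start", "end", "latitude", "longitude",
    "locality", "collection_method", "attractants", "collection_area",
    "taxon_name", "rank", "sex", "life_stage", "value", "unit",
)

_HEURISTICS: list[tuple[re.Pattern, str]] = [
    (re.compile(rx, re.IGNORECASE), concept) for rx, concept in [
        (r"sample[ _]?id|sampleid|event[ _]?id", "sample_id"),
        (r"sample[ _]?name|field[ _]?number", "sample_name"),
        (r"end[ _]?(date|time)( \(.*\))?", "end"),
        (r"(start[ _]?)?(date|time)( \(.*\))?|collection[ _]?date", "start"),
        (r"lat(itude)?\.?", "latitude"),
        (r"lon(g|gitude)?\.?|lng", "longitude"),
        (r"locality|location|site|place|village", "locality"),
        (r"(collection[ _]?)?method|trap([ _]?type)?|(sampling[ _]?)?protocol",
         "collection_method"),
        (r"attractants?", "attractants"),
        (r"(collection[ _]?)?area|(sampling[ _]?)?effort", "collection_area"),
        (r"species|taxon([ _]?name)?|scientific[ _]?name", "taxon_name"),
        (r"(taxon[ _]?)?rank", "rank"),
        (r"sex", "sex"),
        (r"life[ _]?stage|stage", "life_stage"),
        (r"value|count|number([ _]?(collected|caught))?|abundance|total",
         "value"),
        (r"units?([ _]?of.*)?", "unit"),
    ]
]

#: Genera recognisable in single-token wide-table taxon headers.  Data, not
#: logic: extend via FieldMapping bindings for other groups.
KNOWN_GENERA = frozenset({
    "Aedes", "Anopheles", "Culex", "Culiseta", "Psorophora", "Mansonia",
    "Ixodes", "Amblyomma", "Dermacentor", "Rhipicephalus", "Haemaphysalis",
    "Ctenocephalides", "Orchopeas", "Androlaelaps", "Ornithonyssus",
})

_TAXON_HEADER = re.compile(
    r"^(?P<name>[A-Z][a-zA-Z-]+(?: [a-z-]+){0,2})"
    r"(?:, ?(?P<a>[^,()]+?))?(?:, ?(?P<b>[^,()]+?))?"
    r"(?: ?\((?P<unit>[^()]+)\))?$"
)


def parse_taxon_header(header: str) -> Optional[tuple[TaxonomicAssignment, str]]:
    """Interpret a wide-layout column header as ``Name[, sex][, stage] (unit)``.

    Returns None when the header does not look like a taxon column (one-token
    names must be a known arthropod genus — that is what separates
    ``"Ixodes (individuals)"`` from ``"Temp (°C)"``).
    """
    m = _TAXON_HEADER.match(" ".join(header.split()))
    if not m:
        return None
    name_tokens = m["name"].split()
    if len(name_tokens) == 1 and name_tokens[0] not in KNOWN_GENERA:
        return None
    sex, stage = Sex.unknown, LifeStage.unknown
    for tok in (m["a"], m["b"]):
        if tok is None:
            continue
        key = tok.strip().casefold()
        if key in {s for s in map(str.casefold, ("",))}:
            continue
        from .schema import SEX_SYNONYMS, STAGE_SYNONYMS
        if key in SEX_SYNONYMS and key not in ("", "na", "n/a"):
            sex = SEX_SYNONYMS[key]
        elif key in STAGE_SYNONYMS and key not in ("", "na", "n/a"):
            stage = STAGE_SYNONYMS[key]
        else:
            return None     # unparsed annotation: caller falls back with a warning
    unit = (m["unit"] or "individuals").strip()
    try:
        taxon = resolve_rank(name_tokens, sex=sex, life_stage=stage)
    except MireadError:
        return None
    return taxon, unit


@dataclass
class FieldMapping:
    """Declarative binding of source columns to standard concepts.

    ``bindings`` maps a source column name to a concept from
    :data:`CONCEPTS`, ``"taxon"`` (a wide-layout per-taxon value column),
    ``"additional_info"`` or ``"ignore"``.  Unlisted columns fall through to
    the header heuristics.  ``vocab`` extends the sex/life-stage synonym maps.
    """

    bindings: dict[str, str] = field(default_factory=dict)
    layout: str = "auto"                      # long | wide | auto
    vocab: dict[str, dict[str, str]] = field(default_factory=dict)
    absence_policy: Optional[str] = None      # overrides metadata's policy

    def __post_init__(self) -> None:
        if self.layout not in ("long", "wide", "auto"):
            raise MireadError(f"unknown layout {self.layout!r}")
        seen: dict[str, str] = {}
        for col, concept in self.bindings.items():
            if concept in CONCEPTS:
                if concept in seen.values():
                    raise MireadError(
                        f"concept {concept!r} bound to more than one column")
                seen[col] = concept
            elif concept not in ("taxon", "additional_info", "ignore"):
                raise MireadError(f"unknown concept {concept!r} for column {col!r}")
        if self.layout == "wide" and self.bindings and \
                not any(c == "taxon" for c in self.bindings.values()) and \
                all(c != "taxon" for c in self.bindings.values()):
            # wide layouts may rely on header heuristics for taxon columns,
            # so an empty taxon set here is only a problem at bind time
            pass


def load_config(path: Union[str, os.PathLike]) -> tuple[FieldMapping, Optional[ResourceMetadata]]:
    """Load a YAML/JSON mapping config, optionally with a ``metadata`` block."""
    with open(path, "r", encoding="utf-8") as f:
        doc = yaml.safe_load(f) or {}
    mapping = FieldMapping(
        bindings=doc.get("bindings", {}) or {},
        layout=doc.get("layout", "auto"),
        vocab=doc.get("vocab", {}) or {},
        absence_policy=doc.get("absence_policy"),
    )
    meta = None
    if "metadata" in doc and doc["metadata"]:
        meta = ResourceMetadata.model_validate(doc["metadata"])
    return mapping, meta


# ---------------------------------------------------------------------------
# Binding
# ---------------------------------------------------------------------------

#: resolution of one column: a concept name, ("taxon", assignment, unit),
#: "additional_info" or "ignore"
_Resolved = Union[str, tuple]


def resolve_bindings(
    table: RawTable, mapping: FieldMapping
) -> tuple[dict[str, _Resolved], list[str], list[dict]]:
    """Resolve every column to a concept, taxon column or additional_info.

    Returns (resolution map, unbound column names, notes).  Unbound columns
    are carried as additional_info — never silently dropped — and named in a
    finding so the submitter can bind them explicitly.
    """
    resolved: dict[str, _Resolved] = {}
    unbound: list[str] = []
    notes: list[dict] = []
    taken = set()
    for col in table.header:
        explicit = mapping.bindings.get(col)
        if explicit is not None:
            if explicit == "taxon":
                parsed = parse_taxon_header(col)
                if parsed is None:
                    taxon = resolve_rank(col.split()[:1])
                    parsed = (taxon, "individuals")
                    notes.append({
                        "rule_id": "R4_FORMAT", "severity": "warning",
                        "row": None, "column": col,
                        "message": f"taxon column {col!r} header not parseable as "
                                   "'Name[, sex][, stage] (unit)'; "
                                   "sex/stage recorded as unknown",
                    })
                resolved[col] = ("taxon",) + parsed
            else:
                resolved[col] = explicit
                taken.add(explicit)
            continue
        concept = None
        folded = " ".join(col.split())
        for rx, c in _HEURISTICS:
            if rx.fullmatch(folded) and c not in taken:
                concept = c
                break
        if concept is not None:
            resolved[col] = concept
            taken.add(concept)
            continue
        if mapping.layout in ("wide", "auto"):
            parsed = parse_taxon_header(col)
            if parsed is not None:
                resolved[col] = ("taxon",) + parsed
                continue
        resolved[col] = "additional_info"
        unbound.append(col)
        notes.append({
            "rule_id": "R4_FORMAT", "severity": "warning", "row": None,
            "column": col,
            "message": f"column {col!r} not bound to a standard concept; "
                       "carried as additional sample information",
        })
    return resolved, unbound, notes


def detect_layout(table: RawTable, mapping: FieldMapping) -> str:
    """Decide long vs wide from the bound column signature."""
    if mapping.layout in ("long", "wide"):
        return mapping.layout
    resolved, _, _ = resolve_bindings(table, mapping)
    concepts = [r for r in resolved.values() if isinstance(r, str)]
    n_taxon_cols = sum(1 for r in resolved.values()
                       if isinstance(r, tuple) and r[0] == "taxon")
    if n_taxon_cols >= 1:
        return "wide"
    if "taxon_name" in concepts and "value" in concepts:
        return "long"
    raise AmbiguousLayout(
        "neither layout signature matches: no per-taxon value columns and no "
        "taxon-name + value column pair; supply an explicit mapping")


def _parse_float(cell: str) -> Optional[float]:
    try:
        return float(cell)
    except ValueError:
        return None


def _make_event(
    idx: int,
    cells: dict[str, str],
    extra: dict[str, str],
    auto_id: Optional[str],
    notes: list[dict],
    row: int,
) -> SamplingEvent:
    """Leniently construct an event from bound cells (validator re-checks)."""
    start = end = None
    for which in ("start", "end"):
        raw = cells.get(which, "")
        if raw:
            try:
                tp, warned = parse_date(raw)
                if which == "start":
                    start = tp
                else:
                    end = tp
            except MireadError:
                pass    # left unparsed; the date rule reports it from the raw text
    lat = _parse_float(cells.get("latitude", "")) if cells.get("latitude") else None
    lon = _parse_float(cells.get("longitude", "")) if cells.get("longitude") else None
    sample_id = cells.get("sample_id", "") or auto_id or f"E{idx + 1:04d}"
    return SamplingEvent.model_construct(
        sample_id=sample_id,
        sample_name=cells.get("sample_name") or None,
        start=start, end=end,
        start_raw=cells.get("start", ""), end_raw=cells.get("end", ""),
        latitude=lat, longitude=lon,
        lat_raw=cells.get("latitude", ""), lon_raw=cells.get("longitude", ""),
        locality=cells.get("locality") or None,
        collection_method=cells.get("collection_method", ""),
        attractants=cells.get("attractants") or None,
        collection_area=cells.get("collection_area") or None,
        additional_info=dict(extra),
    )


def bind_columns(
    table: RawTable,
    mapping: Optional[FieldMapping] = None,
    metadata: Optional[ResourceMetadata] = None,
) -> MireadDataset:
    """Bind a raw table to a dataset: events + abundance records + findings.

    Long layout groups rows into events by sample_id (or by the full tuple of
    event fields when the source has none, with auto-generated ids); wide
    layout makes one event per row and one record per taxon column.  Every
    source cell either lands in the dataset or is named in a finding.
    """
    mapping = mapping or FieldMapping()
    metadata = metadata or ResourceMetadata()
    if mapping.absence_policy:
        metadata = metadata.model_copy(
            update={"absence_policy": mapping.absence_policy})
    resolved, _, notes = resolve_bindings(table, mapping)
    notes = list(table.notes) + notes
    layout = detect_layout(table, mapping)

    concept_col = {r: col for col, r in resolved.items() if isinstance(r, str)
                   and r in CONCEPTS}
    taxon_cols = [(col, r[1], r[2]) for col, r in resolved.items()
                  if isinstance(r, tuple) and r[0] == "taxon"]
    extra_cols = [col for col, r in resolved.items() if r == "additional_info"]

    if "start" not in concept_col:
        raise MissingConceptColumn("no collection date/time column bound")
    if layout == "long" and "value" not in concept_col:
        raise MissingConceptColumn("long layout but no value column bound")

    table.date_column = concept_col["start"]
    idx_of = {col: i for i, col in enumerate(table.header)}

    def cellmap(row: list[str]) -> dict[str, str]:
        return {concept: row[idx_of[col]] for concept, col in
                ((r, c) for c, r in resolved.items() if isinstance(r, str)
                 and r in CONCEPTS)}

    sex_vocab = {k.casefold(): v for k, v in mapping.vocab.get("sex", {}).items()}
    stage_vocab = {k.casefold(): v for k, v in mapping.vocab.get("life_stage", {}).items()}

    events: list[SamplingEvent] = []
    records: list[AbundanceRecord] = []
    event_index: dict[tuple, int] = {}
    auto_counter = 0

    for row_i, row in enumerate(table.rows):
        if sum(1 for c in row if c) <= 1 and len(row) > 1:
            continue        # heading-like row; the structure rule reports it
        cells = cellmap(row)
        extra = {col: row[idx_of[col]] for col in extra_cols if row[idx_of[col]]}

        if layout == "wide":
            auto_counter += 1
            ev = _make_event(len(events), cells, extra,
                             None if cells.get("sample_id") else f"E{auto_counter:04d}",
                             notes, row_i)
            if not cells.get("sample_id"):
                notes.append({
                    "rule_id": None, "severity": "info", "row": row_i,
                    "column": None,
                    "message": f"sample_id {ev.sample_id!r} auto-generated",
                })
            events.append(ev)
            for col, taxon, unit in taxon_cols:
                cell = row[idx_of[col]]
                if cell == "":
                    policy = metadata.absence_policy
                    if policy is None:
                        notes.append({
                            "rule_id": None, "severity": "info", "row": row_i,
                            "column": col,
                            "message": "empty abundance cell with no declared "
                                       "absence policy: meaning unknown",
                        })
                        continue
                    if policy.value == "absent_means_zero":
                        records.append(AbundanceRecord.model_construct(
                            event_ref=ev.sample_id, taxon=taxon, value=0.0,
                            unit=unit, components=None))
                    else:
                        notes.append({
                            "rule_id": None, "severity": "info", "row": row_i,
                            "column": col,
                            "message": f"cell ({ev.sample_id}, {col!r}) declared "
                                       f"{policy.value}; no record materialized",
                        })
                    continue
                value = _parse_float(cell)
                if value is None:
                    notes.append({
                        "rule_id": "R4_FORMAT", "severity": "error",
                        "row": row_i, "column": col,
                        "message": f"non-numeric abundance value {cell!r}",
                    })
                    continue
                records.append(AbundanceRecord.model_construct(
                    event_ref=ev.sample_id, taxon=taxon, value=value,
                    unit=unit, components=None))
            continue

        # long layout: group rows into events
        key_cells = {k: cells.get(k, "") for k in
                     ("sample_id", "start", "end", "latitude", "longitude",
                      "locality", "collection_method", "attractants",
                      "collection_area")}
        key = (key_cells["sample_id"],) if key_cells["sample_id"] else \
            tuple(key_cells.values()) + tuple(sorted(extra.items()))
        if key not in event_index:
            auto_id = None
            if not key_cells["sample_id"]:
                auto_counter += 1
                auto_id = f"E{auto_counter:04d}"
                notes.append({
                    "rule_id": None, "severity": "info", "row": row_i,
                    "column": None,
                    "message": f"sample_id {auto_id!r} auto-generated",
                })
            event_index[key] = len(events)
            events.append(_make_event(len(events), cells, extra, auto_id,
                                      notes, row_i))
        ev = events[event_index[key]]

        name_cell = cells.get("taxon_name", "")
        sex = normalize_sex(cells.get("sex", ""), sex_vocab)
        stage = normalize_stage(cells.get("life_stage", ""), stage_vocab)
        rank_cell = cells.get("rank", "").strip().casefold()
        try:
            if rank_cell:
                taxon = TaxonomicAssignment.model_construct(
                    rank=Rank(rank_cell), name=name_cell.strip(),
                    sex=sex, life_stage=stage)
            else:
                taxon = resolve_rank(name_cell.split(), sex=sex, life_stage=stage)
        except MireadError as e:
            notes.append({
                "rule_id": "R1_ABBREV", "severity": "error", "row": row_i,
                "column": concept_col.get("taxon_name"),
                "message": str(e),
            })
            taxon = TaxonomicAssignment.model_construct(
                rank=Rank.genus, name=name_cell.strip(), sex=sex,
                life_stage=stage)
        value_cell = cells.get("value", "")
        value = _parse_float(value_cell)
        if value is None:
            notes.append({
                "rule_id": "R4_FORMAT", "severity": "error", "row": row_i,
                "column": concept_col.get("value"),
                "message": f"non-numeric abundance value {value_cell!r}",
            })
            continue
        records.append(AbundanceRecord.model_construct(
            event_ref=ev.sample_id, taxon=taxon, value=value,
            unit=cells.get("unit", "").strip(), components=None))

    return MireadDataset.model_construct(
        metadata=metadata, events=events, records=records, notes=notes,
        raw_table=table)
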