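"""Rule engine: data-quality rules plus minimum-information completeness.

Rules never raise — every problem becomes a :class:`Finding` with a fixed
default severity.  Errors are reserved for rules checkable without
heuristics (missing mandatory metadata, ambiguous dates, out-of-range
coordinates, duplicate keys, relative-abundance units, contradictions);
heuristic rules (abbreviations, coordinate precision, language) emit
warnings.  A dataset is compliant iff it has zero error-severity findings.

Row indices in findings refer to the sequence the rule inspects: the event
list for event-level rules (R2, R3, R6, D3, D4), the record list for
record-level rules (M6, D1, D2) and the raw table's data rows for structural
rules (R5).
"""

from __future__ import annotations

import enum
import json
import re
from collections import Counter
from typing import Optional

from pydantic import BaseModel, Field

from .errors import AmbiguousDate, MireadError, TwoDigitYear, UnparseableDate
from .ingest import RawTable, parse_date
from .schema import MireadDataset, canonical_key


class RuleId(str, enum.Enum):
    R1_ABBREV = "R1_ABBREV"
    R2_EXTERNAL_KEY = "R2_EXTERNAL_KEY"
    R3_DATE = "R3_DATE"
    R4_FORMAT = "R4_FORMAT"
    R5_STYLING = "R5_STYLING"
    R6_PRECISION = "R6_PRECISION"
    R7_LANGUAGE = "R7_LANGUAGE"
    M1_CONTACT = "M1_CONTACT"
    M2_STUDY_DESCRIPTION = "M2_STUDY_DESCRIPTION"
    M3_IDENTIFICATION_METHOD = "M3_IDENTIFICATION_METHOD"
    M4_ABSENCE_POLICY = "M4_ABSENCE_POLICY"
    M5_USAGE_RIGHTS = "M5_USAGE_RIGHTS"
    M6_UNIT = "M6_UNIT"
    D1_DUPLICATE_KEY = "D1_DUPLICATE_KEY"
    D2_RELATIVE_ABUNDANCE = "D2_RELATIVE_ABUNDANCE"
    D3_BAD_COORD = "D3_BAD_COORD"
    D4_TIME_ORDER = "D4_TIME_ORDER"


#: Fixed default severity per rule.  R3 date findings are errors except the
#: day-slot-forced numeric form, which parses and is therefore a warning.
DEFAULT_SEVERITY: dict[RuleId, str] = {
    RuleId.R1_ABBREV: "warning",
    RuleId.R2_EXTERNAL_KEY: "error",
    RuleId.R3_DATE: "error",
    RuleId.R4_FORMAT: "warning",
    RuleId.R5_STYLING: "error",
    RuleId.R6_PRECISION: "warning",
    RuleId.R7_LANGUAGE: "warning",
    RuleId.M1_CONTACT: "error",
    RuleId.M2_STUDY_DESCRIPTION: "error",
    RuleId.M3_IDENTIFICATION_METHOD: "error",
    RuleId.M4_ABSENCE_POLICY: "error",
    RuleId.M5_USAGE_RIGHTS: "error",
    RuleId.M6_UNIT: "error",
    RuleId.D1_DUPLICATE_KEY: "error",
    RuleId.D2_RELATIVE_ABUNDANCE: "error",
    RuleId.D3_BAD_COORD: "error",
    RuleId.D4_TIME_ORDER: "error",
}


class Finding(BaseModel):
    rule_id: RuleId
    severity: str           # "error" | "warning"
    row: Optional[int] = None
    column: Optional[str] = None
    message: str

    def sort_key(self) -> tuple:
        return (self.rule_id.value,
                -1 if self.row is None else self.row,
                self.column or "")


class ValidationReport(BaseModel):
    findings: list[Finding] = Field(default_factory=list)
    is_compliant: bool = True

    @classmethod
    def from_findings(cls, findings: list[Finding]) -> "ValidationReport":
        ordered = sorted(findings, key=Finding.sort_key)
        return cls(findings=ordered,
                   is_compliant=not any(f.severity == "error" for f in ordered))

    def errors(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "error"]

    def to_json(self) -> str:
        """Deterministic serialization: identical datasets → identical bytes."""
        payload = {
            "is_compliant": self.is_compliant,
            "findings": [
                {"rule_id": f.rule_id.value, "severity": f.severity,
                 "row": f.row, "column": f.column, "message": f.message}
                for f in self.findings
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True, ensure_ascii=False)

    def to_text(self) -> str:
        lines = [f"compliant: {'yes' if self.is_compliant else 'no'}"]
        for f in self.findings:
            loc = []
            if f.row is not None:
                loc.append(f"row {f.row}")
            if f.column:
                loc.append(f"column {f.column!r}")
            where = f" [{', '.join(loc)}]" if loc else ""
            lines.append(f"{f.severity.upper():7s} {f.rule_id.value}{where}: {f.message}")
        return "\n".join(lines)


def _finding(rule: RuleId, message: str, row: Optional[int] = None,
             column: Optional[str] = None,
             severity: Optional[str] = None) -> Finding:
    return Finding(rule_id=rule, severity=severity or DEFAULT_SEVERITY[rule],
                   row=row, column=column, message=message)


# ---------------------------------------------------------------------------
# Minimum-information completeness (M-class)
# ---------------------------------------------------------------------------

#: (attribute, rule, field label as submitters know it)
REQUIRED_METADATA = [
    ("contact", RuleId.M1_CONTACT, "Contact details"),
    ("study_description", RuleId.M2_STUDY_DESCRIPTION,
     "General description of the experiment/collection set"),
    ("identification_method", RuleId.M3_IDENTIFICATION_METHOD,
     "Species Identification Method"),
    ("absence_policy", RuleId.M4_ABSENCE_POLICY,
     "Not present vs zero information"),
    ("usage_rights", RuleId.M5_USAGE_RIGHTS, "Data usage information"),
]


def check_completeness(dataset: MireadDataset) -> list[Finding]:
    out = []
    for attr, rule, label in REQUIRED_METADATA:
        value = getattr(dataset.metadata, attr)
        if value is None or (isinstance(value, str) and not value.strip()):
            out.append(_finding(
                rule, f"required metadata field {label!r} is missing or empty",
                column=label))
    for j, rec in enumerate(dataset.records):
        if not rec.unit.strip():
            out.append(_finding(
                RuleId.M6_UNIT,
                f"record {j} ({rec.taxon.name}) has no unit of "
                "measurement/observation", row=j, column="Unit"))
    return out


# ---------------------------------------------------------------------------
# R1 — no abbreviations
# ---------------------------------------------------------------------------

_DOTTED = re.compile(r"\b[A-Za-z]{1,6}\.(?=\s|$)")
_ALLCAPS = re.compile(r"\b[A-Z]{2,6}\b")

#: Tokens exempt from the all-caps heuristic: measurement units, common
#: technical sigla and formulae that are not abbreviations of data content.
UNIT_WHITELIST = frozenset({
    "C", "F", "K", "MM", "CM", "KM", "HA", "M2", "KM2", "GPS", "ID", "UTC",
    "GMT", "WGS84", "ISO", "CO2", "UV", "LED", "DNA", "PCR",
})

#: Whole-phrase lexicon of established trap/collection-method names whose
#: sigla are proper names, not abbreviations of omitted content.
TRAP_LEXICON = frozenset(p.casefold() for p in (
    "CDC light trap", "CDC miniature light trap", "CDC gravid trap",
    "New Jersey light trap", "BG-Sentinel trap", "BG-Sentinel",
    "EVS trap", "gravid trap", "malaise trap", "pitfall trap", "light trap",
    "sweep net", "tick drag", "tick flag", "Sherman live trap",
    "Sherman trap", "host examination", "aspiration", "human landing catch",
))


def _abbrev_tokens(text: str) -> list[str]:
    if text.strip().casefold() in TRAP_LEXICON:
        return []
    hits = list(_DOTTED.findall(text))
    hits += [t for t in _ALLCAPS.findall(text)
             if t not in UNIT_WHITELIST
             and not any(t.casefold() in p for p in TRAP_LEXICON)]
    return hits


def check_abbreviations(dataset: MireadDataset) -> list[Finding]:
    """Flag dotted/all-caps tokens in column names and categorical values
    (units and whitelisted trap names exempt).  Heuristic → warnings."""
    out = []
    table: Optional[RawTable] = dataset.raw_table
    if table is not None:
        for col in table.header:
            hits = _abbrev_tokens(col)
            if hits:
                out.append(_finding(
                    RuleId.R1_ABBREV,
                    f"column name {col!r} looks abbreviated ({', '.join(hits)})",
                    column=col))
    for i, ev in enumerate(dataset.events):
        for label, text in (("Collection method", ev.collection_method),
                            ("Attractants", ev.attractants or "")):
            hits = _abbrev_tokens(text)
            if hits:
                out.append(_finding(
                    RuleId.R1_ABBREV,
                    f"value {text!r} looks abbreviated ({', '.join(hits)})",
                    row=i, column=label))
    return out


# ---------------------------------------------------------------------------
# R2 — no external legend/key files
# ---------------------------------------------------------------------------

_CODE = re.compile(r"^[A-Za-z]{0,8}[ _\-#]?\d+$")
_TAXON_CODE = re.compile(r"^(?:spp?\.?\s*\d+|[A-Za-z]{1,3}[_\-]?\d+)$", re.IGNORECASE)


def check_external_keys(dataset: MireadDataset) -> list[Finding]:
    """All data must be interpretable without a separate legend: a location
    given only as an opaque site code, or a taxon given only as a code,
    requires an external key file and is an error."""
    out = []
    for i, ev in enumerate(dataset.events):
        has_coords = ev.latitude is not None and ev.longitude is not None
        if has_coords:
            continue
        loc = (ev.locality or "").strip()
        if not loc:
            out.append(_finding(
                RuleId.R2_EXTERNAL_KEY,
                f"event {ev.sample_id} has no coordinates and no locality — "
                "location cannot be interpreted without external information",
                row=i))
        elif _CODE.match(loc):
            out.append(_finding(
                RuleId.R2_EXTERNAL_KEY,
                f"event {ev.sample_id} location given only as opaque identifier "
                f"{loc!r} with no coordinates — requires an external key",
                row=i))
    for j, rec in enumerate(dataset.records):
        name = rec.taxon.name.strip()
        if _TAXON_CODE.match(name):
            out.append(_finding(
                RuleId.R2_EXTERNAL_KEY,
                f"taxon given as code {name!r}, not a scientific name — "
                "requires an external key", row=j))
    return out


# ---------------------------------------------------------------------------
# R3 — unambiguous dates  (judged on the raw source text)
# ---------------------------------------------------------------------------

def check_dates(dataset: MireadDataset) -> list[Finding]:
    out = []
    for i, ev in enumerate(dataset.events):
        for column, raw, parsed in (("Start Time", ev.start_raw, ev.start),
                                    ("End Time", ev.end_raw, ev.end)):
            if raw:
                try:
                    _, warned = parse_date(raw)
                except AmbiguousDate as e:
                    out.append(_finding(RuleId.R3_DATE, f"ambiguous date: {e}",
                                        row=i, column=column))
                except TwoDigitYear as e:
                    out.append(_finding(RuleId.R3_DATE, f"two-digit year: {e}",
                                        row=i, column=column))
                except UnparseableDate as e:
                    out.append(_finding(RuleId.R3_DATE, f"unparseable date: {e}",
                                        row=i, column=column))
                else:
                    if warned:
                        out.append(_finding(
                            RuleId.R3_DATE,
                            f"numeric month in {raw!r}: prefer alphabetical "
                            "months or ISO 8601", row=i, column=column,
                            severity="warning"))
            elif column == "Start Time" and parsed is None:
                out.append(_finding(
                    RuleId.R3_DATE,
                    f"event {ev.sample_id} has no collection date",
                    row=i, column=column))
    return out


# ---------------------------------------------------------------------------
# R5 — no styling / subsection headings; every row self-contained
# ---------------------------------------------------------------------------

def check_structure(table: Optional[RawTable]) -> list[Finding]:
    """Flag heading-like rows and rows whose date must be inferred from
    vertical context (ditto-dependence)."""
    if table is None:
        return []
    out = []
    date_idx = None
    if table.date_column and table.date_column in table.header:
        date_idx = table.header.index(table.date_column)
    for r, row in enumerate(table.rows):
        populated = [c for c in row if c]
        if len(row) > 1 and len(populated) == 1 and row[0]:
            out.append(_finding(
                RuleId.R5_STYLING,
                f"row {r} looks like a subsection heading ({row[0]!r}); every "
                "line must be interpretable in isolation", row=r))
            continue
        if date_idx is not None and not row[date_idx] and len(populated) >= 1:
            out.append(_finding(
                RuleId.R5_STYLING,
                f"row {r} has data but no date in column "
                f"{table.date_column!r}; it is interpretable only via "
                "vertical context", row=r))
    return out


# ---------------------------------------------------------------------------
# R6 — highest precision possible (coordinates)
# ---------------------------------------------------------------------------

_DECL_DECIMALS = re.compile(r"(\d+)\s*decimal")
_DECL_DEGREES = re.compile(r"0\.(\d*1)\s*(?:°|degree)")


def declared_precision_decimals(gps_obfuscation: str) -> Optional[int]:
    """Parse a declared coordinate-degradation precision to decimal places.

    Recognises "... 2 decimal places ..." and "... rounded to 0.1° ..."
    phrasings; returns None when nothing quantitative is declared.
    """
    m = _DECL_DECIMALS.search(gps_obfuscation)
    if m:
        return int(m.group(1))
    m = _DECL_DEGREES.search(gps_obfuscation)
    if m:
        return len(m.group(1))
    return None


def _decimals(raw: str) -> Optional[int]:
    raw = raw.strip()
    if not raw or not re.fullmatch(r"-?\d+(\.\d*)?", raw):
        return None
    return len(raw.split(".")[1]) if "." in raw else 0


def check_precision(dataset: MireadDataset) -> list[Finding]:
    out = []
    gps = dataset.metadata.gps_obfuscation.strip()
    declared = declared_precision_decimals(gps) if gps else None
    for i, ev in enumerate(dataset.events):
        decs = [d for d in (_decimals(ev.lat_raw), _decimals(ev.lon_raw))
                if d is not None]
        if not decs:
            continue
        precision = min(decs)
        if not gps and precision < 2:
            out.append(_finding(
                RuleId.R6_PRECISION,
                f"event {ev.sample_id} coordinates given to {precision} decimal "
                "place(s) with no degradation statement in study information",
                row=i))
        elif declared is not None and precision > declared:
            out.append(_finding(
                RuleId.R6_PRECISION,
                f"event {ev.sample_id} coordinates carry {precision} decimals "
                f"but the metadata declares rounding to {declared}: the "
                "obfuscation statement is contradicted",
                row=i, severity="error"))
    return out


# ---------------------------------------------------------------------------
# R7 — language
# ---------------------------------------------------------------------------

def check_language(dataset: MireadDataset) -> list[Finding]:
    out = []
    headers: list[str] = []
    if dataset.raw_table is not None:
        headers = list(dataset.raw_table.header)
    else:
        for ev in dataset.events:
            headers.extend(k for k in ev.additional_info)
    seen = set()
    for col in headers:
        if col in seen:
            continue
        seen.add(col)
        if not col.isascii():
            out.append(_finding(
                RuleId.R7_LANGUAGE,
                f"non-English/non-ASCII field name {col!r}: prefer English "
                "field names for the submitted version", column=col))
    return out


# ---------------------------------------------------------------------------
# R4 — machine-readable formats (pass-through from ingest)
# ---------------------------------------------------------------------------

def check_format(dataset: MireadDataset) -> list[Finding]:
    out = []
    table: Optional[RawTable] = dataset.raw_table
    if table is not None and table.dialect.encoding.casefold() not in ("utf-8", "ascii"):
        out.append(_finding(
            RuleId.R4_FORMAT,
            f"table decoded with non-UTF-8 fallback encoding "
            f"{table.dialect.encoding!r}"))
    return out


# ---------------------------------------------------------------------------
# D-class — data rules
# ---------------------------------------------------------------------------

_RELATIVE_UNIT = re.compile(r"relative|percent|%|proportion|fraction", re.IGNORECASE)


def check_data_rules(dataset: MireadDataset) -> list[Finding]:
    out = []
    seen: Counter = Counter()
    for j, rec in enumerate(dataset.records):
        key = canonical_key(rec)
        if seen[key]:
            out.append(_finding(
                RuleId.D1_DUPLICATE_KEY,
                f"record {j} duplicates canonical key {key}", row=j))
        seen[key] += 1
        if _RELATIVE_UNIT.search(rec.unit):
            out.append(_finding(
                RuleId.D2_RELATIVE_ABUNDANCE,
                f"record {j} unit {rec.unit!r} declares a relative abundance; "
                "only raw quantities are reusable", row=j))
    for i, ev in enumerate(dataset.events):
        if ev.latitude is not None and not -90.0 <= ev.latitude <= 90.0:
            out.append(_finding(
                RuleId.D3_BAD_COORD,
                f"event {ev.sample_id} latitude {ev.latitude} outside [-90, 90]",
                row=i, column="Latitude"))
        if ev.longitude is not None and not -180.0 <= ev.longitude <= 180.0:
            out.append(_finding(
                RuleId.D3_BAD_COORD,
                f"event {ev.sample_id} longitude {ev.longitude} outside "
                "[-180, 180]", row=i, column="Longitude"))
        if ev.latitude is None and ev.lat_raw.strip():
            out.append(_finding(
                RuleId.D3_BAD_COORD,
                f"event {ev.sample_id} latitude {ev.lat_raw!r} is not a decimal "
                "degree value", row=i, column="Latitude"))
        if (ev.start is not None and ev.end is not None
                and ev.start.sort_key() > ev.end.sort_key()):
            out.append(_finding(
                RuleId.D4_TIME_ORDER,
                f"event {ev.sample_id} starts ({ev.start.iso()}) after it ends "
                f"({ev.end.iso()})", row=i))
    return out


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _lift_notes(dataset: MireadDataset) -> list[Finding]:
    out = []
    for note in dataset.notes:
        rule = note.get("rule_id")
        severity = note.get("severity")
        if rule is None or severity not in ("error", "warning"):
            continue
        out.append(Finding(rule_id=RuleId(rule), severity=severity,
                           row=note.get("row"), column=note.get("column"),
                           message=note["message"]))
    return out


def validate(dataset: MireadDataset) -> ValidationReport:
    """Run every rule exactly once; deterministic finding order
    (rule id, then row, then column)."""
    findings: list[Finding] = []
    findings += check_completeness(dataset)
    findings += check_abbreviations(dataset)
    findings += check_external_keys(dataset)
    findings += check_dates(dataset)
    findings += check_format(dataset)
    findings += check_structure(dataset.raw_table)
    findings += check_precision(dataset)
    findings += check_language(dataset)
    findings += check_data_rules(dataset)
    findings += _lift_notes(dataset)
    return ValidationReport.from_findings(findings)
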