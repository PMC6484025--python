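"""Core data model for minimum-information arthropod abundance submissions.

A submission has two components: dataset-level *resource metadata*
(:class:`ResourceMetadata`) and the *data records* — sampling events
(:class:`SamplingEvent`, one collection act: a trap night, a tick drag, an
examined host) and abundance records (:class:`AbundanceRecord`, one observed
quantity of one taxon/sex/life-stage class within an event).  The standard
mandates the *information*, not field names or vocabularies, so ingestion
maps arbitrary source vocabularies onto the canonical enumerations here.

Models validate their invariants on normal construction.  Ingestion and the
fault injector deliberately build instances through pydantic's
non-validating path (``model_construct``) so that invalid field combinations
coming from real files can be *represented* and then reported as findings by
:mod:`miread.validate` instead of crashing the pipeline.
"""

from __future__ import annotations

import datetime as dt
import enum
import re
from typing import Any, Optional

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .errors import AbbreviationError, EmptyName


class AbsencePolicy(str, enum.Enum):
    """What a missing taxon×event cell means in the source data."""

    explicit_zeros = "explicit_zeros"          # zeros are written out; absence = not sampled
    absent_means_unknown = "absent_means_unknown"
    absent_means_zero = "absent_means_zero"


class Sex(str, enum.Enum):
    female = "female"
    male = "male"
    mixed = "mixed"
    unknown = "unknown"


class LifeStage(str, enum.Enum):
    egg = "egg"
    larva = "larva"
    nymph = "nymph"
    pupa = "pupa"
    adult = "adult"
    mixed = "mixed"
    unknown = "unknown"


class Rank(str, enum.Enum):
    kingdom = "kingdom"
    phylum = "phylum"
    class_ = "class"
    order = "order"
    family = "family"
    genus = "genus"
    species = "species"
    subspecies = "subspecies"


#: Default free-text → canonical synonym maps.  The standard mandates no
#: vocabulary, so ingestion folds whatever the source wrote (case-insensitive)
#: through these; a mapping config may extend them.
SEX_SYNONYMS: dict[str, Sex] = {
    "f": Sex.female, "fem": Sex.female, "female": Sex.female, "females": Sex.female,
    "♀": Sex.female,
    "m": Sex.male, "male": Sex.male, "males": Sex.male, "♂": Sex.male,
    "mixed": Sex.mixed, "mix": Sex.mixed, "both": Sex.mixed, "f+m": Sex.mixed,
    "unknown": Sex.unknown, "unk": Sex.unknown, "u": Sex.unknown, "na": Sex.unknown,
    "n/a": Sex.unknown, "": Sex.unknown,
}

STAGE_SYNONYMS: dict[str, LifeStage] = {
    "egg": LifeStage.egg, "eggs": LifeStage.egg,
    "larva": LifeStage.larva, "larvae": LifeStage.larva, "larval": LifeStage.larva,
    "nymph": LifeStage.nymph, "nymphs": LifeStage.nymph, "nymphal": LifeStage.nymph,
    "pupa": LifeStage.pupa, "pupae": LifeStage.pupa,
    "adult": LifeStage.adult, "adults": LifeStage.adult, "imago": LifeStage.adult,
    "imagines": LifeStage.adult,
    "mixed": LifeStage.mixed, "mix": LifeStage.mixed,
    "unknown": LifeStage.unknown, "unk": LifeStage.unknown, "u": LifeStage.unknown,
    "na": LifeStage.unknown, "n/a": LifeStage.unknown, "": LifeStage.unknown,
}

#: Units whose values denote counts of discrete individuals (and must
#: therefore be integers).
COUNT_UNITS = frozenset({
    "individuals", "individual", "count", "counts", "specimen", "specimens",
})


def normalize_sex(text: str, extra: Optional[dict[str, str]] = None) -> Sex:
    """Map free-text sex annotation to the canonical enum (default unknown)."""
    key = text.strip().casefold()
    if extra and key in extra:
        return Sex(extra[key])
    return SEX_SYNONYMS.get(key, Sex.unknown)


def normalize_stage(text: str, extra: Optional[dict[str, str]] = None) -> LifeStage:
    key = text.strip().casefold()
    if extra and key in extra:
        return LifeStage(extra[key])
    return STAGE_SYNONYMS.get(key, LifeStage.unknown)


class TimePoint(BaseModel):
    """A calendar date with an optional clock time.

    The standard requires a date for every collection start/end; clock time
    is optional (overnight trap runs carry one, a one-off survey may not).
    """

    model_config = ConfigDict(frozen=True)

    date: dt.date
    time: Optional[dt.time] = None

    def sort_key(self) -> tuple[dt.date, dt.time]:
        return (self.date, self.time or dt.time.min)

    def iso(self) -> str:
        """``YYYY-MM-DD`` or ``YYYY-MM-DD HH:MM`` (seconds only if nonzero)."""
        if self.time is None:
            return self.date.isoformat()
        fmt = "%H:%M:%S" if self.time.second else "%H:%M"
        return f"{self.date.isoformat()} {self.time.strftime(fmt)}"

    def clock(self) -> str:
        if self.time is None:
            return ""
        fmt = "%H:%M:%S" if self.time.second else "%H:%M"
        return self.time.strftime(fmt)


class ResourceMetadata(BaseModel):
    """Dataset-level minimum information.

    For a submission to be judged compliant, ``contact``,
    ``study_description``, ``identification_method``, ``absence_policy`` and
    ``usage_rights`` must be non-empty; missing ones are reported as
    completeness findings, not construction errors, because a dataset with
    incomplete metadata must still be loadable in order to be diagnosed.
    """

    contact: str = ""
    study_description: str = ""
    citations: list[str] = Field(default_factory=list)
    identification_method: str = ""
    absence_policy: Optional[AbsencePolicy] = None
    absence_note: str = ""           # free-text elaboration of the policy
    gps_obfuscation: str = ""        # empty = coordinates not degraded
    datum: str = ""                  # geodetic datum label; WGS84 assumed if empty
    usage_rights: str = ""
    language: str = "en"             # IETF-style language tag


class SamplingEvent(BaseModel):
    """One collection act.

    ``start_raw``/``end_raw`` and ``lat_raw``/``lon_raw`` preserve the source
    text exactly as written; the date-grammar and coordinate-precision rules
    are judged on that text, not on the parsed values.
    """

    sample_id: str
    sample_name: Optional[str] = None
    start: Optional[TimePoint] = None
    end: Optional[TimePoint] = None
    start_raw: str = ""
    end_raw: str = ""
    latitude: Optional[float] = None
    longitude: Optional[float] = None
    lat_raw: str = ""
    lon_raw: str = ""
    locality: Optional[str] = None
    collection_method: str = ""
    attractants: Optional[str] = None
    collection_area: Optional[str] = None   # magnitude + unit, e.g. "100 m2"
    additional_info: dict[str, str] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _invariants(self) -> "SamplingEvent":
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if self.latitude is not None and not -90.0 <= self.latitude <= 90.0:
            raise ValueError(
                f"latitude {self.latitude!r} outside [-90, 90]")
        if self.longitude is not None and not -180.0 <= self.longitude <= 180.0:
            raise ValueError(
                f"longitude {self.longitude!r} outside [-180, 180]")
        if (self.start is not None and self.end is not None
                and self.start.sort_key() > self.end.sort_key()):
            raise ValueError(
                f"start_time {self.start.iso()} after end_time {self.end.iso()}")
        return self


_SINGLE_LETTER_ABBREV = re.compile(r"^[A-Za-z]\.$")


class TaxonomicAssignment(BaseModel):
    """A name at its most precise asserted rank, plus sex and life stage.

    Genus-only assignments are legal (immatures often cannot be keyed to
    species); the name must never be an unexpanded abbreviation.
    """

    model_config = ConfigDict(frozen=True)

    rank: Rank
    name: str
    sex: Sex = Sex.unknown
    life_stage: LifeStage = LifeStage.unknown

    @field_validator("name")
    @classmethod
    def _name_ok(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("taxon name must be non-empty")
        for token in v.split():
            if _SINGLE_LETTER_ABBREV.match(token):
                raise ValueError(
                    f"taxon name {v!r} contains unexpanded abbreviation {token!r}")
        return v.strip()


class AbundanceRecord(BaseModel):
    """One observed quantity: one (event, taxon, sex, life stage, unit) cell.

    Values are raw quantities only; relative abundances are derived values
    and declaring such a unit is a compliance error (caught by validation).
    ``components`` optionally carries a per-class breakdown (e.g. per life
    stage) for composite records awaiting :func:`miread.normalize.split_linked_records`.
    """

    event_ref: str
    taxon: TaxonomicAssignment
    value: float
    unit: str = "individuals"
    components: Optional[dict[str, float]] = None

    @model_validator(mode="after")
    def _invariants(self) -> "AbundanceRecord":
        if self.value < 0:
            raise ValueError(f"abundance value {self.value!r} is negative")
        if self.unit.strip().casefold() in COUNT_UNITS and self.value != int(self.value):
            raise ValueError(
                f"unit {self.unit!r} denotes individual counts but value "
                f"{self.value!r} is not an integer")
        return self


class MireadDataset(BaseModel):
    """A full submission: resource metadata + events + abundance records.

    The dataset is the unit of validation, normalization and export.
    ``notes`` accumulates machine findings raised while reading/binding the
    source (encoding fallbacks, unbound columns, ...) so the validator can
    replay them; ``raw_table`` optionally retains the source table for the
    structural rules that are judged on raw rows and headers.
    """

    model_config = ConfigDict(arbitrary_types_allowed=True)

    metadata: ResourceMetadata = Field(default_factory=ResourceMetadata)
    events: list[SamplingEvent] = Field(default_factory=list)
    records: list[AbundanceRecord] = Field(default_factory=list)
    notes: list[dict] = Field(default_factory=list)
    raw_table: Any = None

    @model_validator(mode="after")
    def _invariants(self) -> "MireadDataset":
        ids = [e.sample_id for e in self.events]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"sample_id values not unique: {dupes}")
        known = set(ids)
        for r in self.records:
            if r.event_ref not in known:
                raise ValueError(
                    f"record references unknown sampling event {r.event_ref!r}")
        return self

    def event_by_id(self, sample_id: str) -> SamplingEvent:
        for e in self.events:
            if e.sample_id == sample_id:
                return e
        raise KeyError(sample_id)


CanonicalKey = tuple[str, str, str, str, str, str]


def canonical_key(record: AbundanceRecord) -> CanonicalKey:
    """Deterministic identity of a record's cell, excluding its value.

    Used for duplicate detection and long↔wide pivot round-trips: two
    records with equal keys describe the same (event, taxon, sex, life
    stage, unit) cell.  Pure function of its input.
    """
    return (
        record.event_ref,
        record.taxon.rank.value,
        record.taxon.name.casefold(),
        record.taxon.sex.value,
        record.taxon.life_stage.value,
        record.unit.strip().casefold(),
    )


def resolve_rank(
    name_parts: list[str],
    sex: Sex = Sex.unknown,
    life_stage: LifeStage = LifeStage.unknown,
) -> TaxonomicAssignment:
    """Build a taxonomic assignment from tokenized name parts.

    One token asserts genus, two species, three subspecies; the epithet is
    never guessed.  Single-letter dotted tokens ("A.") are rejected because
    abbreviations are ambiguous.
    """
    tokens = [t.strip() for t in name_parts if t and t.strip()]
    if not tokens:
        raise EmptyName("all name tokens blank")
    for t in tokens:
        if _SINGLE_LETTER_ABBREV.match(t):
            raise AbbreviationError(
                f"unexpanded abbreviation {t!r} in taxon name {' '.join(tokens)!r}")
    rank = {1: Rank.genus, 2: Rank.species}.get(len(tokens), Rank.subspecies)
    name = " ".join(tokens[:3])
    return TaxonomicAssignment(rank=rank, name=name, sex=sex, life_stage=life_stage)
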