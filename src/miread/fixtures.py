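"""Synthetic surveillance datasets and an exhaustive fault injector.

Four scenarios mirror the standard's worked examples: long-format light-trap
mosquito counts, wide-format counts with a sub-location field, tick
drag/flag collections reporting three life stages independently (larvae
keyed only to genus) linked by a sample name, and ectoparasites collected
from trapped mice with host attributes as additional sample information.

Counts follow a negative-binomial model with a sinusoidal seasonal mean —
the shape of real temperate trap series (overdispersed, strongly seasonal).
The generator is deterministic: one (spec, seed) pair always produces an
identical dataset.  The fault injector applies one minimal, ledgered
corruption per requested rule class so validator recall can be tested
exhaustively.
"""

from __future__ import annotations

import datetime as dt
import math
import random
from dataclasses import dataclass, field

import numpy as np

from .errors import InapplicableFault, MireadError
from .ingest import read_table_text
from .normalize import write_long_csv, write_wide_csv
from .schema import (
    AbsencePolicy,
    AbundanceRecord,
    LifeStage,
    MireadDataset,
    Rank,
    ResourceMetadata,
    SamplingEvent,
    Sex,
    TaxonomicAssignment,
    TimePoint,
)

SCENARIOS = ("long_trap", "wide_subloc", "tick_drag", "host_ectoparasite")

#: Real vector taxa used for realism; data, not logic.
MOSQUITOES = [
    ("Aedes", "aegypti"), ("Culex", "pipiens"), ("Anopheles", "gambiae"),
    ("Aedes", "albopictus"), ("Culex", "quinquefasciatus"),
    ("Culiseta", "melanura"),
]
TICKS = [
    ("Ixodes", "scapularis"), ("Amblyomma", "americanum"),
    ("Dermacentor", "variabilis"),
]
ECTOPARASITES = [
    ("Orchopeas", "leucopus", LifeStage.adult),
    ("Ixodes", "scapularis", LifeStage.nymph),
    ("Androlaelaps", "fahrenholzi", LifeStage.adult),
]

ALL_FAULTS = (
    "R1_ABBREV", "R2_EXTERNAL_KEY", "R3_DATE", "R4_FORMAT", "R5_STYLING",
    "R6_PRECISION", "R7_LANGUAGE",
    "M1_CONTACT", "M2_STUDY_DESCRIPTION", "M3_IDENTIFICATION_METHOD",
    "M4_ABSENCE_POLICY", "M5_USAGE_RIGHTS", "M6_UNIT",
    "D1_DUPLICATE_KEY", "D2_RELATIVE_ABUNDANCE", "D3_BAD_COORD",
    "D4_TIME_ORDER",
)


@dataclass
class ScenarioSpec:
    """Parameters of one synthetic scenario.

    The abundance model draws counts from a negative binomial whose mean
    follows a yearly sinusoid: ``mu(t) = level * (1 + amplitude *
    sin(2π (doy - 120)/365))``, dispersion ``k`` (smaller = more
    overdispersed).  Defaults emulate a weekly temperate-summer trap series.
    """

    scenario: str = "long_trap"
    n_events: int = 12
    n_taxa: int = 3
    seed: int = 0
    mean_level: float = 20.0
    seasonal_amplitude: float = 0.6
    dispersion: float = 2.0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise MireadError(f"unknown scenario {self.scenario!r}; "
                              f"choose from {SCENARIOS}")
        if self.n_events < 1:
            raise MireadError("n_events must be >= 1")
        if self.n_taxa < 1:
            raise MireadError("n_taxa must be >= 1")


@dataclass
class FaultLedger:
    """Exactly the corruptions applied: (rule_id, row, column) triples where
    row indexes the sequence the corresponding rule inspects."""

    injected: list[tuple] = field(default_factory=list)


def _metadata(scenario: str) -> ResourceMetadata:
    descriptions = {
        "long_trap": "Weekly overnight adult mosquito surveillance with a "
                     "single fixed New Jersey light trap at a farm site; "
                     "females counted per species per trap night.",
        "wide_subloc": "Weekly overnight adult mosquito collections with CDC "
                       "light traps rotated across named sub-locations in one "
                       "village; counts per species per night and place.",
        "tick_drag": "Standardised 100 m2 tick drags along fixed woodland "
                     "transects; adults, nymphs and larvae counted "
                     "independently per drag.",
        "host_ectoparasite": "Small-mammal live trapping with full-body "
                             "ectoparasite screening of each captured mouse; "
                             "parasites counted per host examination.",
    }
    return ResourceMetadata(
        contact="Jane Field, Vector Surveillance Unit, jane.field@example.org",
        study_description=descriptions[scenario],
        citations=["Field J (2018) Seasonal arthropod surveillance at fixed "
                   "sites. Journal of Vector Ecology 43:1-9."],
        identification_method="Morphological identification to the lowest "
                              "reliable rank using regional dichotomous keys; "
                              "immature ticks keyed to genus only.",
        absence_policy=AbsencePolicy.explicit_zeros,
        absence_note="A reported zero means the taxon was sought in that "
                     "sampling event and none were found; taxa never listed "
                     "were not screened.",
        gps_obfuscation="",
        datum="WGS84",
        usage_rights="CC-BY 4.0",
        language="en",
    )


def _count(rng: np.random.Generator, date: dt.date, spec: ScenarioSpec) -> int:
    doy = date.timetuple().tm_yday
    mu = spec.mean_level * (1.0 + spec.seasonal_amplitude
                            * math.sin(2.0 * math.pi * (doy - 120) / 365.0))
    mu = max(mu, 0.05)
    k = spec.dispersion
    return int(rng.negative_binomial(k, k / (k + mu)))


def _event(i: int, date: dt.date, lat: float, lon: float, *,
           method: str, locality: str, attractants: str | None = None,
           area: str | None = None, sample_name: str | None = None,
           overnight: bool = True,
           additional: dict[str, str] | None = None) -> SamplingEvent:
    if overnight:
        start = TimePoint(date=date, time=dt.time(18, 0))
        end = TimePoint(date=date + dt.timedelta(days=1), time=dt.time(6, 0))
    else:
        start = TimePoint(date=date, time=dt.time(9, 0))
        end = TimePoint(date=date, time=dt.time(11, 0))
    return SamplingEvent(
        sample_id=f"E{i + 1:04d}", sample_name=sample_name,
        start=start, end=end, start_raw=start.iso(), end_raw=end.iso(),
        latitude=lat, longitude=lon,
        lat_raw=f"{lat:.4f}", lon_raw=f"{lon:.4f}",
        locality=locality, collection_method=method,
        attractants=attractants, collection_area=area,
        additional_info=additional or {},
    )


def generate(spec: ScenarioSpec) -> MireadDataset:
    """Generate one compliant scenario dataset (with its raw source table
    attached, as an ingested file would carry)."""
    rng = np.random.default_rng(spec.seed)
    start_date = dt.date(2016, 4, 6)
    meta = _metadata(spec.scenario)
    events: list[SamplingEvent] = []
    records: list[AbundanceRecord] = []

    base_lat = 41.5868 + float(rng.uniform(-0.05, 0.05))
    base_lon = -93.6250 + float(rng.uniform(-0.05, 0.05))

    if spec.scenario == "long_trap":
        taxa = MOSQUITOES[:spec.n_taxa]
        for i in range(spec.n_events):
            date = start_date + dt.timedelta(weeks=i)
            ev = _event(i, date, round(base_lat, 4), round(base_lon, 4),
                        method="New Jersey light trap", attractants="light",
                        locality="Hickory Grove research farm",
                        area="1 trap night")
            events.append(ev)
            for genus, species in taxa:
                records.append(AbundanceRecord(
                    event_ref=ev.sample_id,
                    taxon=TaxonomicAssignment(
                        rank=Rank.species, name=f"{genus} {species}",
                        sex=Sex.female, life_stage=LifeStage.adult),
                    value=float(_count(rng, date, spec)),
                    unit="individuals"))

    elif spec.scenario == "wide_subloc":
        taxa = MOSQUITOES[:spec.n_taxa]
        sublocs = ["cattle shed", "market square", "school yard"]
        for i in range(spec.n_events):
            date = start_date + dt.timedelta(weeks=i // len(sublocs))
            sub = sublocs[i % len(sublocs)]
            lat = round(base_lat + 0.002 * (i % len(sublocs)), 4)
            ev = _event(i, date, lat, round(base_lon, 4),
                        method="CDC light trap", attractants="carbon dioxide",
                        locality="Cedar Rapids village",
                        area="1 trap night",
                        additional={"sub-location": sub})
            events.append(ev)
            for genus, species in taxa:
                records.append(AbundanceRecord(
                    event_ref=ev.sample_id,
                    taxon=TaxonomicAssignment(
                        rank=Rank.species, name=f"{genus} {species}",
                        sex=Sex.female, life_stage=LifeStage.adult),
                    value=float(_count(rng, date, spec)),
                    unit="individuals"))

    elif spec.scenario == "tick_drag":
        taxa = TICKS[:spec.n_taxa]
        for i in range(spec.n_events):
            date = start_date + dt.timedelta(weeks=i)
            ev = _event(i, date, round(base_lat, 4), round(base_lon, 4),
                        method="tick drag", locality="Bluestem woodland transect",
                        area="100 m2", sample_name=f"TD-{i + 1:03d}",
                        overnight=False)
            events.append(ev)
            for genus, species in taxa:
                # three life stages reported independently, linked by the
                # shared sample name; larvae keyed only to genus
                for taxon in (
                    TaxonomicAssignment(rank=Rank.species,
                                        name=f"{genus} {species}",
                                        sex=Sex.female, life_stage=LifeStage.adult),
                    TaxonomicAssignment(rank=Rank.species,
                                        name=f"{genus} {species}",
                                        sex=Sex.unknown, life_stage=LifeStage.nymph),
                    TaxonomicAssignment(rank=Rank.genus, name=genus,
                                        sex=Sex.unknown, life_stage=LifeStage.larva),
                ):
                    scale = {"adult": 1.0, "nymph": 2.0, "larva": 8.0}[
                        taxon.life_stage.value]
                    records.append(AbundanceRecord(
                        event_ref=ev.sample_id, taxon=taxon,
                        value=float(int(scale * _count(rng, date, spec) / 2)),
                        unit="individuals"))

    else:  # host_ectoparasite
        taxa = ECTOPARASITES[:spec.n_taxa]
        host_sexes = ["female", "male"]
        for i in range(spec.n_events):
            date = start_date + dt.timedelta(days=3 * i)
            ev = _event(i, date, round(base_lat, 4), round(base_lon, 4),
                        method="host examination",
                        locality="Oak Hollow trapping grid",
                        sample_name=f"MOUSE-{i + 1:03d}", overnight=False,
                        additional={
                            "host species": "Peromyscus leucopus",
                            "host sex": host_sexes[i % 2],
                            "trap": "Sherman live trap",
                        })
            events.append(ev)
            for genus, species, stage in taxa:
                records.append(AbundanceRecord(
                    event_ref=ev.sample_id,
                    taxon=TaxonomicAssignment(
                        rank=Rank.species, name=f"{genus} {species}",
                        sex=Sex.unknown, life_stage=stage),
                    value=float(max(0, _count(rng, date, spec) // 4)),
                    unit="individuals"))

    ds = MireadDataset(metadata=meta, events=events, records=records)
    text = write_wide_csv(ds) if spec.scenario == "wide_subloc" else write_long_csv(ds)
    table = read_table_text(text, source_path=f"<generated:{spec.scenario}>")
    table.notes = []            # generator output carries no reading findings
    table.date_column = "Start Time"
    ds.raw_table = table
    return ds


def scenario_csv(spec: ScenarioSpec) -> str:
    """The scenario as its natural CSV shape (wide for wide_subloc, long
    otherwise), mirroring the worked-example file shapes."""
    ds = generate(spec)
    return write_wide_csv(ds) if spec.scenario == "wide_subloc" else write_long_csv(ds)


# ---------------------------------------------------------------------------
# Fault injection
# ---------------------------------------------------------------------------

def corrupt(dataset: MireadDataset, faults, seed: int = 0
            ) -> tuple[MireadDataset, FaultLedger]:
    """Apply one minimal corruption per requested fault class.

    Event-targeted faults pick distinct events; record mutations are applied
    before the duplicate-record fault so a later mutation can never undo an
    already-ledgered duplicate key.  Invalid states are written through the
    non-validating construction path — that is the point: the validator must
    find them.
    """
    faults = set(faults)
    unknown = faults - set(ALL_FAULTS)
    if unknown:
        raise InapplicableFault(f"unknown fault class(es): {sorted(unknown)}")
    ds = dataset.model_copy(deep=True)
    rng = random.Random(seed)
    ledger = FaultLedger()
    if not faults:
        return ds, ledger

    table_faults = {"R1_ABBREV", "R4_FORMAT", "R5_STYLING", "R7_LANGUAGE"}

    event_faults = [f for f in ("R2_EXTERNAL_KEY", "R3_DATE", "R6_PRECISION",
                                "D3_BAD_COORD", "D4_TIME_ORDER") if f in faults]
    if len(event_faults) > len(ds.events):
        raise InapplicableFault(
            f"{len(event_faults)} event-level faults requested but the "
            f"dataset has only {len(ds.events)} events")
    target_events = dict(zip(event_faults,
                             rng.sample(range(len(ds.events)), len(event_faults))))
    record_faults = [f for f in ("M6_UNIT", "D2_RELATIVE_ABUNDANCE")
                     if f in faults]
    if record_faults and len(ds.records) < len(record_faults):
        raise InapplicableFault("not enough records for record-level faults")
    target_records = dict(zip(record_faults,
                              rng.sample(range(len(ds.records)),
                                         len(record_faults))))

    def replace_event(i: int, **updates) -> None:
        # model_copy does not re-validate: invalid states are intentional here
        ds.events[i] = ds.events[i].model_copy(update=updates)

    meta_updates: dict = {}

    # dataset-level faults first; the raw table is then rebuilt from the
    # corrupted dataset so table-level faults (and a written fixture CSV)
    # see the same content the validator sees
    dataset_phase = sorted(faults - table_faults,
                           key=lambda f: (f == "D1_DUPLICATE_KEY", f))
    table_phase = sorted(faults & table_faults)

    for f in dataset_phase + ["__rebuild__"] + table_phase:
        if f == "__rebuild__":
            if ds.raw_table is not None:
                text = write_long_csv(ds)
                table = read_table_text(
                    text, source_path=ds.raw_table.source_path)
                table.notes = []
                table.date_column = "Start Time"
                ds.raw_table = table
            continue
        if f == "R1_ABBREV":
            table = ds.raw_table
            if table is None or "Collection Method" not in table.header:
                raise InapplicableFault("R1 needs a raw table with a "
                                        "'Collection Method' column")
            idx = table.header.index("Collection Method")
            table.header[idx] = "Col. Meth."
            ledger.injected.append((f, None, "Col. Meth."))
        elif f == "R2_EXTERNAL_KEY":
            i = target_events[f]
            replace_event(i, latitude=None, longitude=None, lat_raw="",
                          lon_raw="", locality="site_07")
            ledger.injected.append((f, i, None))
        elif f == "R3_DATE":
            i = target_events[f]
            replace_event(i, start_raw="04/06/17")
            ledger.injected.append((f, i, "Start Time"))
        elif f == "R4_FORMAT":
            table = ds.raw_table
            if table is None:
                raise InapplicableFault("R4 needs a raw table")
            table.dialect.encoding = "latin-1"
            ledger.injected.append((f, None, None))
        elif f == "R5_STYLING":
            table = ds.raw_table
            if table is None or not table.rows:
                raise InapplicableFault("R5 needs a raw table with rows")
            r = rng.randrange(len(table.rows) + 1)
            table.rows.insert(
                r, ["June collections"] + [""] * (len(table.header) - 1))
            ledger.injected.append((f, r, None))
        elif f == "R6_PRECISION":
            i = target_events[f]
            replace_event(i, latitude=8.5, longitude=8.5,
                          lat_raw="8.5", lon_raw="8.5")
            ledger.injected.append((f, i, None))
        elif f == "R7_LANGUAGE":
            table = ds.raw_table
            if table is None or "Locality" not in table.header:
                raise InapplicableFault("R7 needs a raw table with a "
                                        "'Locality' column")
            idx = table.header.index("Locality")
            table.header[idx] = "Ubicación"
            ledger.injected.append((f, None, "Ubicación"))
        elif f in ("M1_CONTACT", "M2_STUDY_DESCRIPTION",
                   "M3_IDENTIFICATION_METHOD", "M4_ABSENCE_POLICY",
                   "M5_USAGE_RIGHTS"):
            attr, label = {
                "M1_CONTACT": ("contact", "Contact details"),
                "M2_STUDY_DESCRIPTION": (
                    "study_description",
                    "General description of the experiment/collection set"),
                "M3_IDENTIFICATION_METHOD": (
                    "identification_method", "Species Identification Method"),
                "M4_ABSENCE_POLICY": (
                    "absence_policy", "Not present vs zero information"),
                "M5_USAGE_RIGHTS": ("usage_rights", "Data usage information"),
            }[f]
            meta_updates[attr] = None if attr == "absence_policy" else ""
            if attr == "absence_policy":
                meta_updates["absence_note"] = ""
            ledger.injected.append((f, None, label))
        elif f == "M6_UNIT":
            j = target_records[f]
            ds.records[j] = ds.records[j].model_copy(update={"unit": ""})
            ledger.injected.append((f, j, "Unit"))
        elif f == "D1_DUPLICATE_KEY":
            if not ds.records:
                raise InapplicableFault("D1 needs at least one record")
            j = rng.randrange(len(ds.records))
            ds.records.append(ds.records[j].model_copy(deep=True))
            ledger.injected.append((f, len(ds.records) - 1, None))
        elif f == "D2_RELATIVE_ABUNDANCE":
            j = target_records[f]
            ds.records[j] = ds.records[j].model_copy(
                update={"unit": "relative abundance"})
            ledger.injected.append((f, j, None))
        elif f == "D3_BAD_COORD":
            i = target_events[f]
            replace_event(i, latitude=95.1234, lat_raw="95.1234")
            ledger.injected.append((f, i, "Latitude"))
        elif f == "D4_TIME_ORDER":
            i = target_events[f]
            ev = ds.events[i]
            if ev.start is None or ev.end is None or \
                    ev.start.sort_key() >= ev.end.sort_key():
                raise InapplicableFault(
                    f"event {ev.sample_id} has no strict start<end to invert")
            replace_event(i, start=ev.end, end=ev.start,
                          start_raw=ev.end.iso(), end_raw=ev.start.iso())
            ledger.injected.append((f, i, None))

    if meta_updates:
        ds.metadata = ds.metadata.model_copy(update=meta_updates)
    return ds, ledger
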