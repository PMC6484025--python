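"""Layout conversions: round-trips, count conservation, splitting."""

import datetime as dt

import pytest

from miread import ScenarioSpec, generate
from miread.errors import DuplicateKey, MireadError
from miread.ingest import FieldMapping
from miread.normalize import (
    long_to_wide,
    split_linked_records,
    to_canonical,
    wide_to_long,
    write_long_csv,
    write_wide_csv,
)
from miread.schema import (
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
    canonical_key,
)


def _key_multiset(ds):
    return sorted((canonical_key(r), r.value) for r in ds.records)


def test_round_trip_long_wide_long_is_identity(scenario_dataset):
    ds = scenario_dataset
    back = wide_to_long(long_to_wide(ds), ds.metadata)
    assert _key_multiset(back) == _key_multiset(ds)
    # event content survives too
    assert [(e.sample_id, e.start, e.end, e.additional_info)
            for e in back.events] == \
        [(e.sample_id, e.start, e.end, e.additional_info)
         for e in ds.events]


@pytest.mark.parametrize("seed", range(5))
def test_count_conservation_under_every_conversion(seed):
    ds = generate(ScenarioSpec(scenario="tick_drag", seed=seed, n_events=6))
    total = sum(r.value for r in ds.records)
    assert sum(r.value for r in wide_to_long(long_to_wide(ds),
                                             ds.metadata).records) == total
    wide = long_to_wide(ds)
    cell_sum = sum(float(c) for row in wide.rows
                   for c in row[len(row) - len(ds.records) // len(ds.events):]
                   if c)
    assert cell_sum == total


def test_wide_pivot_materializes_zeros_distinct_from_unknowns():
    ev = SamplingEvent(sample_id="E1",
                       start=TimePoint(date=dt.date(2017, 6, 4)),
                       latitude=41.0, longitude=-93.0,
                       collection_method="sweep net")
    rec = lambda name, v: AbundanceRecord(
        event_ref="E1", taxon=TaxonomicAssignment(
            rank=Rank.species, name=name, sex=Sex.female,
            life_stage=LifeStage.adult), value=v)
    ds = MireadDataset(
        metadata=ResourceMetadata(absence_policy=AbsencePolicy.explicit_zeros),
        events=[ev], records=[rec("Aedes aegypti", 7), rec("Culex pipiens", 0)])
    wide = long_to_wide(ds)
    taxon_cells = wide.rows[0][-2:]
    assert taxon_cells == ["7", "0"]       # the asserted zero is written out
    back = wide_to_long(wide, ds.metadata)
    assert sorted(r.value for r in back.records) == [0.0, 7.0]


def test_two_life_stages_become_two_columns():
    ds = generate(ScenarioSpec(scenario="tick_drag", seed=1, n_events=3,
                               n_taxa=1))
    wide = long_to_wide(ds)
    stage_cols = [h for h in wide.header if h.startswith("Ixodes")]
    assert len(stage_cols) == 3            # adult, nymph, larva columns
    assert any(", larva (" in h for h in stage_cols)


def test_empty_dataset_gives_header_only_table():
    ds = MireadDataset(metadata=ResourceMetadata())
    wide = long_to_wide(ds)
    assert wide.rows == [] and len(wide.header) >= 10
    assert write_long_csv(ds).count("\n") == 1


def test_canonicalization_is_idempotent_and_detects_duplicates(long_trap):
    c1 = to_canonical(long_trap)
    c2 = to_canonical(c1)
    assert _key_multiset(c1) == _key_multiset(c2)
    assert [r.event_ref for r in c1.records] == [r.event_ref for r in c2.records]
    dup = long_trap.model_copy(deep=True)
    dup.records.append(dup.records[0].model_copy(deep=True))
    with pytest.raises(DuplicateKey):
        to_canonical(dup)


def test_split_linked_records_apportions_by_stage_and_links_by_sample_name():
    ev = SamplingEvent(sample_id="E1", sample_name=None,
                       start=TimePoint(date=dt.date(2017, 6, 4)),
                       latitude=41.0, longitude=-93.0,
                       collection_method="tick drag")
    composite = AbundanceRecord(
        event_ref="E1",
        taxon=TaxonomicAssignment(rank=Rank.species,
                                  name="Ixodes scapularis",
                                  life_stage=LifeStage.mixed),
        value=48, components={"adult": 3, "nymph": 5, "larva": 40})
    ds = MireadDataset(metadata=ResourceMetadata(), events=[ev],
                       records=[composite])
    out = split_linked_records(ds)
    assert len(out.records) == 3
    assert {r.taxon.life_stage.value for r in out.records} == \
        {"adult", "nymph", "larva"}
    assert sum(r.value for r in out.records) == 48
    assert out.events[0].sample_name == "E1"   # linking label assigned
    # idempotent on an already-split dataset
    again = split_linked_records(out)
    assert _key_multiset(again) == _key_multiset(out)


def test_unsplittable_composite_kept_with_note():
    ev = SamplingEvent(sample_id="E1",
                       start=TimePoint(date=dt.date(2017, 6, 4)),
                       latitude=41.0, longitude=-93.0,
                       collection_method="sweep net")
    mixed = AbundanceRecord(
        event_ref="E1",
        taxon=TaxonomicAssignment(rank=Rank.species, name="Aedes aegypti",
                                  sex=Sex.mixed, life_stage=LifeStage.adult),
        value=12)
    ds = MireadDataset(metadata=ResourceMetadata(), events=[ev], records=[mixed])
    out = split_linked_records(ds)
    assert len(out.records) == 1 and out.records[0].taxon.sex is Sex.mixed
    assert any("kept composite" in n["message"] for n in out.notes)


def test_host_descriptors_live_on_the_event_not_the_arthropod():
    ds = generate(ScenarioSpec(scenario="host_ectoparasite", seed=4))
    assert all(ev.additional_info.get("host sex") in ("female", "male")
               for ev in ds.events)
    from miread.normalize import attach_host_context
    assert attach_host_context(ds) is ds
    bad_mapping = FieldMapping(bindings={"host sex": "sex"})
    with pytest.raises(MireadError, match="host"):
        attach_host_context(ds, bad_mapping)


def test_generated_wide_column_order_is_deterministic():
    ds = generate(ScenarioSpec(scenario="wide_subloc", seed=9))
    h1 = long_to_wide(ds).header
    h2 = long_to_wide(ds).header
    assert h1 == h2
    taxa = [h for h in h1 if "(" in h]
    assert taxa == sorted(taxa)


def test_wide_csv_and_long_csv_serializations_are_stable(long_trap):
    assert write_long_csv(long_trap) == write_long_csv(long_trap)
    assert write_wide_csv(long_trap) == write_wide_csv(long_trap)


from hypothesis import given, settings
from hypothesis import strategies as st

from miread.fixtures import SCENARIOS


@settings(max_examples=20, deadline=None, derandomize=True)
@given(scenario=st.sampled_from(SCENARIOS),
       seed=st.integers(0, 2**16),
       n_events=st.integers(1, 8),
       n_taxa=st.integers(1, 3),
       amplitude=st.floats(0.0, 0.95))
def test_pivot_round_trip_property(scenario, seed, n_events, n_taxa, amplitude):
    """For any generated dataset shape, pivoting to wide and back is the
    identity on canonical records and conserves the total count."""
    ds = generate(ScenarioSpec(scenario=scenario, seed=seed,
                               n_events=n_events, n_taxa=n_taxa,
                               seasonal_amplitude=amplitude))
    back = wide_to_long(long_to_wide(ds), ds.metadata)
    assert _key_multiset(back) == _key_multiset(ds)
    assert sum(r.value for r in back.records) == sum(r.value for r in ds.records)
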