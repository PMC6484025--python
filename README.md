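# miread

Tooling for **minimum-information arthropod abundance data**: validate,
normalize and publish field-collected arthropod count data (mosquito trap
series, tick drags, host ectoparasite surveys, pollinator and pest
monitoring) so that it can be reused without consulting its creators.

Surveillance programmes worldwide produce abundance time series, but the
files that reach repositories routinely lack the metadata needed to
reinterpret them: which trap was used, what a missing taxon means (a true
zero or simply "not screened"), whether `04/06/2017` is April or June,
whether coordinates were deliberately degraded for privacy. This package
implements a minimum-information checklist and data-quality rule set for
such submissions, plus the conversions a data aggregator needs.

## What it does

A submission is modelled as two components:

- **Resource metadata** — contact, study description, species
  identification method, the zero-vs-not-present policy, GPS obfuscation
  statement, usage rights;
- **Data records** — *sampling events* (one collection act: a trap night,
  a 100 m² drag, one examined host) and *abundance records* (one observed
  quantity of one taxon × sex × life-stage class, with its unit).

On top of that model:

- **Validation** (`miread.validate`): a rule engine covering the
  data-quality standards — no abbreviations (R1), no external legend/key
  files (R2), unambiguous dates (R3), machine-readable formats (R4), no
  styling/section headings and no rows that need vertical context (R5),
  highest available precision (R6), language (R7) — plus completeness of
  the mandatory metadata (M1–M5), per-record units (M6) and data rules
  (duplicate keys D1, relative-abundance units D2, coordinate range D3,
  time ordering D4). Output is an ordered, machine-readable report with a
  compliance verdict: compliant ⇔ zero error-severity findings.
- **Ingestion** (`miread.ingest`): delimited-text reading with layout
  detection (long: one row per taxon × event; wide: one column per taxon
  class), header heuristics plus an explicit column-mapping config — the
  standard mandates *information*, never field names — and a date parser
  that accepts only unambiguous forms (ISO 8601, `4-Jun-2017`,
  `Nov 12, 2015`; all-numeric forms only when a field > 12 forces the day
  slot).
- **Normalization** (`miread.normalize`): lossless long ↔ wide pivots that
  conserve counts and preserve the zero-vs-unknown distinction, record
  splitting by life stage/sex linked via a shared sample name, host
  attributes kept as event information.
- **Darwin Core export** (`miread.dwc_export`): event core + occurrence
  extension Darwin Core Archives (`event.txt`, `occurrence.txt`,
  `meta.xml`, `eml.xml`) with the documented routing of every concept
  (e.g. SampleID → `eventID`, collection method and attractants →
  `samplingProtocol`, value/unit → `sampleSizeValue`/`sampleSizeUnit`,
  zero counts → `occurrenceStatus=absent`), and a GBIF-profile EML
  document. Archives are byte-stable for a fixed dataset.
- **Synthetic scenarios** (`miread.fixtures`): a seeded generator for four
  realistic scenario shapes (long trap series; wide table with a
  sub-location field; tick drags with genus-only larvae; mouse
  ectoparasite screening) with negative-binomial, seasonally forced
  counts, and a fault injector that applies one minimal, ledgered
  corruption per rule class for validator testing.

## Worked example

Generate a small trap-series CSV with its metadata sidecar, then validate:

```sh
$ miread fixture long_trap --seed 1 --n-events 4 --out demo.csv
$ head -2 demo.csv
SampleID,Sample Name,Start Time,End Time,Latitude,Longitude,Locality,Collection Method,Attractants,Collection Area,Taxon Rank,Taxon Name,Sex,Life Stage,Value,Unit
E0001,,2016-04-06 18:00,2016-04-07 06:00,41.5880,-93.5800,Hickory Grove research farm,New Jersey light trap,light,1 trap night,species,Aedes aegypti,female,adult,14,individuals

$ miread validate demo.csv --metadata demo.metadata.json
compliant: yes
```

Inject two faults (an ambiguous date and a blanked identification method)
and the validator pinpoints both; the exit code becomes 1:

```sh
$ miread fixture long_trap --seed 1 --n-events 4 --out demo2.csv \
    --faults R3_DATE,M3_IDENTIFICATION_METHOD
$ miread validate demo2.csv --metadata demo2.metadata.json
compliant: no
ERROR   M3_IDENTIFICATION_METHOD [column 'Species Identification Method']: required metadata field 'Species Identification Method' is missing or empty
ERROR   R3_DATE [row 1, column 'Start Time']: two-digit year: two-digit year in '04/06/17'
```

Convert the clean file to a Darwin Core Archive:

```sh
$ miread convert demo.csv --to dwca --out demo.zip --metadata demo.metadata.json
```

`demo.zip` contains `meta.xml`, `eml.xml`, `event.txt` and
`occurrence.txt`; the first event row reads

```
E0001  2016-04-06/2016-04-07  18:00/06:00  41.5880  -93.5800  WGS84  Hickory Grove research farm  New Jersey light trap; attractant: light  1 trap night
```

i.e. the overnight trap run became an ISO date interval with an
`eventTime` interval, and the record `Aedes aegypti, 14 individuals`
became occurrence `E0001:1` with `occurrenceStatus=present`.

The same pipeline is available as a library; `miread.validate(dataset)`
returns the report object, `miread.long_to_wide` / `miread.wide_to_long`
convert layouts, and `miread.write_dwca` writes archives.

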