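# Methods

## The data model and its assumptions

A submission separates into resource metadata and data records. The data
side is event-centric: a *sampling event* is one collection act with a
start and end timestamp (date mandatory, clock time optional; equal
endpoints model cross-sectional one-off sampling), a location, a method,
optional attractants and effort/area, and an ordered set of named
free-text attributes for anything else (sub-location, host sex, ...).
An *abundance record* is one observed quantity for one
(taxon, sex, life stage, unit) class within an event. The identity of a
record — its *canonical key* — is exactly that tuple plus the event
reference, case-folded; the value is deliberately excluded so that
duplicate reporting of one cell is detectable.

Only raw quantities are modelled. Relative abundances are derived values;
a unit that declares one ("relative abundance", "% of catch") is a
compliance error, because derived values cannot be safely re-aggregated
(naive means over skewed count data being the canonical mistake).

Taxonomic assignments carry the most precise rank actually asserted:
genus-only records are first-class (immatures frequently cannot be keyed
further), and token count determines rank when a rank column is absent
(1 = genus, 2 = species, 3 = subspecies). An epithet is never guessed,
and single-letter dotted genus abbreviations are rejected outright.

Coordinates are decimal degrees, WGS84 assumed unless the metadata names
another datum. The source *text* of dates and coordinates is retained
alongside the parsed values, because two rules are judged on the text:
date-format ambiguity and coordinate precision.

### Strict construction, lenient ingestion

Models reject invariant-violating combinations (latitude 95, start after
end, negative counts) at construction. Files, however, contain exactly
such values, and a validator that crashes on them is useless. Ingestion
and the fault injector therefore build instances through the
non-validating construction path; every construction invariant is
re-checked by the validator as a finding (D3, D4, ...). The strict path
is for programmatic producers; the lenient path exists so problems can be
*reported*.

## The rule engine

Every rule runs exactly once per validation; findings are ordered by
(rule id, row, column), so identical datasets serialize to byte-identical
reports. Severity policy: rules checkable without heuristics — missing
mandatory metadata (M1–M5), missing units (M6), ambiguous/two-digit-year/
unparseable dates (R3), external-key-only locations or coded taxa (R2),
heading or ditto rows (R5), duplicate keys (D1), relative-abundance units
(D2), out-of-range coordinates (D3), inverted time order (D4), and a
contradicted obfuscation statement (R6) — are errors. Heuristic rules —
abbreviation detection (R1), encoding fallback and unbound columns (R4),
undeclared low precision (R6), non-ASCII field names (R7) — are warnings:
they flag likely problems without being provable from the file alone.
Compliance is the absence of errors; warnings never block.

Details worth knowing:

- **R1** flags dotted tokens and short all-caps tokens in column names and
  method/attractant values, exempting measurement units and a small
  lexicon of established trap names ("CDC light trap", "New Jersey light
  trap", ...) whose sigla are proper names.
- **R3** is judged on the raw text via the same grammar the parser uses.
  All-numeric dates with both fields ≤ 12 are irrecoverably ambiguous
  (error) — except when day equals month, where both slot assignments
  coincide and the date parses (with the numeric-month warning). A field
  in 13..31 forces the day slot: the date parses and is flagged as a
  warning, since the format remains discouraged. Two-digit years always
  error. Year-first numeric forms (`2017/06/04`) parse with a warning.
- **R5** flags rows where only the first cell is populated (subsection
  headings) and rows carrying data without a date in the bound date
  column (interpretable only by "ditto" from the row above).
- **R6** parses the declared obfuscation statement for a quantitative
  precision ("rounded to 0.1°", "2 decimal places"). Coordinates with
  fewer than 2 decimals and no statement draw a warning; coordinates
  *finer* than a declared rounding contradict the declaration and error.
- **Duplicate keys are reported, never collapsed**: aggregation is the
  submitter's decision, not the validator's.

## Layout conversion

Canonical form is long. Wide tables use the column convention
`Taxon name[, sex][, stage] (unit)`; single-token names must be a known
arthropod genus, which is what distinguishes a taxon column from
`Temp (°C)`. Generated wide tables order taxon columns alphabetically by
(name, stage, sex, unit) so output is diffable and byte-stable.

Empty wide cells are resolved by the declared absence policy:
`explicit_zeros` and `absent_means_unknown` materialize no record (the
latter with a per-cell note), `absent_means_zero` materializes a zero;
with no declared policy every empty cell is flagged. Zeros asserted by
the source are kept as records end-to-end — the zero-vs-unknown
distinction survives any number of pivots, and total counts are conserved
exactly (integer arithmetic on text-round-tripped values).

Composite records (a mixed pool with per-class component counts) split
into one record per life stage/sex sharing a sample name; a composite
*without* per-class counts is kept as-is with a note — apportionment is
never invented. Sample names are linking labels only; the sample id
remains the sole key.

## Darwin Core export

Event core with an occurrence extension, because abundance data is
sampling-event-centric. The concept → term routing is declared in two
module-level tables (7 metadata routings, 12 data routings) that tests
introspect for coverage. Choices:

- Same-day start/end collapses `eventDate` to a single date, with clock
  times in `eventTime` (as an interval when both are present).
- `organismQuantity`/`organismQuantityType` duplicate
  `sampleSizeValue`/`sampleSizeUnit` for aggregator friendliness — an
  extension beyond the minimum routing.
- "Additional sample information" is emitted identically to both
  `fieldNotes` and `eventRemarks` (no split criterion exists).
- `occurrenceStatus` is `absent` iff the value is 0.
- The archive refuses non-compliant datasets unless forced; the forced
  path drops events with no parseable date (they cannot become event
  rows) together with their records.
- Byte stability: fixed member order, fixed zip timestamps, UTF-8,
  tab-delimited, Unix newlines.

## The synthetic scenarios

The generator emulates the four shapes a validator must handle: a weekly
long-format light-trap series; the same kind of data in wide format with
a sub-location attribute; tick drags reporting adult/nymph/larva
independently (larvae at genus rank) linked by a sample name; and mouse
ectoparasite screening with host species/sex as event attributes. Counts
are negative-binomial with a sinusoidal seasonal mean,
`mu(t) = level · (1 + A · sin(2π(doy − 120)/365))`, defaults level 20,
amplitude 0.6, dispersion 2.0, weekly events from early April — an
overdispersed temperate-summer series of realistic magnitude. The
defaults (12 events, 3 taxa) keep test datasets small while exercising
every structural feature.

What the generator does **not** emulate: messy real-world headers in
other languages, mixed encodings, multi-sheet workbooks, free-text value
columns ("too many to count"), or taxonomic misspellings. Passing tests
therefore demonstrate correctness of the rules and conversions on
well-formed and minimally corrupted inputs, not robustness to arbitrary
field files.

The fault injector applies one minimal corruption per requested rule
class and returns a ledger of exactly what it did, enabling recall
testing: every injected class must be reported at its injected location.
Record-mutating faults are applied before the duplicate-record fault so a
later mutation cannot destroy an already-ledgered duplicate key;
event-targeted faults draw distinct events. After dataset-level faults
the attached raw table is regenerated from the corrupted dataset, so the
table the structural rules (and any written fixture CSV) see is the same
data the record-level rules see.

## Numerical and degenerate-input choices

- Dates: months are matched against English names/abbreviations;
  seconds are optional; invalid calendar dates (30 February) are
  unparseable rather than ambiguous.
- Values serialize as integers when integral, `repr` otherwise, so
  text round trips are exact.
- An empty dataset with valid metadata exports an archive with header
  rows and EML only.
- Events without records still serialize (a trap night that caught
  nothing but asserted zeros elsewhere remains a documented event).
- Delimiter sniffing picks the most frequent of comma/tab/semicolon in
  the header line; UTF-8 is attempted first, latin-1 is the recorded
  fallback.

## Known limitations

- No taxonomic name resolution against external backbones, and no
  georeferencing of textual localities (both out of scope by design).
- The abbreviation and site-code detectors are heuristic; their
  warnings/errors can misfire on unusual but legitimate vocabulary —
  the trap lexicon and unit whitelist are extension points.
- Wide headers with commas inside taxon names are not representable in
  the column convention.
- The language rule checks field names for non-ASCII text only; it does
  not attempt language identification of values.
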