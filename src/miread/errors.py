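"""Exception hierarchy.

Exceptions are reserved for conditions under which a dataset cannot be
represented at all (unreadable files, unresolvable mappings, impossible
conversions).  Quality problems in data that *can* be represented are never
exceptions — they become findings in a :class:`~miread.validate.ValidationReport`.
"""


class MireadError(Exception):
    """Base class for all errors raised by this package."""


# -- schema ------------------------------------------------------------------

class EmptyName(MireadError):
    """A taxonomic name was requested from blank tokens."""


class AbbreviationError(MireadError):
    """A scientific name contains an unexpanded abbreviation (e.g. ``A.``)."""


# -- ingest ------------------------------------------------------------------

class NotMachineReadable(MireadError):
    """Input is not a machine-readable delimited text file (PDF, binary, ...)."""


class RaggedTable(MireadError):
    """Rows of a delimited table do not all have the header's arity."""


class DuplicateHeader(MireadError):
    """Two columns share a name after whitespace folding."""


class AmbiguousLayout(MireadError):
    """Neither the long- nor the wide-layout signature matches; an explicit
    column mapping is required."""


class AmbiguousDate(MireadError):
    """An all-numeric date whose day and month slots cannot be told apart."""


class TwoDigitYear(MireadError):
    """A date with a two-digit year."""


class UnparseableDate(MireadError):
    """Text that matches no accepted date form or names an invalid date."""


class MissingConceptColumn(MireadError):
    """The table binds no column for an indispensable concept (date, value)."""


# -- normalize / export ------------------------------------------------------

class DuplicateKey(MireadError):
    """Two records collapse onto one canonical (event, taxon, sex, stage,
    unit) key during canonicalization."""


class ValueNotSplittable(MireadError):
    """A composite count carries no per-class values to apportion."""


class UnmappableEvent(MireadError):
    """A sampling event has no parseable date and cannot become a Darwin
    Core event row."""


class NotCompliant(MireadError):
    """Export refused because the dataset has error-severity findings."""


# -- fixtures ----------------------------------------------------------------

class InapplicableFault(MireadError):
    """A requested fault class cannot be injected into the given dataset."""
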