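"""Exception hierarchy shared across the package."""


class DecontaxError(Exception):
    """Base class for all package errors."""


class FormatError(DecontaxError):
    """Malformed input: bad taxdump/Kraken/FASTA/FASTQ syntax or empty fields."""


class TaxonomyStructureError(DecontaxError):
    """Structurally invalid taxonomy: missing parent, cycle, or no/multiple roots."""


class TaxonLookupError(DecontaxError):
    """A taxon name or ID could not be resolved, or resolved ambiguously."""


class PairingError(DecontaxError):
    """Paired FASTQ streams disagree in record count or read IDs."""


class UsageError(DecontaxError):
    """Operation invoked with inconsistent arguments (mixed samples, missing totals...)."""


class SpecError(DecontaxError):
    """A synthetic community specification is internally inconsistent."""


class DegenerateTableError(DecontaxError):
    """A contingency table has a zero row or column total."""


class UndefinedMetricError(DecontaxError):
    """A metric's denominator is zero (no truth positives / nothing removed)."""
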