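"""Exception types shared across the package."""


class OptionValueError(Exception):
    """Base class for all package-specific errors."""


class TreeFormatError(OptionValueError):
    """A tree file could not be parsed; names the offending tree index."""


class EnsembleConsistencyError(OptionValueError):
    """Trees in an ensemble do not share an identical tip set."""


class SchemaError(OptionValueError):
    """A species table is missing required columns or has malformed values."""


class VocabularyError(OptionValueError):
    """A categorical value falls outside its closed vocabulary."""


class ReconciliationError(OptionValueError):
    """Tree tips and species-table rows cannot be matched under strict policy."""


class DegenerateSetError(OptionValueError):
    """A null distribution is degenerate (zero variance), e.g. all or no tips."""


class FeasibilityError(OptionValueError):
    """A constrained sampling request cannot be satisfied by the universe."""


class CoverageError(OptionValueError):
    """A score map does not cover every species it is asked to rank."""
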