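"""Exception hierarchy.

Exit-code mapping used by the CLI: UsageError/ConfigError -> 2, everything
else derived from MGNetError -> 1.
"""


class MGNetError(Exception):
    """Base class for all package errors."""


class FormatError(MGNetError):
    """A file does not conform to its declared format."""


class EmptyInputError(MGNetError):
    """An input that must be non-empty was empty."""


class InputError(MGNetError):
    """A value violates a documented precondition or invariant."""


class DataError(MGNetError):
    """Input data is structurally invalid (e.g. a cyclic ontology)."""


class LookupError_(MGNetError):
    """An identifier is not present in the structure being queried."""


class ScoreError(MGNetError):
    """An association score is undefined for the given profiles."""


class FitError(MGNetError):
    """A model fit is undefined for the given data."""


class UsageError(MGNetError):
    """The caller asked for an unknown mode/format/class."""


class ConfigError(MGNetError):
    """A configuration is missing keys or is infeasible."""
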