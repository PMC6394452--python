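"""Exception hierarchy for eegdecode.

All library errors derive from :class:`EegDecodeError` so callers can catch
one base class. Subclasses distinguish malformed files, invalid analysis
parameters, and data that is structurally valid but unusable (e.g. an empty
condition).
"""


class EegDecodeError(Exception):
    """Base class for all eegdecode errors."""


class FormatError(EegDecodeError):
    """A file does not follow the expected on-disk layout."""


class ValidationError(EegDecodeError):
    """A dataset violates a structural invariant (e.g. ragged dimensions)."""


class ConfigurationError(EegDecodeError):
    """Analysis parameters are inconsistent or out of range."""


class DataError(EegDecodeError):
    """Data is structurally valid but unusable for the requested analysis."""


class DegenerateDataError(DataError):
    """A computation is undefined on this data (e.g. zero projected variance)."""


class ConditionLookupError(EegDecodeError, KeyError):
    """A requested run or condition index does not exist."""

    def __str__(self) -> str:  # KeyError quotes its message; undo that
        return Exception.__str__(self)
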