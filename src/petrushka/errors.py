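"""Exception hierarchy.

All package errors derive from :class:`PetrushkaError`; argument-validation
errors additionally derive from :class:`ValueError` so callers relying on
standard-library semantics keep working.
"""


class PetrushkaError(Exception):
    """Base class for all errors raised by this package."""


class InvalidArgumentError(PetrushkaError, ValueError):
    """An argument is outside its documented domain."""


class NetworkError(PetrushkaError):
    """A treatment network is disconnected or otherwise unusable."""

    def __init__(self, message: str, components=None):
        super().__init__(message)
        self.components = components or []


class FormatError(PetrushkaError, ValueError):
    """A data file does not match its documented format."""


class MonotonicityError(FormatError):
    """A crosswalk table is not monotone non-decreasing."""


class DegenerateInputError(PetrushkaError, ValueError):
    """Input has too little variation for the requested operation."""


class DegenerateOutcomeError(DegenerateInputError):
    """Outcome is constant where variation is required (e.g. binary fit)."""


class UnimputableVariableError(PetrushkaError):
    """A variable is 100% missing and cannot be imputed."""


class IdentifiabilityError(PetrushkaError):
    """Model parameters are not identifiable from the supplied data."""


class BoundaryError(PetrushkaError, ValueError):
    """A probability sits exactly on {0, 1} where an open interval is required."""


class ConfigurationError(PetrushkaError):
    """A pipeline component is missing or inconsistent; names the component."""


class EmptyCandidateError(PetrushkaError):
    """Every drug was excluded; nothing left to recommend."""


class ConsistencyError(PetrushkaError):
    """Two artifacts that must agree (e.g. ranking vs predictions) do not."""


class DataError(PetrushkaError, ValueError):
    """Non-finite or otherwise unusable numeric input."""
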