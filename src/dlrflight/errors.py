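"""Exception hierarchy shared across the package."""


class DlrFlightError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DlrFlightError):
    """A parameter or option is outside its documented domain."""


class SchemaError(DlrFlightError):
    """A file does not conform to the documented table schema."""


class DataError(DlrFlightError):
    """Well-formed file, but the values violate an invariant (e.g. time order)."""


class InsufficientDataError(DlrFlightError):
    """Too few samples to compute the requested quantity."""


class DegeneratePathError(DlrFlightError):
    """Net displacement too small for a path-ratio metric (e.g. closed loop)."""


class EmptyResultError(DlrFlightError):
    """An operation removed or excluded every sample."""
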