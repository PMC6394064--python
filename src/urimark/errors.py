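"""Exception hierarchy for the urimark pipeline.

Every stage raises a distinct subclass so that pipeline drivers can report
the failing stage by name.
"""


class UrimarkError(Exception):
    """Base class for all urimark errors."""


class ConfigurationError(UrimarkError):
    """A simulation or run configuration is invalid; the message names the field."""


class ValidationError(UrimarkError):
    """Input data violate a documented precondition."""


class ParseError(ValidationError):
    """A file could not be parsed; the message carries the line number when known."""


class HarmonizationError(UrimarkError):
    """Platform pooling failed (e.g. empty feature intersection)."""


class ContrastError(UrimarkError):
    """A differential-expression contrast cannot be formed."""


class EstimationError(UrimarkError):
    """Too little data to estimate the variance prior."""


class ScreeningError(UrimarkError):
    """Candidate screening is missing a required contrast result."""
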