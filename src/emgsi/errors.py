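"""Exception hierarchy.

Two broad families matter downstream: validation errors (malformed inputs,
bad parameters — the caller's fault) and data errors (well-formed inputs
that cannot support the requested computation). The CLI maps them to
distinct exit codes.
"""


class EmgsiError(Exception):
    """Base class for all package errors."""


class ValidationError(EmgsiError, ValueError):
    """Input violates a structural invariant (montage, window ordering, range)."""


class MontageError(ValidationError):
    """Channel set does not form the canonical 10-channel montage."""


class ParseError(ValidationError):
    """A file could not be parsed; carries location information in the message."""


class ParameterError(ValidationError):
    """A configuration parameter is out of its admissible range."""


class DataError(EmgsiError):
    """Valid input that cannot support the requested computation."""


class ExclusionError(DataError):
    """Artifact exclusions left no usable repetition for some channel/task."""


class DegenerateReferenceError(DataError):
    """A prototype response vector has zero magnitude and cannot anchor a similarity score."""
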