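"""Exception hierarchy shared across the package."""


class EntrackError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(EntrackError, ValueError):
    """A parameter is outside its documented range."""


class AlignmentError(EntrackError, ValueError):
    """Two inputs disagree in rate, window, length, or ordering."""


class DegenerateEnvelopeError(EntrackError, ValueError):
    """The rectified envelope derivative sums to zero; unit-area
    normalization is undefined."""


class PairingError(EntrackError, ValueError):
    """A non-matching stimulus pairing cannot be constructed."""


class SchemaError(EntrackError, KeyError):
    """A data container is missing required datasets or attributes."""


class UndefinedCorrelationError(EntrackError, ValueError):
    """A rank correlation is undefined (constant input)."""
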