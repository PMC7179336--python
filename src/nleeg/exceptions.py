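"""Exception hierarchy for the pipeline.

All package errors derive from :class:`NleegError` so callers can catch one
base class; the CLI maps validation-type errors to exit code 2 and I/O
errors to exit code 3.
"""


class NleegError(Exception):
    """Base class for all package errors."""


class ValidationError(NleegError):
    """Input data violates a documented invariant (bad events, bad spec...)."""


class FormatError(NleegError):
    """A file is not a well-formed instance of its declared format."""


class UnsupportedLayoutError(FormatError):
    """The file is valid but uses a layout the package does not support
    (e.g. mixed sampling rates among selected EDF channels)."""


class IntegrityError(ValidationError):
    """Tabular data violates a uniqueness/key constraint."""


class ParameterError(NleegError):
    """A numeric parameter is outside its valid domain."""


class DegenerateInputError(NleegError):
    """The input is formally valid but carries no usable signal
    (constant series, zero variance, all-zero envelope)."""


class PairingError(ValidationError):
    """Paired statistics requested on unpaired subject sets."""


class DegenerateEnvelopeWarning(UserWarning):
    """Envelope has no oscillatory energy; mean frequency reported as 0."""
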