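"""Exception hierarchy shared across the toolkit.

Validation errors signal bad user input (CLI exit code 1); structural errors
signal inconsistent in-memory objects (CLI exit code 2).
"""


class RfdsegError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(RfdsegError, ValueError):
    """Input violates a documented precondition."""


class StructuralError(RfdsegError, ValueError):
    """Two objects that must be aligned (shapes, lengths) are not."""


class DegenerateInputError(ValidationError):
    """Input is technically valid but admits no meaningful result
    (e.g. fewer distinct brightness values than cluster centers)."""


class UndefinedMetricError(RfdsegError, ValueError):
    """A surface-distance metric was requested for an empty region."""
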