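"""Exception hierarchy shared across the package."""


class BatdynError(Exception):
    """Base class for all package errors."""


class ValidationError(BatdynError, ValueError):
    """Input violates a documented precondition or invariant."""


class GapError(ValidationError):
    """A daily series has a hole; the message names the first gap."""


class RangeError(ValidationError):
    """Requested date range is not covered by the available records."""


class FitError(BatdynError, RuntimeError):
    """An optimisation or regression failed to converge."""
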