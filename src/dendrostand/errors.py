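"""Exception hierarchy shared across the pipeline stages."""


class DendrostandError(Exception):
    """Base class for all package errors."""


class ParseError(DendrostandError):
    """A file could not be parsed; the message names the offending line."""


class IntegrityError(DendrostandError):
    """Structurally valid input that violates an internal consistency rule
    (non-contiguous decades, duplicate year/month keys, ...)."""


class ValidationError(DendrostandError):
    """A value violates a domain invariant (negative DBH, Tmin > Tmax, ...)."""


class CoverageError(DendrostandError):
    """A requested period or window is not covered by the available data."""


class DegenerateInputError(DendrostandError):
    """Input is formally valid but degenerate for the requested operation
    (all-zero ring widths, coincident stems, zero-variance column, ...)."""


class ConvergenceError(DendrostandError):
    """An iterative fit failed to converge and no fallback applies."""
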