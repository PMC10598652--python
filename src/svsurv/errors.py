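"""Exception hierarchy: validation errors (bad input, exit 1) vs estimation
failures (exit 2), plus format errors for unparseable files."""


class SvsurvError(Exception):
    """Base class for all package errors."""


class ValidationError(SvsurvError):
    """Input violates a documented precondition or contract."""


class FormatError(ValidationError):
    """A file could not be parsed in its declared format."""


class EstimationError(SvsurvError):
    """A statistical fit failed in a way that is not a flagged result."""
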