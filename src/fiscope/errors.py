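"""Exception hierarchy.

Every error raised by fiscope derives from :class:`FiscopeError` so callers
can catch pipeline failures with a single except clause while still
distinguishing configuration mistakes from malformed input files.
"""


class FiscopeError(Exception):
    """Base class for all fiscope errors."""


class ConfigurationError(FiscopeError):
    """Invalid simulation or pipeline configuration."""


class FormatError(FiscopeError):
    """Malformed input file (RCC lane file, count matrix, annotation)."""


class DomainError(FiscopeError):
    """Input outside the mathematical domain of an operation."""


class EmptySignatureError(FiscopeError):
    """No transcript passed the significance gate when building weights."""


class DegenerateScoreError(FiscopeError):
    """Score distribution has zero spread; standardization undefined."""
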