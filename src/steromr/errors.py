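"""Exception hierarchy shared across the pipeline."""


class SteromrError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SteromrError, ValueError):
    """Malformed input file: missing columns, asymmetry, out-of-range values."""


class DuplicateSnpError(FormatError):
    """Duplicate variant identifier where uniqueness is required."""


class PreconditionError(SteromrError, ValueError):
    """An operation's documented precondition is violated."""


class InsufficientInstrumentsError(PreconditionError):
    """Fewer instruments than the method's minimum."""


class ConfigError(SteromrError, ValueError):
    """Invalid simulation or pipeline configuration."""


class DegenerateCorrectionError(SteromrError, RuntimeError):
    """Outlier correction would remove every instrument."""
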