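"""Exception hierarchy shared across the pipeline."""


class CvempError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CvempError):
    """A generator or analysis configuration violates its invariants."""


class InsufficientDataError(CvempError):
    """Fewer epochs or sequences are available than the operation requires."""


class UndefinedResponseError(CvempError):
    """A response-level transform was requested for a non-positive amplitude."""


class ProtocolError(CvempError):
    """Input data do not follow the recording protocol (e.g. no initial
    maximum-level sequence to anchor trough tracking)."""


class SchemaError(CvempError):
    """A CSV/JSON artifact is missing required columns or metadata."""
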