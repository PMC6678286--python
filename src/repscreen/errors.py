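"""Exception hierarchy shared across the pipeline stages."""


class RepscreenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RepscreenError, ValueError):
    """A simulation or run configuration violates one of its bounds."""


class InputError(RepscreenError, ValueError):
    """Invalid data handed to an operation (bad doses, mismatched pairing...)."""


class ParseError(RepscreenError, ValueError):
    """A file does not conform to its declared format."""


class EmptySignatureError(RepscreenError):
    """No probe survives the selection thresholds."""


class QueryError(RepscreenError):
    """A connectivity query cannot be executed (empty signature, unknown drug)."""


class ScreeningError(RepscreenError):
    """The consensus screen cannot be assembled (a method produced nothing)."""


class DegenerateFitError(RepscreenError):
    """A median-effect fit is degenerate (zero slope)."""
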