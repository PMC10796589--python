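"""Exception hierarchy shared across the package."""


class DinetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(DinetError):
    """A file does not conform to the documented dialect (e.g. missing column)."""


class ValidationError(DinetError):
    """A record violates a domain invariant (carries row/line context where known)."""


class ParameterError(DinetError):
    """A parameter is outside its natural range."""


class ConsistencyError(DinetError):
    """Two inputs that must share a namespace (e.g. merged PIR nodes) do not."""


class PlacementError(DinetError):
    """A planted feature cannot be placed (e.g. PIR too short to host a motif)."""


class ScoringError(DinetError):
    """A sequence window cannot be scored (e.g. ambiguous base)."""


class DegenerateInputError(DinetError):
    """Input admits no meaningful answer (e.g. all patients identical for k-means)."""
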