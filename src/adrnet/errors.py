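"""Exception hierarchy shared across the package."""


class AdrnetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(AdrnetError, ValueError):
    """An input table or ontology file violates the expected format."""


class StructuralError(AdrnetError, ValueError):
    """A parsed object violates a structural invariant (e.g. cyclic ontology)."""


class MetricError(AdrnetError, ValueError):
    """A performance metric is undefined for the given inputs."""
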