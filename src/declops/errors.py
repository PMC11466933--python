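"""Exception hierarchy for the ops framework.

Everything raised deliberately by the framework derives from :class:`OpsError`,
so callers (and the CLI) can distinguish framework failures from genuine bugs.
"""


class OpsError(Exception):
    """Base class for all framework errors."""


class DescriptorError(OpsError):
    """A YAML descriptor could not be parsed or violates the schema."""


class ValidationError(OpsError):
    """An OpInfo or ParameterSpec violates a structural invariant."""


class IndexingError(OpsError):
    """A doc-comment op annotation was present but could not be parsed."""


class TypeLookupError(OpsError):
    """A type name is not registered in the type registry."""


class AmbiguousTypeError(OpsError):
    """A runtime value is recognized by two unrelated types at equal depth."""


class OpMatchError(OpsError):
    """No op satisfied a request; the message carries per-routine near-misses."""


class DependencyCycleError(OpMatchError):
    """Dependency resolution revisited the same (op, shape) pair."""


class ResolutionDepthError(OpMatchError):
    """Dependency resolution exceeded the depth cap."""


class ParameterError(OpsError):
    """An op was invoked with an out-of-domain parameter value."""


class DimensionError(OpsError):
    """Array/image shapes are incompatible for the requested operation."""


class OpExecutionError(OpsError):
    """An op implementation raised; wraps the cause with the InfoTree digest."""

    def __init__(self, message: str, digest: str | None = None):
        super().__init__(message)
        self.digest = digest
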