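"""Exception hierarchy shared across the package."""


class RiverBodError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(RiverBodError, ValueError):
    """Raised when input data violate a documented invariant."""


class TopologyError(ValidationError):
    """Raised when the downstream graph is not a forest (cycle, braid...)."""


class ReferenceError_(ValidationError):
    """Raised when a downstream_id points at a subbasin that does not exist."""


class ConfigurationError(RiverBodError):
    """Raised when no valid configuration route exists for a computation."""
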