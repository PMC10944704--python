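"""Exception types shared across the package."""


class CtoccError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CtoccError):
    """Raised when data violate a model or format invariant."""


class ConfigurationError(CtoccError):
    """Raised when a configuration references missing columns, files, or keys."""


class FittingError(CtoccError):
    """Raised when maximum-likelihood optimization fails from every start."""
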