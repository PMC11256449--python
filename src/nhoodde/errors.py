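"""Typed exceptions used across the package."""


class NhoodDEError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(NhoodDEError, ValueError):
    """A user-supplied parameter is outside its valid range."""


class InvalidInputError(NhoodDEError, ValueError):
    """Input data violates a structural invariant (NaN coords, shape mismatch...)."""


class ConfigurationError(NhoodDEError, ValueError):
    """Missing or inconsistent configuration (e.g. absent metadata column)."""
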