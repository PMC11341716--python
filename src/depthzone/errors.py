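"""Exception types shared across the package."""


class DepthZoneError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(DepthZoneError):
    """An input table is missing a required column or has the wrong shape."""


class ValidationError(DepthZoneError):
    """A value violates a data invariant (negative depth, zero count, ...)."""


class ContractError(DepthZoneError):
    """Two objects that must line up (rows vs. coefficients, bins vs. truth) do not."""


class ConfigurationError(DepthZoneError):
    """A configuration value is out of its admissible range."""
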