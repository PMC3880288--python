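"""Exception types shared across the package."""


class ConfigError(ValueError):
    """Invalid configuration value or unknown configuration key."""


class GridError(ValueError):
    """Grids or fields that do not live on the same lattice."""


class StabilityError(RuntimeError):
    """Explicit finite-difference step attempted beyond its stability bound."""


class VesselFileError(ValueError):
    """Malformed vessel edge-list file; message names the offending line."""


class DomainError(ValueError):
    """Arguments outside the physical domain of a model function."""
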