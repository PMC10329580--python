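"""Exception hierarchy for the navigation pipeline."""


class HybridNavError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(HybridNavError, ValueError):
    """Invalid configuration value (negative amplitude, oversubscribed grid, ...)."""


class MissingDataError(HybridNavError, ValueError):
    """An operation received an empty input that it requires."""


class InsufficientOrbsError(HybridNavError):
    """Fewer than three orb detections; the pivot center cannot be estimated."""


class UnderdeterminedFitError(HybridNavError):
    """Too few samples (or a rank-deficient design) for the requested fit."""


class DegenerateGeometryError(HybridNavError):
    """Degenerate geometric configuration: parallel rays, collinear point sets,
    or a point at/behind the X-ray source in pinhole mode."""
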