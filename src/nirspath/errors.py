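"""Exception types shared across the pipeline."""


class NirspathError(Exception):
    """Base class for package errors."""


class ConfigurationError(NirspathError):
    """Invalid configuration or distribution specification."""


class GeometryError(NirspathError):
    """Degenerate or inconsistent head geometry."""


class ResolutionError(GeometryError):
    """Voxel size too coarse to resolve the thinnest tissue layer."""


class DomainError(NirspathError):
    """Input outside the mathematical domain of an operation."""


class InsufficientDataError(NirspathError):
    """Too few usable observations for a fit."""


class FitError(NirspathError):
    """Iterative fit failed to converge."""
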