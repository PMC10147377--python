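"""Exception types shared across the package."""


class OcquantError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(OcquantError, ValueError):
    """Degenerate or self-intersecting geometry (polygon, axis, ...)."""


class PlacementError(OcquantError, RuntimeError):
    """Object placement failed after the bounded number of retries."""


class ConfigError(OcquantError, ValueError):
    """Invalid configuration: unknown keys, missing channels, bad thresholds."""


class ParameterError(OcquantError, ValueError):
    """Parameter outside its documented domain."""


class InsufficientDataError(OcquantError, ValueError):
    """Too few observations (or degenerate data) for the requested statistic."""


class FormatError(OcquantError, ValueError):
    """Malformed input file (SWC, TIFF sidecar, matrix triplet...)."""


class ResolutionError(OcquantError, ValueError):
    """Requested structure is below the voxel resolution."""
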