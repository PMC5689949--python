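"""Exception hierarchy for the dosimetry pipeline."""


class VoxdoseError(Exception):
    """Base class for all package errors."""


class ConfigurationError(VoxdoseError):
    """A spec, config file, or table is internally inconsistent."""


class GeometryError(VoxdoseError):
    """An organ primitive does not fit inside the body or the grid."""


class EmptyOrganError(VoxdoseError):
    """An operation was asked about an organ with zero voxels."""


class ValidationError(VoxdoseError):
    """A numeric argument violates its contract (negative activity, ...)."""


class GridMismatchError(VoxdoseError):
    """Two lattices that must share a grid do not."""


class EnergyOutOfRangeError(VoxdoseError):
    """Requested energy lies outside the tabulated stopping-power domain."""
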