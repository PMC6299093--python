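"""Exception hierarchy shared across the package."""


class DsbquantError(Exception):
    """Base class for all package-specific errors."""


class FormatError(DsbquantError):
    """An input file does not match the expected dialect/columns."""


class GeometryError(DsbquantError):
    """An ROI geometry is invalid (self-intersecting polygon, ...)."""


class EmptyROIError(DsbquantError):
    """An ROI has zero area (e.g. an all-zero mask)."""


class PlacementError(DsbquantError):
    """A cluster cannot be placed anywhere inside the ROI."""


class AlignmentError(DsbquantError):
    """Two bin tracks do not share identical bin coordinates."""


class ParameterError(DsbquantError):
    """A numeric parameter violates its precondition."""


class ConfigError(DsbquantError):
    """A run configuration is schema-invalid."""
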