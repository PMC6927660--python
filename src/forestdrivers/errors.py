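"""Exception types shared across the pipeline."""


class ForestDriversError(Exception):
    """Base class for all package errors."""


class ValidationError(ForestDriversError, ValueError):
    """Invalid input data or configuration."""


class CrsMismatchError(ValidationError):
    """Two geospatial layers do not share a coordinate reference system."""


class AlignmentError(ValidationError):
    """Two rasters do not share grid origin, cell size or shape."""


class UnfittableLocationError(ForestDriversError):
    """A local model cannot be fitted at this location (e.g. the dependent
    variable is single-valued in the neighborhood)."""
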