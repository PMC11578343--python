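"""Exception types shared across the package."""


class NpsRheoError(Exception):
    """Base class for all package errors."""


class ConfigError(NpsRheoError):
    """Invalid geometry, pipeline, or run configuration."""


class GeometryError(NpsRheoError):
    """Physically impossible geometric request (e.g. cell larger than pore)."""


class UnstrainedCellError(NpsRheoError):
    """Cell too small to contact both walls of a contraction zone."""


class SaturationError(NpsRheoError):
    """Blockage outside the validity range of the sizing correction."""


class FitError(NpsRheoError):
    """Least-squares fit could not be performed (rank-deficient basis)."""


class EmptyResultsError(NpsRheoError):
    """A pipeline stage produced no usable cells."""
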