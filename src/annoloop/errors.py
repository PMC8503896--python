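"""Exception types shared across the package."""


class AnnoloopError(Exception):
    """Base class for all package-specific errors."""


class DimensionError(AnnoloopError, ValueError):
    """Raised for non-positive or otherwise unusable raster dimensions."""


class MaskFormatError(AnnoloopError, ValueError):
    """Raised when a persisted annotation mask uses values outside the 3-class palette."""


class CoverageError(AnnoloopError, ValueError):
    """Raised when patch predictions fail to cover every tile pixel during reassembly."""


class ConfigError(AnnoloopError, ValueError):
    """Raised for invalid model or run configurations."""


class GateError(AnnoloopError, RuntimeError):
    """Raised when training is requested with fewer annotated patches than the gate allows."""


class StageError(AnnoloopError, RuntimeError):
    """Raised when an operation requires a model stage it has not reached."""


class DataError(AnnoloopError, ValueError):
    """Raised for empty or degenerate data sets."""


class ShapeError(AnnoloopError, ValueError):
    """Raised when array shapes are incompatible."""
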