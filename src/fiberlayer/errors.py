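"""Exception hierarchy.

Every error the pipeline raises deliberately derives from
:class:`FiberlayerError`, so callers (and the CLI) can distinguish
user/input problems from genuine bugs.
"""


class FiberlayerError(Exception):
    """Base class for all errors raised by fiberlayer."""


class InvalidParameterError(FiberlayerError, ValueError):
    """A configuration value violates a documented precondition."""


class InvalidGeometryError(FiberlayerError, ValueError):
    """A section geometry does not fit the requested raster."""


class GenerationFailureError(FiberlayerError, RuntimeError):
    """The synthetic generator could not honour its constraints."""


class MissingLayerError(FiberlayerError, KeyError):
    """A requested anatomical layer is absent from the mask."""


class PlacementFailureError(FiberlayerError, RuntimeError):
    """ROI placement failed for every sector of a layer."""


class CalibrationMismatchError(FiberlayerError, ValueError):
    """Two rasters that must share a grid/calibration do not."""


class NoDataError(FiberlayerError, ValueError):
    """An operation received an empty input where data is required."""


class DegreesOfFreedomError(FiberlayerError, ValueError):
    """Too few observations for the requested statistical test."""


class UndefinedCorrelationError(FiberlayerError, ValueError):
    """Pearson correlation is undefined (a constant variate)."""


class InvalidInputError(FiberlayerError, ValueError):
    """An input value is outside its valid domain (e.g. negative density)."""
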