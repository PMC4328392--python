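"""Micrometre <-> pixel conversions.

All unit conversions in the package go through this module so that a single
rounding convention (round-half-even, Python's built-in ``round``) applies
everywhere; this prevents off-by-one disagreements between, say, the ROI side
used by the sampler and the structuring-element radius used by the
background filter.

At the default calibration of 7 px/μm a 120 μm ROI is 840 px and a 30 μm
rolling-ball radius is 210 px.
"""

from __future__ import annotations

from .errors import InvalidParameterError


def um_to_px(um: float, resolution: float) -> float:
    """Exact (float) conversion of a length in μm to pixels.

    ``resolution`` is in pixels per μm and must be positive.
    """
    if not resolution > 0:
        raise InvalidParameterError(f"resolution must be > 0, got {resolution}")
    return um * resolution


def um_to_px_int(um: float, resolution: float) -> int:
    """Convert μm to an integer pixel count, rounding half to even."""
    return int(round(um_to_px(um, resolution)))


def um_to_px_even(um: float, resolution: float) -> int:
    """Convert μm to the nearest *even* integer pixel count.

    Even ROI sides let a 90° rotation map a square sample onto the same
    pixel grid without resampling.
    """
    return 2 * int(round(um_to_px(um, resolution) / 2.0))


def px_to_um(px: float, resolution: float) -> float:
    """Convert pixels back to μm."""
    if not resolution > 0:
        raise InvalidParameterError(f"resolution must be > 0, got {resolution}")
    return px / resolution
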