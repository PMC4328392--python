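"""Core in-memory containers shared by every stage.

Raster convention: 2-D arrays indexed ``(row, col)``, origin at the top-left,
0-based, half-open pixel bounds. Coordinates in μm use ``(x, y)`` with
``x = col / resolution`` and ``y = row / resolution``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CalibrationMismatchError, InvalidParameterError, MissingLayerError

#: Canonical olfactory-bulb layer names, innermost first.
LAYER_NAMES = ("GCL", "EPL", "GL")

#: Default integer labels used in layer masks (0 is background).
DEFAULT_LEGEND = {1: "GCL", 2: "EPL", 3: "GL"}


@dataclass
class CalibratedImage:
    """A single-channel 2-D intensity raster with a spatial calibration.

    Parameters
    ----------
    pixels
        2-D array of finite, non-negative intensities (any float/int dtype).
    resolution
        Pixels per μm; must be positive.
    channel
        Free-form channel label, e.g. ``"EGFP"``, ``"5-HT"``, ``"DAPI"``.
    """

    pixels: np.ndarray
    resolution: float
    channel: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise InvalidParameterError(
                f"image raster must be 2-D, got shape {self.pixels.shape}"
            )
        if not self.resolution > 0:
            raise InvalidParameterError(f"resolution must be > 0, got {self.resolution}")
        if not np.all(np.isfinite(self.pixels)):
            raise InvalidParameterError("image contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray) -> "CalibratedImage":
        """New image with the same calibration/channel but different pixels."""
        return CalibratedImage(pixels=pixels, resolution=self.resolution, channel=self.channel)


@dataclass
class LayerMask:
    """Integer label raster assigning each pixel to a layer or background (0).

    ``legend`` maps non-zero label integers to layer names; it must be
    injective so names can be looked up both ways.
    """

    labels: np.ndarray
    resolution: float
    legend: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_LEGEND))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise InvalidParameterError(
                f"mask raster must be 2-D, got shape {self.labels.shape}"
            )
        if not self.resolution > 0:
            raise InvalidParameterError(f"resolution must be > 0, got {self.resolution}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise InvalidParameterError("mask labels must be integers")
        names = list(self.legend.values())
        if len(names) != len(set(names)):
            raise InvalidParameterError("mask legend maps two labels to one name")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def layer_names(self) -> tuple[str, ...]:
        return tuple(self.legend.values())

    def label_of(self, layer: str) -> int:
        """Integer label of a named layer; raises :class:`MissingLayerError`."""
        for lab, name in self.legend.items():
            if name == layer:
                return lab
        raise MissingLayerError(layer)

    def layer_pixels(self, layer: str) -> np.ndarray:
        """Boolean raster marking pixels of the named layer."""
        return self.labels == self.label_of(layer)

    def layer_area_px(self, layer: str) -> int:
        return int(np.count_nonzero(self.layer_pixels(layer)))

    def check_same_grid(self, img: CalibratedImage) -> None:
        """Raise unless ``img`` shares this mask's raster grid and calibration."""
        if img.shape != self.shape or not np.isclose(img.resolution, self.resolution):
            raise CalibrationMismatchError(
                f"image grid {img.shape}@{img.resolution} px/μm does not match "
                f"mask grid {self.shape}@{self.resolution} px/μm"
            )
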