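"""Layer-stratified square ROI placement and sample extraction.

Sampling design: ten square samples of 120 × 120 μm per layer, at most one
per 36° angular sector about the layer's pixel centroid, each drawn
uniformly from candidate centres whose full square footprint lies inside
the layer. Placement uses only the layer mask (derived from the anatomy
channel), never the signal channel, so sample positions cannot be biased by
where label happens to be.

Conventions: the angular origin is "3 o'clock" (the +column direction from
the centroid) and angles increase counter-clockwise in the usual image
display (i.e. towards decreasing row). The ROI side in pixels is rounded to
the nearest even integer so the 90° rotation used by the colocalization
control maps a sample onto its own grid without resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import CalibratedImage, LayerMask
from .errors import CalibrationMismatchError, InvalidParameterError, MissingLayerError
from .units import um_to_px_even

__all__ = ["SamplingConfig", "SampleROI", "PlacementResult", "Sample", "place_rois", "extract_samples"]


@dataclass(frozen=True)
class SamplingConfig:
    """ROI sampling parameters (defaults: ten 120 μm samples, 36° sectors)."""

    roi_side_um: float = 120.0
    n_per_layer: int = 10
    sector_deg: float = 36.0
    max_attempts_per_sector: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.roi_side_um > 0:
            raise InvalidParameterError("roi_side_um must be > 0")
        if self.n_per_layer < 1 or self.max_attempts_per_sector < 1:
            raise InvalidParameterError("n_per_layer and max_attempts_per_sector must be >= 1")
        if not 0 < self.sector_deg <= 360:
            raise InvalidParameterError("sector_deg must be in (0, 360]")


@dataclass(frozen=True)
class SampleROI:
    """One square sampling window tied to a layer and an angular sector.

    ``bounds`` is the half-open pixel rectangle ``(row0, col0, row1, col1)``.
    """

    layer: str
    sector_index: int
    center: tuple[int, int]
    side_px: int
    bounds: tuple[int, int, int, int]
    resolution: float

    @property
    def slices(self) -> tuple[slice, slice]:
        r0, c0, r1, c1 = self.bounds
        return slice(r0, r1), slice(c0, c1)


@dataclass
class PlacementResult:
    """ROIs placed for one layer plus the sectors where placement failed."""

    rois: list[SampleROI]
    failed_sectors: list[int] = field(default_factory=list)


@dataclass
class Sample:
    """An extracted square sample raster tagged with its ROI."""

    roi: SampleROI
    pixels: np.ndarray


def _integral_image(mask_bool: np.ndarray) -> np.ndarray:
    """Zero-padded summed-area table for O(1) rectangle sums."""
    s = np.zeros((mask_bool.shape[0] + 1, mask_bool.shape[1] + 1), dtype=np.int64)
    np.cumsum(mask_bool, axis=0, dtype=np.int64, out=s[1:, 1:])
    np.cumsum(s[1:, 1:], axis=1, out=s[1:, 1:])
    return s


def _rect_sum(integral: np.ndarray, r0: int, c0: int, r1: int, c1: int) -> int:
    return int(integral[r1, c1] - integral[r0, c1] - integral[r1, c0] + integral[r0, c0])


def place_rois(mask: LayerMask, layer: str, cfg: SamplingConfig | None = None) -> PlacementResult:
    """Place up to one ROI per angular sector of the named layer.

    Candidate centres are drawn by rejection sampling, uniformly over the
    layer's pixels within each sector, and accepted when the full square
    footprint lies inside the layer and the raster. Deterministic given
    ``cfg.seed``. Sectors where no placement succeeded within
    ``max_attempts_per_sector`` accepted-candidate draws are reported in
    ``failed_sectors``; no exception is raised for them.
    """
    cfg = cfg or SamplingConfig()
    label = mask.label_of(layer)  # raises MissingLayerError when unknown to legend
    layer_bool = mask.labels == label
    flat = np.flatnonzero(layer_bool)
    if flat.size == 0:
        raise MissingLayerError(f"layer {layer!r} has no pixels in the mask")

    rows_img, cols_img = mask.shape
    side = um_to_px_even(cfg.roi_side_um, mask.resolution)
    if side < 2:
        raise InvalidParameterError("ROI side is below 2 px at this resolution")
    n_sectors = min(cfg.n_per_layer, int(round(360.0 / cfg.sector_deg)))
    half_lo = side // 2  # footprint: [center - half_lo, center - half_lo + side)

    rs, cs = np.divmod(flat, cols_img)
    centroid_r = float(rs.mean())
    centroid_c = float(cs.mean())
    # CCW angle from "3 o'clock" with image rows increasing downwards
    angles = np.degrees(np.arctan2(centroid_r - rs, cs - centroid_c)) % 360.0
    sector_of = np.minimum((angles // cfg.sector_deg).astype(np.int32), n_sectors - 1)

    integral = _integral_image(layer_bool)
    rois: list[SampleROI] = []
    failed: list[int] = []
    for sector in range(n_sectors):
        rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), int(label), sector]))
        cand = flat[sector_of == sector]
        if cand.size == 0:
            failed.append(sector)
            continue
        placed = False
        for _ in range(cfg.max_attempts_per_sector):
            pick = int(cand[rng.integers(0, cand.size)])
            r, c = divmod(pick, cols_img)
            r0, c0 = r - half_lo, c - half_lo
            r1, c1 = r0 + side, c0 + side
            if r0 < 0 or c0 < 0 or r1 > rows_img or c1 > cols_img:
                continue
            if _rect_sum(integral, r0, c0, r1, c1) == side * side:
                rois.append(
                    SampleROI(
                        layer=layer,
                        sector_index=sector,
                        center=(r, c),
                        side_px=side,
                        bounds=(r0, c0, r1, c1),
                        resolution=mask.resolution,
                    )
                )
                placed = True
                break
        if not placed:
            failed.append(sector)
    return PlacementResult(rois=rois, failed_sectors=failed)


def extract_samples(img: CalibratedImage, rois: list[SampleROI]) -> list[Sample]:
    """Extract the square sample rasters for ``rois``, in order.

    The image must share the grid/calibration the ROIs were placed on.
    """
    out: list[Sample] = []
    rows_img, cols_img = img.shape
    for roi in rois:
        if not np.isclose(roi.resolution, img.resolution):
            raise CalibrationMismatchError(
                f"ROI calibration {roi.resolution} px/μm does not match image {img.resolution}"
            )
        r0, c0, r1, c1 = roi.bounds
        if r0 < 0 or c0 < 0 or r1 > rows_img or c1 > cols_img:
            raise CalibrationMismatchError(f"ROI bounds {roi.bounds} fall outside {img.shape}")
        out.append(Sample(roi=roi, pixels=np.array(img.pixels[r0:r1, c0:c1], copy=True)))
    return out
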