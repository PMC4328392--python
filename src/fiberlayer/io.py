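"""File formats: grayscale TIFF rasters, CSV tables, YAML configs/sidecars.

Images are written as single-plane grayscale TIFF — 16-bit for intensity
channels (values rounded and clipped to the uint16 range) and 8-bit for
label masks, with the pixel calibration stored in the TIFF resolution tags
(pixels per centimetre). On reading, an explicitly passed resolution takes
precedence over the file's tags.

Masks travel with a YAML legend sidecar mapping label integers to layer
names; every CSV carries a header row naming its units.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .coloc import MarkerSet
from .core import DEFAULT_LEGEND, CalibratedImage, LayerMask
from .density import DensityRecord
from .errors import InvalidParameterError
from .sampling import SampleROI

__all__ = [
    "write_image",
    "read_image",
    "write_mask",
    "read_mask",
    "write_rois_csv",
    "read_rois_csv",
    "write_density_csv",
    "read_density_csv",
    "write_markers_csv",
    "read_markers_csv",
    "write_curves_csv",
    "load_yaml",
    "save_yaml",
]

_CM_PER_UM = 1e-4


def _resolution_tag(resolution_px_per_um: float) -> tuple[float, float]:
    ppcm = resolution_px_per_um / _CM_PER_UM
    return (ppcm, ppcm)


def write_image(path: str | os.PathLike, img: CalibratedImage) -> Path:
    """Write an intensity channel as 16-bit grayscale TIFF."""
    path = Path(path)
    data = np.clip(np.round(np.asarray(img.pixels, dtype=np.float64)), 0, 65535).astype(np.uint16)
    tifffile.imwrite(
        path,
        data,
        resolution=_resolution_tag(img.resolution),
        resolutionunit="CENTIMETER",
        metadata={"channel": img.channel},
    )
    return path


def _read_tag_resolution(page: "tifffile.TiffPage") -> float | None:
    try:
        xres = page.tags["XResolution"].value
        unit = page.tags["ResolutionUnit"].value
    except KeyError:
        return None
    ppu = xres[0] / xres[1] if isinstance(xres, tuple) else float(xres)
    unit = int(getattr(unit, "value", unit))
    if unit == 3:  # centimetre
        return ppu * _CM_PER_UM
    if unit == 2:  # inch
        return ppu / 25400.0
    return None


def read_image(
    path: str | os.PathLike, resolution: float | None = None, channel: str = ""
) -> CalibratedImage:
    """Read a grayscale TIFF; an explicit ``resolution`` overrides the tags."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        res = resolution if resolution is not None else _read_tag_resolution(page)
    if res is None:
        raise InvalidParameterError(
            f"{path}: no usable resolution tag; pass resolution= explicitly"
        )
    return CalibratedImage(pixels=data.astype(np.float32), resolution=float(res), channel=channel)


def write_mask(path: str | os.PathLike, mask: LayerMask, legend_path: str | os.PathLike | None = None) -> Path:
    """Write a label mask as 8-bit TIFF plus a YAML legend sidecar."""
    path = Path(path)
    if mask.labels.max(initial=0) > 255:
        raise InvalidParameterError("mask labels exceed 8-bit range")
    tifffile.imwrite(
        path,
        mask.labels.astype(np.uint8),
        resolution=_resolution_tag(mask.resolution),
        resolutionunit="CENTIMETER",
    )
    legend_path = Path(legend_path) if legend_path else path.with_suffix(".legend.yaml")
    save_yaml(legend_path, {int(k): str(v) for k, v in mask.legend.items()})
    return path


def read_mask(
    path: str | os.PathLike,
    legend_path: str | os.PathLike | None = None,
    resolution: float | None = None,
) -> LayerMask:
    """Read a label mask TIFF and its YAML legend (defaults when absent)."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        labels = page.asarray()
        res = resolution if resolution is not None else _read_tag_resolution(page)
    if res is None:
        raise InvalidParameterError(f"{path}: no usable resolution tag; pass resolution=")
    legend_path = Path(legend_path) if legend_path else Path(path).with_suffix(".legend.yaml")
    legend = (
        {int(k): str(v) for k, v in load_yaml(legend_path).items()}
        if Path(legend_path).exists()
        else dict(DEFAULT_LEGEND)
    )
    return LayerMask(labels=labels.astype(np.uint8), resolution=float(res), legend=legend)


def write_rois_csv(path: str | os.PathLike, rois: list[SampleROI]) -> Path:
    path = Path(path)
    pd.DataFrame(
        [
            dict(
                layer=r.layer,
                sector_index=r.sector_index,
                center_row_px=r.center[0],
                center_col_px=r.center[1],
                side_px=r.side_px,
                resolution_px_per_um=r.resolution,
            )
            for r in rois
        ]
    ).to_csv(path, index=False)
    return path


def read_rois_csv(path: str | os.PathLike) -> list[SampleROI]:
    df = pd.read_csv(path)
    rois = []
    for row in df.itertuples():
        side = int(row.side_px)
        half = side // 2
        r0 = int(row.center_row_px) - half
        c0 = int(row.center_col_px) - half
        rois.append(
            SampleROI(
                layer=str(row.layer),
                sector_index=int(row.sector_index),
                center=(int(row.center_row_px), int(row.center_col_px)),
                side_px=side,
                bounds=(r0, c0, r0 + side, c0 + side),
                resolution=float(row.resolution_px_per_um),
            )
        )
    return rois


def write_density_csv(path: str | os.PathLike, records: list[DensityRecord]) -> Path:
    path = Path(path)
    pd.DataFrame(
        [
            dict(
                animal=r.animal,
                layer=r.layer,
                detected_px=r.detected_px,
                total_px=r.total_px,
                density_um2_per_100um2=r.density,
                resolution_px_per_um=r.resolution,
            )
            for r in records
        ]
    ).to_csv(path, index=False)
    return path


def read_density_csv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    return df.rename(columns={"density_um2_per_100um2": "density"})


def write_markers_csv(path: str | os.PathLike, sets: list[MarkerSet]) -> Path:
    path = Path(path)
    rows = []
    for ms in sets:
        for x, y in ms.points:
            rows.append(dict(x_um=x, y_um=y, channel=ms.channel, replicate=ms.replicate))
    pd.DataFrame(rows, columns=["x_um", "y_um", "channel", "replicate"]).to_csv(path, index=False)
    return path


def read_markers_csv(path: str | os.PathLike) -> list[MarkerSet]:
    df = pd.read_csv(path)
    sets = []
    for (channel, replicate), g in df.groupby(["channel", "replicate"], sort=True):
        sets.append(
            MarkerSet(
                points=g[["x_um", "y_um"]].to_numpy(float),
                channel=str(channel),
                replicate=int(replicate),
            )
        )
    return sets


def write_curves_csv(path: str | os.PathLike, curves: list) -> Path:
    """Write shift-correlation curves (one block per sample) as tidy CSV."""
    path = Path(path)
    rows = []
    for i, c in enumerate(curves):
        for j, dx in enumerate(c.dx):
            rows.append(
                dict(
                    sample=i,
                    dx_px=int(dx),
                    r_test=float(c.r[j]),
                    r_control=float(c.control_r[j]) if c.control_r is not None else np.nan,
                )
            )
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def load_yaml(path: str | os.PathLike):
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_yaml(path: str | os.PathLike, obj) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
    return path
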