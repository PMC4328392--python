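"""Synthetic laminar-section generator with exhaustively known ground truth.

This module emulates the data the rest of the pipeline was built for:
coronal sections of the mouse olfactory bulb, a concentric three-layer
annular structure (granule cell layer GCL innermost, then the external
plexiform layer EPL, then the glomerular layer GL), imaged in separate
fluorescence channels:

* a DAPI-like nuclei channel (dense small nuclei in GCL and GL, sparse in
  the EPL) used only for anatomy,
* one or two fiber channels carrying punctate/varicose axonal label at a
  controllable per-layer area density (μm²/100 μm², i.e. percent area),
* sensor noise: additive Gaussian noise, strictly single-pixel impulse
  ("speckle") noise, and a smooth additive background gradient.

Design notes
------------
Fibers are rendered as chains of small constant-shape "bouton" stamps placed
along a random-walk path, without anti-aliasing, so the true signal area is
an exact pixel count. The default parameters produce isolated ~0.7 μm
boutons (presynaptic-marker label is punctate); longer ``fiber_length_um``
yields beaded fibers and ``render="stroke"`` draws continuous thickened
polylines. Bouton stamps of 5 px and larger are invariant under a 3×3
median filter, which makes the despeckle stage unbiased on true signal.

Fiber seed points are placed by stratified (jittered-grid) sampling within
each layer so sections are spatially homogeneous — the property the
layer-stratified ROI sampling design implicitly assumes.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence``; sub-streams per channel/stage are spawned
deterministically, so identical (spec, seed) give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from skimage.draw import disk as _draw_disk
from skimage.draw import line as _draw_line

from .core import DEFAULT_LEGEND, LAYER_NAMES, CalibratedImage, LayerMask
from .errors import (
    GenerationFailureError,
    InvalidGeometryError,
    InvalidParameterError,
)
from .units import um_to_px

__all__ = [
    "SectionGeometry",
    "FiberFieldSpec",
    "NoiseSpec",
    "GroundTruth",
    "generate_section",
    "generate_fiber_channel",
    "generate_channel_pair",
    "generate_marker_sets",
    "apply_noise",
    "uniform_mask",
    "generate_cohort_summaries",
]


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SectionGeometry:
    """Concentric annular layer geometry of one coronal section.

    ``layer_radii_um`` are the outer boundary radii of GCL, EPL and GL (in
    that order, strictly increasing, μm). ``image_shape`` defaults to the
    smallest square raster that holds the outermost circle plus
    ``margin_um`` on every side; ``center_px`` defaults to the raster
    centre.
    """

    layer_radii_um: tuple[float, float, float] = (250.0, 430.0, 610.0)
    resolution: float = 7.0
    image_shape: tuple[int, int] | None = None
    center_px: tuple[float, float] | None = None
    margin_um: float = 2.0

    def __post_init__(self) -> None:
        radii = tuple(float(r) for r in self.layer_radii_um)
        if len(radii) != 3 or any(r <= 0 for r in radii):
            raise InvalidGeometryError(f"need three positive radii, got {radii}")
        if not (radii[0] < radii[1] < radii[2]):
            raise InvalidGeometryError(f"radii must be strictly increasing, got {radii}")
        if not self.resolution > 0:
            raise InvalidGeometryError(f"resolution must be > 0, got {self.resolution}")
        object.__setattr__(self, "layer_radii_um", radii)
        if self.image_shape is None:
            side = 2 * int(math.ceil(um_to_px(radii[2] + self.margin_um, self.resolution))) + 1
            object.__setattr__(self, "image_shape", (side, side))
        if self.center_px is None:
            object.__setattr__(
                self,
                "center_px",
                ((self.image_shape[0] - 1) / 2.0, (self.image_shape[1] - 1) / 2.0),
            )
        r_out = um_to_px(radii[2], self.resolution)
        cr, cc = self.center_px
        rows, cols = self.image_shape
        if (
            cr - r_out < -0.5
            or cc - r_out < -0.5
            or cr + r_out > rows - 0.5
            or cc + r_out > cols - 0.5
        ):
            raise InvalidGeometryError(
                f"outer radius {radii[2]} μm ({r_out:.0f} px) does not fit a "
                f"{rows}×{cols} raster at centre {self.center_px}"
            )


@dataclass(frozen=True)
class FiberFieldSpec:
    """Target fiber field for one channel.

    ``per_layer_density`` maps layer name → target signal area density in
    μm²/100 μm² (equivalently, percent of layer area). The achieved density
    is met by adding whole fibers, never by trimming a rendered fiber; the
    recorded ground truth is the achieved value.

    Defaults render each fiber as a single ~0.7 μm bouton (one stamp);
    raise ``fiber_length_um`` to get beaded fibers with one bouton every
    ``step_length_um`` along a random walk whose heading diffuses with
    standard deviation ``turn_sd`` (radians) per step.
    """

    per_layer_density: Mapping[str, float] = field(
        default_factory=lambda: {"GL": 0.014, "EPL": 0.0007, "GCL": 0.0008}
    )
    fiber_width_um: float = 0.7
    fiber_amplitude: float = 600.0
    fiber_length_um: float = 1.0
    step_length_um: float = 2.0
    turn_sd: float = 0.35
    density_tolerance: float = 0.10
    render: str = "puncta"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.per_layer_density.values()):
            raise InvalidParameterError("per-layer densities must be >= 0")
        if not self.fiber_width_um > 0:
            raise InvalidParameterError("fiber_width_um must be > 0")
        if not self.fiber_amplitude > 0:
            raise InvalidParameterError("fiber_amplitude must be > 0")
        if not self.step_length_um > 0:
            raise InvalidParameterError("step_length_um must be > 0")
        if self.render not in ("puncta", "stroke"):
            raise InvalidParameterError(f"render must be 'puncta' or 'stroke', got {self.render!r}")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise model applied independently per channel.

    ``background`` gives a smooth additive plane ``(b0, b_row, b_col)``:
    constant offset plus linear gradients spanning the full raster.
    Impulse noise is strictly single-pixel (no two impulses are 8-adjacent),
    so a 3×3 median filter removes it exactly.
    """

    gaussian_sd: float = 30.0
    speckle_rate: float = 5e-4
    impulse_amplitude: float = 4000.0
    background: tuple[float, float, float] = (100.0, 40.0, 25.0)

    def __post_init__(self) -> None:
        if self.gaussian_sd < 0:
            raise InvalidParameterError("gaussian_sd must be >= 0")
        if not 0 <= self.speckle_rate <= 1:
            raise InvalidParameterError("speckle_rate must be in [0, 1]")

    @classmethod
    def none(cls) -> "NoiseSpec":
        """A no-op noise spec (all components zero)."""
        return cls(gaussian_sd=0.0, speckle_rate=0.0, impulse_amplitude=0.0, background=(0.0, 0.0, 0.0))


@dataclass
class GroundTruth:
    """Exhaustive bookkeeping of what was rendered.

    ``per_layer_true_density`` is recounted from the rendered raster
    (achieved, not target), in μm²/100 μm². For channel pairs, channel B has
    its own density map and the shared-fiber bookkeeping is filled in; for
    marker sets only ``marker_truth`` is populated.
    """

    per_layer_true_density: dict[str, float] = field(default_factory=dict)
    per_layer_true_density_b: dict[str, float] | None = None
    n_fibers: dict[str, int] | None = None
    n_fibers_b: dict[str, int] | None = None
    shared_fiber_fraction: float | None = None
    n_shared_fibers: int | None = None
    marker_truth: dict[str, int] | None = None


# ---------------------------------------------------------------------------
# Section (mask + nuclei channel)
# ---------------------------------------------------------------------------

_DEFAULT_NUCLEI_PER_100UM2 = {"GCL": 1.1, "EPL": 0.15, "GL": 0.7}
_NUCLEUS_RADIUS_UM = 2.6
_NUCLEUS_AMPLITUDE = 900.0


def generate_section(
    geometry: SectionGeometry,
    seed: int,
    nuclei_per_100um2: Mapping[str, float] | None = None,
) -> tuple[LayerMask, CalibratedImage]:
    """Generate the layer-label mask and a DAPI-like nuclei channel.

    The mask contains exactly four labels: 0 (background) and the three
    concentric annular layers. Nuclei are drawn as bright discs at
    per-layer areal densities (count per 100 μm²); defaults are dense in
    GCL and GL and sparse in the EPL. Deterministic given ``seed``.
    """
    dens = dict(_DEFAULT_NUCLEI_PER_100UM2)
    if nuclei_per_100um2 is not None:
        dens.update(nuclei_per_100um2)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA1]))

    rows, cols = geometry.image_shape
    cr, cc = geometry.center_px
    res = geometry.resolution
    dr = (np.arange(rows, dtype=np.float32) - np.float32(cr)) ** 2
    dc = (np.arange(cols, dtype=np.float32) - np.float32(cc)) ** 2
    r2 = dr[:, None] + dc[None, :]
    bounds2 = np.asarray([um_to_px(r, res) ** 2 for r in geometry.layer_radii_um], dtype=np.float32)
    # digitize: 0 -> GCL(1), 1 -> EPL(2), 2 -> GL(3), 3 -> background(0)
    bins = np.digitize(r2, bounds2, right=False)
    labels = np.where(bins >= 3, 0, bins + 1).astype(np.uint8)
    del r2, bins

    mask = LayerMask(labels=labels, resolution=res, legend=dict(DEFAULT_LEGEND))
    nuclei = np.zeros((rows, cols), dtype=np.float32)
    rad_px = um_to_px(_NUCLEUS_RADIUS_UM, res)
    for layer in LAYER_NAMES:
        layer_bool = mask.layer_pixels(layer)
        n_px = int(np.count_nonzero(layer_bool))
        if n_px == 0:
            continue
        area_um2 = n_px / res**2
        n_nuclei = int(round(dens.get(layer, 0.0) / 100.0 * area_um2))
        if n_nuclei == 0:
            continue
        flat = np.flatnonzero(layer_bool)
        centers = rng.choice(flat, size=n_nuclei, replace=True)
        radii = rad_px * rng.uniform(0.8, 1.2, size=n_nuclei)
        amps = _NUCLEUS_AMPLITUDE * rng.uniform(0.85, 1.15, size=n_nuclei)
        crs, ccs = np.divmod(centers, cols)
        for i in range(n_nuclei):
            rr, cc_ = _draw_disk((int(crs[i]), int(ccs[i])), radii[i], shape=(rows, cols))
            np.maximum.at(nuclei, (rr, cc_), np.float32(amps[i]))
        del flat
    return mask, CalibratedImage(pixels=nuclei, resolution=res, channel="DAPI")


# ---------------------------------------------------------------------------
# Fiber rendering
# ---------------------------------------------------------------------------


def _bouton_offsets(width_px: int) -> np.ndarray:
    """Integer (dr, dc) offsets of one bouton stamp.

    Stamps of side >= 5 px are squares with the four corner pixels removed —
    a shape invariant under the 3×3 median filter.
    """
    w = max(1, width_px)
    if w % 2 == 0:
        w += 1
    h = w // 2
    dr, dc = np.mgrid[-h : h + 1, -h : h + 1]
    keep = np.ones_like(dr, dtype=bool)
    if w >= 5:
        keep[(np.abs(dr) == h) & (np.abs(dc) == h)] = False
    return np.stack([dr[keep], dc[keep]], axis=1)


@dataclass
class _Fiber:
    """One rendered fiber: its path (px, float) and in-layer pixel coords."""

    path: np.ndarray  # (k, 2) float row/col
    rows: np.ndarray  # in-layer rendered pixels
    cols: np.ndarray
    new_rows: np.ndarray  # subset newly added to the layer canvas
    new_cols: np.ndarray


def _walk_path(rng: np.random.Generator, start: tuple[float, float], spec: FiberFieldSpec, resolution: float) -> np.ndarray:
    """Random-walk vertex sequence, one vertex per step, spacing step_length."""
    n_steps = max(0, int(math.floor(spec.fiber_length_um / spec.step_length_um + 1e-9)))
    step_px = um_to_px(spec.step_length_um, resolution)
    theta = rng.uniform(0.0, 2.0 * math.pi)
    pts = [np.asarray(start, dtype=float)]
    for _ in range(n_steps):
        theta += rng.normal(0.0, spec.turn_sd)
        pts.append(pts[-1] + step_px * np.asarray([math.sin(theta), math.cos(theta)]))
    return np.asarray(pts)


def _render_path(path: np.ndarray, offsets: np.ndarray, shape: tuple[int, int], render: str) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize a path to unique pixel coordinates (no anti-aliasing)."""
    verts = np.round(path).astype(np.int64)
    if render == "stroke" and len(verts) > 1:
        segs = []
        for (r0, c0), (r1, c1) in zip(verts[:-1], verts[1:]):
            rr, cc = _draw_line(int(r0), int(c0), int(r1), int(c1))
            segs.append(np.stack([rr, cc], axis=1))
        centers = np.concatenate(segs, axis=0)
    else:
        centers = verts
    pts = (centers[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
    ok = (pts[:, 0] >= 0) & (pts[:, 0] < shape[0]) & (pts[:, 1] >= 0) & (pts[:, 1] < shape[1])
    pts = pts[ok]
    flat = np.unique(pts[:, 0] * shape[1] + pts[:, 1])
    return (flat // shape[1]).astype(np.intp), (flat % shape[1]).astype(np.intp)


def _jittered_grid_starts(
    rng: np.random.Generator, layer_bool: np.ndarray, n_target: int
) -> np.ndarray:
    """Stratified candidate start points: one jittered point per grid cell.

    Returns an (m, 2) float array of in-layer points in a shuffled order.
    The grid is sized so roughly ``n_target`` points fall inside the layer.
    """
    rows_any = np.flatnonzero(layer_bool.any(axis=1))
    cols_any = np.flatnonzero(layer_bool.any(axis=0))
    r0, r1 = int(rows_any[0]), int(rows_any[-1]) + 1
    c0, c1 = int(cols_any[0]), int(cols_any[-1]) + 1
    layer_px = int(np.count_nonzero(layer_bool))
    bbox_px = (r1 - r0) * (c1 - c0)
    # cell area such that n_target cells land inside the layer on average
    cell = max(1.0, math.sqrt(bbox_px / max(1, n_target) * (layer_px / bbox_px)))
    nr = max(1, int(math.ceil((r1 - r0) / cell)))
    nc = max(1, int(math.ceil((c1 - c0) / cell)))
    gr, gc = np.mgrid[0:nr, 0:nc]
    pr = r0 + (gr.ravel() + rng.uniform(0, 1, gr.size)) * (r1 - r0) / nr
    pc = c0 + (gc.ravel() + rng.uniform(0, 1, gc.size)) * (c1 - c0) / nc
    ir = np.clip(np.round(pr).astype(np.intp), 0, layer_bool.shape[0] - 1)
    ic = np.clip(np.round(pc).astype(np.intp), 0, layer_bool.shape[1] - 1)
    inside = layer_bool[ir, ic]
    pts = np.stack([pr[inside], pc[inside]], axis=1)
    rng.shuffle(pts)
    return pts


_MAX_ZERO_PROGRESS = 200


def _generate_layer_fibers(
    rng: np.random.Generator,
    mask: LayerMask,
    layer: str,
    target_px: int,
    spec: FiberFieldSpec,
    canvas: np.ndarray,
) -> list[_Fiber]:
    """Add whole fibers to ``canvas`` until the layer's target area is met.

    Stops at the whole-fiber count whose achieved pixel area is closest to
    the target (the last fiber is dropped again if that lands closer).
    Raises :class:`GenerationFailureError` naming the layer if the target
    is beyond the packing limit or no progress can be made.
    """
    label = mask.label_of(layer)
    layer_bool = mask.labels == label
    layer_total = int(np.count_nonzero(layer_bool))
    if target_px <= 0:
        return []
    if layer_total == 0 or target_px > 0.45 * layer_total:
        raise GenerationFailureError(
            f"layer {layer!r}: target of {target_px} px exceeds the packing limit "
            f"of a {layer_total}-px layer"
        )
    shape = mask.shape
    width_px = max(1, int(round(spec.fiber_width_um * mask.resolution)))
    offsets = _bouton_offsets(width_px)
    per_fiber_est = len(offsets) * max(
        1, int(math.floor(spec.fiber_length_um / spec.step_length_um + 1e-9)) + 1
    )
    starts = _jittered_grid_starts(rng, layer_bool, max(1, int(math.ceil(target_px / per_fiber_est))))
    fibers: list[_Fiber] = []
    achieved = 0
    start_idx = 0
    zero_progress = 0
    while achieved < target_px:
        if start_idx < len(starts):
            start = (float(starts[start_idx, 0]), float(starts[start_idx, 1]))
            start_idx += 1
        else:  # top-up: uniform rejection sampling inside the layer
            for _ in range(1000):
                r = rng.integers(0, shape[0])
                c = rng.integers(0, shape[1])
                if layer_bool[r, c]:
                    start = (float(r), float(c))
                    break
            else:
                raise GenerationFailureError(f"layer {layer!r}: could not draw a start point")
        path = _walk_path(rng, start, spec, mask.resolution)
        rows, cols = _render_path(path, offsets, shape, spec.render)
        inlayer = layer_bool[rows, cols]
        rows, cols = rows[inlayer], cols[inlayer]
        fresh = ~canvas[rows, cols]
        new_rows, new_cols = rows[fresh], cols[fresh]
        if new_rows.size == 0:
            zero_progress += 1
            if zero_progress > _MAX_ZERO_PROGRESS:
                raise GenerationFailureError(
                    f"layer {layer!r}: no free space left after {len(fibers)} fibers "
                    f"({achieved}/{target_px} px achieved)"
                )
            continue
        zero_progress = 0
        canvas[new_rows, new_cols] = True
        achieved += int(new_rows.size)
        fibers.append(_Fiber(path=path, rows=rows, cols=cols, new_rows=new_rows, new_cols=new_cols))
    if fibers:
        last = fibers[-1]
        without = achieved - last.new_rows.size
        if abs(without - target_px) < abs(achieved - target_px):
            canvas[last.new_rows, last.new_cols] = False
            fibers.pop()
    return fibers


def _density_of(canvas: np.ndarray, mask: LayerMask) -> dict[str, float]:
    """Recount rendered pixels per layer, in μm²/100 μm² (percent area)."""
    out = {}
    for layer in mask.layer_names:
        layer_bool = mask.layer_pixels(layer)
        total = int(np.count_nonzero(layer_bool))
        hit = int(np.count_nonzero(canvas & layer_bool))
        out[layer] = 100.0 * hit / total if total else 0.0
    return out


def _targets_px(mask: LayerMask, spec: FiberFieldSpec) -> dict[str, int]:
    return {
        layer: int(round(d / 100.0 * mask.layer_area_px(layer)))
        for layer, d in spec.per_layer_density.items()
    }


def generate_fiber_channel(
    mask: LayerMask, spec: FiberFieldSpec
) -> tuple[CalibratedImage, GroundTruth]:
    """Render one fiber channel to the requested per-layer densities.

    Returns the clean (noise-free) channel and the achieved ground truth;
    apply :func:`apply_noise` afterwards for the full image model.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0xF1]))
    canvas = np.zeros(mask.shape, dtype=bool)
    n_fibers: dict[str, int] = {}
    for layer, target in _targets_px(mask, spec).items():
        fibers = _generate_layer_fibers(rng, mask, layer, target, spec, canvas)
        n_fibers[layer] = len(fibers)
    img = np.where(canvas, np.float32(spec.fiber_amplitude), np.float32(0.0))
    truth = GroundTruth(per_layer_true_density=_density_of(canvas, mask), n_fibers=n_fibers)
    return CalibratedImage(pixels=img, resolution=mask.resolution, channel="EGFP"), truth


def generate_channel_pair(
    mask: LayerMask,
    spec: FiberFieldSpec,
    shared_fraction: float,
    jitter_sd_um: float = 0.3,
    noise: NoiseSpec | None = None,
) -> tuple[CalibratedImage, CalibratedImage, GroundTruth]:
    """Render a two-channel pair with a controllable colocalized fraction.

    A fraction ``shared_fraction`` of channel A's fibers is re-rendered in
    channel B after a rigid Gaussian jitter of ``jitter_sd_um`` per fiber;
    the remaining fiber budget of B is filled with channel-exclusive fibers.
    Noise (if given) is applied independently per channel.
    """
    if not 0.0 <= shared_fraction <= 1.0:
        raise InvalidParameterError(f"shared_fraction must be in [0, 1], got {shared_fraction}")
    if jitter_sd_um < 0:
        raise InvalidParameterError("jitter_sd_um must be >= 0")
    ss = np.random.SeedSequence([int(spec.seed), 0xAB])
    rng_a, rng_b, rng_na, rng_nb = (np.random.default_rng(s) for s in ss.spawn(4))

    canvas_a = np.zeros(mask.shape, dtype=bool)
    canvas_b = np.zeros(mask.shape, dtype=bool)
    width_px = max(1, int(round(spec.fiber_width_um * mask.resolution)))
    offsets = _bouton_offsets(width_px)
    n_total = 0
    n_shared_total = 0
    n_fibers_a: dict[str, int] = {}
    n_fibers_b: dict[str, int] = {}
    for layer, target in _targets_px(mask, spec).items():
        fibers = _generate_layer_fibers(rng_a, mask, layer, target, spec, canvas_a)
        n_a = len(fibers)
        n_shared = int(round(shared_fraction * n_a))
        order = rng_a.permutation(n_a)
        shared = [fibers[i] for i in order[:n_shared]]
        label = mask.label_of(layer)
        layer_bool = mask.labels == label
        for fib in shared:
            if jitter_sd_um > 0:
                off = rng_b.normal(0.0, um_to_px(jitter_sd_um, mask.resolution), size=2)
                path = fib.path + off[None, :]
                rows, cols = _render_path(path, offsets, mask.shape, spec.render)
                inl = layer_bool[rows, cols]
                rows, cols = rows[inl], cols[inl]
            else:
                rows, cols = fib.rows, fib.cols
            canvas_b[rows, cols] = True
        # channel-B-exclusive fibers: same count as A's exclusives
        n_excl_b = n_a - n_shared
        made = 0
        zero_progress = 0
        while made < n_excl_b:
            for _ in range(1000):
                r = rng_b.integers(0, mask.shape[0])
                c = rng_b.integers(0, mask.shape[1])
                if layer_bool[r, c]:
                    break
            else:
                raise GenerationFailureError(f"layer {layer!r}: could not place channel-B fiber")
            path = _walk_path(rng_b, (float(r), float(c)), spec, mask.resolution)
            rows, cols = _render_path(path, offsets, mask.shape, spec.render)
            inl = layer_bool[rows, cols]
            rows, cols = rows[inl], cols[inl]
            if rows.size == 0:
                zero_progress += 1
                if zero_progress > _MAX_ZERO_PROGRESS:
                    raise GenerationFailureError(f"layer {layer!r}: channel-B placement stalled")
                continue
            canvas_b[rows, cols] = True
            made += 1
        n_total += n_a
        n_shared_total += n_shared
        n_fibers_a[layer] = n_a
        n_fibers_b[layer] = n_shared + n_excl_b

    amp = np.float32(spec.fiber_amplitude)
    img_a = CalibratedImage(np.where(canvas_a, amp, np.float32(0.0)), mask.resolution, "EGFP")
    img_b = CalibratedImage(np.where(canvas_b, amp, np.float32(0.0)), mask.resolution, "5-HT")
    truth = GroundTruth(
        per_layer_true_density=_density_of(canvas_a, mask),
        per_layer_true_density_b=_density_of(canvas_b, mask),
        n_fibers=n_fibers_a,
        n_fibers_b=n_fibers_b,
        shared_fiber_fraction=(n_shared_total / n_total) if n_total else None,
        n_shared_fibers=n_shared_total,
    )
    if noise is not None:
        img_a = apply_noise(img_a, noise, rng_na)
        img_b = apply_noise(img_b, noise, rng_nb)
    return img_a, img_b, truth


# ---------------------------------------------------------------------------
# Noise
# ---------------------------------------------------------------------------


def apply_noise(
    img: CalibratedImage, noise: NoiseSpec, rng: np.random.Generator | int
) -> CalibratedImage:
    """Apply the additive noise model; output is clipped at zero.

    Components, in order: smooth background plane, Gaussian sensor noise,
    strictly single-pixel impulse noise (no two impulses 8-adjacent).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(np.random.SeedSequence([int(rng), 0x0E]))
    rows, cols = img.shape
    out = img.pixels.astype(np.float32, copy=True)
    b0, br, bc = noise.background
    if b0 or br or bc:
        rr = np.linspace(0.0, 1.0, rows, dtype=np.float32)[:, None]
        cc = np.linspace(0.0, 1.0, cols, dtype=np.float32)[None, :]
        out += np.float32(b0) + np.float32(br) * rr + np.float32(bc) * cc
    if noise.gaussian_sd > 0:
        out += rng.normal(0.0, noise.gaussian_sd, size=out.shape).astype(np.float32)
    if noise.speckle_rate > 0 and noise.impulse_amplitude != 0:
        n = int(round(noise.speckle_rate * out.size))
        if n > 0:
            flat = np.unique(rng.integers(0, out.size, size=2 * n))[:2 * n]
            rng.shuffle(flat)
            taken: set[tuple[int, int]] = set()
            picked = []
            for f in flat:
                r, c = divmod(int(f), cols)
                if any((r + dr, c + dc) in taken for dr in (-1, 0, 1) for dc in (-1, 0, 1)):
                    continue
                taken.add((r, c))
                picked.append(f)
                if len(picked) == n:
                    break
            idx = np.asarray(picked, dtype=np.int64)
            out.ravel()[idx] += np.float32(noise.impulse_amplitude)
    np.clip(out, 0.0, None, out=out)
    return img.with_pixels(out)


# ---------------------------------------------------------------------------
# Marker sets
# ---------------------------------------------------------------------------


def generate_marker_sets(
    region_um: tuple[float, float],
    n_a: int,
    n_b: int,
    n_shared: int,
    shared_offset_sd_um: float = 1.0,
    seed: int = 0,
    cutoff_um: float = 12.0,
):
    """Two point-marker sets with unambiguous colocalization ground truth.

    ``n_shared`` pairs are placed as base points plus Gaussian offsets of
    ``shared_offset_sd_um``; every other point keeps a minimum separation of
    3 × ``cutoff_um`` from all opposite-channel points (and base points from
    each other), so the true matching is unambiguous.
    """
    from .coloc import MarkerSet  # local import to avoid a cycle

    if n_shared > min(n_a, n_b):
        raise InvalidParameterError("n_shared must be <= min(n_a, n_b)")
    if shared_offset_sd_um < 0:
        raise InvalidParameterError("shared_offset_sd_um must be >= 0")
    w, h = float(region_um[0]), float(region_um[1])
    sep = 3.0 * cutoff_um
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x3A]))

    def _place(n: int, min_sep_from: list[np.ndarray]) -> list[np.ndarray]:
        placed: list[np.ndarray] = []
        for _ in range(n):
            for _attempt in range(20000):
                p = rng.uniform([0.0, 0.0], [w, h])
                if all(np.hypot(*(p - q)) >= sep for q in min_sep_from + placed):
                    placed.append(p)
                    break
            else:
                raise GenerationFailureError(
                    f"region {w}×{h} μm too small for {n} points at {sep} μm separation"
                )
        return placed

    base = _place(n_shared, [])
    pts_a = [p.copy() for p in base]
    pts_b = [p + rng.normal(0.0, shared_offset_sd_um, size=2) for p in base]
    # exclusives must stay away from ALL opposite-channel points
    only_a = _place(n_a - n_shared, pts_b)
    only_b = _place(n_b - n_shared, pts_a + only_a)
    a = MarkerSet(points=np.asarray(pts_a + only_a, dtype=float).reshape(-1, 2), channel="A")
    b = MarkerSet(points=np.asarray(pts_b + only_b, dtype=float).reshape(-1, 2), channel="B")
    truth = GroundTruth(
        marker_truth={
            "n_shared": n_shared,
            "n_only_a": n_a - n_shared,
            "n_only_b": n_b - n_shared,
        }
    )
    return a, b, truth


# ---------------------------------------------------------------------------
# Helpers and cohort-level simulation
# ---------------------------------------------------------------------------


def uniform_mask(side_px: int, resolution: float, layer: str = "GL") -> LayerMask:
    """A square single-layer mask — a plain tissue patch for channel pairs."""
    legend = {DEFAULT_LEGEND_INV[layer]: layer} if layer in DEFAULT_LEGEND_INV else {1: layer}
    label = next(iter(legend))
    return LayerMask(
        labels=np.full((side_px, side_px), label, dtype=np.uint8),
        resolution=resolution,
        legend=legend,
    )


DEFAULT_LEGEND_INV = {v: k for k, v in DEFAULT_LEGEND.items()}

# Mixing model: mean label density contributed to each OB layer per infected
# cell, anchored to the field's reported per-animal summaries (GL density
# ~0.013 μm²/100 μm² for ~127 MRN cells; GCL ~0.012 for ~303 DRN cells; small
# cross terms for the sparse off-target label).
_GL_PER_MRN_CELL = 0.013 / 127.0
_GL_PER_DRN_CELL = 0.001 / 303.0
_GCL_PER_DRN_CELL = 0.012 / 303.0
_GCL_PER_MRN_CELL = 0.0005 / 127.0
_EPL_PER_DRN_CELL = 0.003 / 303.0
_EPL_PER_MRN_CELL = 0.002 / 127.0

_COUNT_MODEL = {
    # injection target -> ((mean, sd) DRN cells, (mean, sd) MRN cells)
    "DRN": ((303.0, 55.0), (11.0, 8.0)),
    "MRN": ((57.0, 39.0), (127.0, 26.0)),
}


def generate_cohort_summaries(
    n_drn_animals: int = 4,
    n_mrn_animals: int = 3,
    seed: int = 0,
    noise_cv: float = 0.10,
):
    """Per-animal summary table from a graded infection-mixing model.

    Each animal draws its DRN/MRN infected-cell counts from the injection
    group's distribution; layer label densities are linear in the two counts
    (projection strength per infected cell) times multiplicative lognormal
    noise with coefficient of variation ``noise_cv``. Returns a
    ``pandas.DataFrame`` with columns ``animal, injection_target, n_drn,
    n_mrn, d_gl, d_epl, d_gcl``.
    """
    import pandas as pd

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0]))
    sigma = math.sqrt(math.log(1.0 + noise_cv**2))
    records = []
    targets = ["DRN"] * n_drn_animals + ["MRN"] * n_mrn_animals
    for i, target in enumerate(targets):
        (d_mu, d_sd), (m_mu, m_sd) = _COUNT_MODEL[target]
        n_drn = max(0, int(round(rng.normal(d_mu, d_sd))))
        n_mrn = max(0, int(round(rng.normal(m_mu, m_sd))))
        lognoise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=3)
        d_gl = (_GL_PER_MRN_CELL * n_mrn + _GL_PER_DRN_CELL * n_drn) * lognoise[0]
        d_epl = (_EPL_PER_MRN_CELL * n_mrn + _EPL_PER_DRN_CELL * n_drn) * lognoise[1]
        d_gcl = (_GCL_PER_MRN_CELL * n_mrn + _GCL_PER_DRN_CELL * n_drn) * lognoise[2]
        records.append(
            dict(
                animal=f"animal_{i + 1:02d}",
                injection_target=target,
                n_drn=n_drn,
                n_mrn=n_mrn,
                d_gl=d_gl,
                d_epl=d_epl,
                d_gcl=d_gcl,
            )
        )
    return pd.DataFrame.from_records(records)
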