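"""Colocalization: shift-correlation with a rotated null, and marker matching.

Two complementary measures are implemented.

Pixel level — the van Steensel shift correlation: Pearson's r between two
channels of one sample as a function of an integer horizontal displacement
dx applied to the second channel. Genuine colocalization produces a
distinct peak at dx = 0; the null control repeats the curve after rotating
the second channel by 90°, which destroys true spatial correspondence while
preserving first-order image statistics. The cohort-level test is a paired
t-test of per-sample peak r (test vs rotated control) plus the mean ± SEM
of the per-sample peak displacement.

Sign convention: positive dx means the second channel is displaced towards
+columns before correlating, so if b equals a translated by +s columns the
curve peaks at dx = −s. Correlation at each dx uses only the overlapping
region (no zero padding), which keeps r undamped at large |dx|; the
``max_shift < side/2`` precondition guarantees at least half overlap.

Object level — point-marker colocalization by proximity: a one-to-one
greedy matching that repeatedly pairs the globally closest unmatched
cross-channel pair within a cutoff distance (default 12 μm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (
    DegreesOfFreedomError,
    InvalidParameterError,
    UndefinedCorrelationError,
)

__all__ = [
    "ShiftCorrelationCurve",
    "MarkerSet",
    "MatchResult",
    "ColocReport",
    "CountSummary",
    "shift_correlation",
    "rotated_control",
    "coloc_curves",
    "coloc_test",
    "match_markers",
    "aggregate_counts",
]

DEFAULT_MAX_SHIFT_PX = 50
DEFAULT_CUTOFF_UM = 12.0


# ---------------------------------------------------------------------------
# Shift correlation
# ---------------------------------------------------------------------------


def _peak(dx: np.ndarray, r: np.ndarray) -> tuple[int, float]:
    """Argmax of r; ties resolved towards the smallest |dx|, then smaller dx."""
    best = np.flatnonzero(r == np.nanmax(r))
    order = sorted(best, key=lambda i: (abs(int(dx[i])), int(dx[i])))
    i = order[0]
    return int(dx[i]), float(r[i])


@dataclass
class ShiftCorrelationCurve:
    """Pearson r vs integer displacement dx, with its rotated-control twin."""

    dx: np.ndarray
    r: np.ndarray
    control_r: np.ndarray | None = None

    @property
    def peak_dx(self) -> int:
        return _peak(self.dx, self.r)[0]

    @property
    def peak_r(self) -> float:
        return _peak(self.dx, self.r)[1]

    @property
    def control_peak_dx(self) -> int:
        if self.control_r is None:
            raise InvalidParameterError("curve has no rotated-control data")
        return _peak(self.dx, self.control_r)[0]

    @property
    def control_peak_r(self) -> float:
        if self.control_r is None:
            raise InvalidParameterError("curve has no rotated-control data")
        return _peak(self.dx, self.control_r)[1]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x.ravel().astype(np.float64)
    y = y.ravel().astype(np.float64)
    xm = x - x.mean()
    ym = y - y.mean()
    denom = np.sqrt((xm * xm).sum() * (ym * ym).sum())
    if denom == 0.0:
        return 0.0  # constant overlap: define r = 0 rather than NaN
    return float((xm * ym).sum() / denom)


def shift_correlation(
    a: np.ndarray, b: np.ndarray, max_shift: int = DEFAULT_MAX_SHIFT_PX, axis: int = 1
) -> ShiftCorrelationCurve:
    """Pearson r between ``a`` and ``b`` displaced by each dx in −D..+D.

    ``axis=1`` (default) shifts along columns; ``axis=0`` gives the
    equivalent vertical-displacement curve. Rasters must share their shape,
    be non-constant, and ``max_shift`` must be below half the shifted side.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 2:
        raise InvalidParameterError(f"rasters must be 2-D and share a shape, got {a.shape} vs {b.shape}")
    if axis not in (0, 1):
        raise InvalidParameterError("axis must be 0 or 1")
    if axis == 0:
        a, b = a.T, b.T
    side = a.shape[1]
    if not 0 <= max_shift < side / 2:
        raise InvalidParameterError(f"max_shift {max_shift} must satisfy 0 <= D < side/2 = {side / 2}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant raster")
    dxs = np.arange(-max_shift, max_shift + 1, dtype=int)
    rs = np.empty(dxs.size, dtype=float)
    for i, dx in enumerate(dxs):
        if dx >= 0:  # b'(c) = b(c - dx): compare a[:, dx:] with b[:, :side-dx]
            av, bv = a[:, dx:], b[:, : side - dx]
        else:
            av, bv = a[:, :side + dx], b[:, -dx:]
        rs[i] = _pearson(av, bv)
    return ShiftCorrelationCurve(dx=dxs, r=rs)


def rotated_control(
    a: np.ndarray, b: np.ndarray, max_shift: int = DEFAULT_MAX_SHIFT_PX, axis: int = 1
) -> ShiftCorrelationCurve:
    """Shift correlation after rotating ``b`` by 90° (the null pairing)."""
    b = np.asarray(b)
    if b.ndim != 2 or b.shape[0] != b.shape[1]:
        raise InvalidParameterError(f"rotated control needs a square raster, got {b.shape}")
    return shift_correlation(a, np.rot90(b), max_shift=max_shift, axis=axis)


def coloc_curves(
    a: np.ndarray, b: np.ndarray, max_shift: int = DEFAULT_MAX_SHIFT_PX, axis: int = 1
) -> ShiftCorrelationCurve:
    """Test curve and rotated-control curve on one dx grid."""
    curve = shift_correlation(a, b, max_shift=max_shift, axis=axis)
    curve.control_r = rotated_control(a, b, max_shift=max_shift, axis=axis).r
    return curve


@dataclass
class ColocReport:
    """Cohort-level shift-correlation summary across samples."""

    n: int
    mean_peak_dx: float
    sem_peak_dx: float
    mean_peak_r: float
    mean_control_peak_r: float
    t_stat: float
    p_value: float
    degenerate: bool = False


def coloc_test(curves: list[ShiftCorrelationCurve]) -> ColocReport:
    """Paired t-test of per-sample peak r against the rotated control.

    Needs at least two samples, each carrying both curves. A zero-variance
    difference is flagged ``degenerate`` with p reported at the smallest
    positive float (or 1 when the difference is identically zero).
    """
    if len(curves) < 2:
        raise DegreesOfFreedomError("coloc_test needs at least two samples")
    peak_dx = np.array([c.peak_dx for c in curves], dtype=float)
    peak_r = np.array([c.peak_r for c in curves], dtype=float)
    control_r = np.array([c.control_peak_r for c in curves], dtype=float)
    diffs = peak_r - control_r
    degenerate = bool(np.ptp(diffs) == 0)
    if degenerate:
        if diffs[0] == 0.0:
            t_stat, p_value = 0.0, 1.0
        else:
            t_stat = float(np.inf if diffs[0] > 0 else -np.inf)
            p_value = float(np.finfo(float).tiny)
    else:
        t_stat, p_value = (float(v) for v in stats.ttest_rel(peak_r, control_r))
    return ColocReport(
        n=len(curves),
        mean_peak_dx=float(peak_dx.mean()),
        sem_peak_dx=float(peak_dx.std(ddof=1) / np.sqrt(len(curves))),
        mean_peak_r=float(peak_r.mean()),
        mean_control_peak_r=float(control_r.mean()),
        t_stat=t_stat,
        p_value=p_value,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Marker matching
# ---------------------------------------------------------------------------


@dataclass
class MarkerSet:
    """Point annotations in μm coordinates for one channel.

    ``points`` is an (n, 2) array of (x, y) positions; ``replicate`` indexes
    repeated manual counts of the same material.
    """

    points: np.ndarray
    channel: str = ""
    replicate: int = 1

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if not np.all(np.isfinite(self.points)):
            raise InvalidParameterError("marker coordinates must be finite")
        if self.replicate < 1:
            raise InvalidParameterError("replicate index must be >= 1")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class MatchResult:
    """One-to-one proximity matching between two marker sets."""

    pairs: list[tuple[int, int, float]]
    n_colocalized: int
    unmatched_a: int
    unmatched_b: int
    ambiguous: bool = False


def match_markers(a: MarkerSet, b: MarkerSet, cutoff_um: float = DEFAULT_CUTOFF_UM) -> MatchResult:
    """Greedy one-to-one matching by globally closest pair within the cutoff.

    Repeatedly pairs the closest unmatched cross-channel pair until no pair
    within ``cutoff_um`` remains. ``ambiguous`` is flagged when some matched
    point had more than one candidate partner within the cutoff (clustered
    annotations where the pairing is not forced by the data).
    """
    if not cutoff_um > 0:
        raise InvalidParameterError("cutoff_um must be > 0")
    na, nb = len(a), len(b)
    if na == 0 or nb == 0:
        return MatchResult(pairs=[], n_colocalized=0, unmatched_a=na, unmatched_b=nb)
    diff = a.points[:, None, :] - b.points[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    within = dist <= cutoff_um
    ambiguous = bool(np.any(within.sum(axis=1) > 1) or np.any(within.sum(axis=0) > 1))
    work = np.where(within, dist, np.inf)
    pairs: list[tuple[int, int, float]] = []
    while np.isfinite(work).any():
        i, j = np.unravel_index(int(np.argmin(work)), work.shape)
        pairs.append((int(i), int(j), float(dist[i, j])))
        work[i, :] = np.inf
        work[:, j] = np.inf
    return MatchResult(
        pairs=pairs,
        n_colocalized=len(pairs),
        unmatched_a=na - len(pairs),
        unmatched_b=nb - len(pairs),
        ambiguous=ambiguous,
    )


@dataclass
class CountSummary:
    """Mean ± SD of totals and colocalized counts across manual replicates."""

    n_replicates: int
    mean_total_a: float
    sd_total_a: float | None
    mean_total_b: float
    sd_total_b: float | None
    mean_colocalized: float
    sd_colocalized: float | None


def _mean_sd(vals: np.ndarray) -> tuple[float, float | None]:
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size > 1 else None
    return mean, sd


def aggregate_counts(results: list[MatchResult]) -> CountSummary:
    """Aggregate replicate matchings (e.g. counts repeated three times)."""
    if len(results) == 0:
        raise DegreesOfFreedomError("aggregate_counts needs at least one replicate")
    coloc = np.array([r.n_colocalized for r in results], dtype=float)
    tot_a = np.array([r.n_colocalized + r.unmatched_a for r in results], dtype=float)
    tot_b = np.array([r.n_colocalized + r.unmatched_b for r in results], dtype=float)
    ma, sa = _mean_sd(tot_a)
    mb, sb = _mean_sd(tot_b)
    mc, sc = _mean_sd(coloc)
    return CountSummary(
        n_replicates=len(results),
        mean_total_a=ma,
        sd_total_a=sa,
        mean_total_b=mb,
        sd_total_b=sb,
        mean_colocalized=mc,
        sd_colocalized=sc,
    )
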