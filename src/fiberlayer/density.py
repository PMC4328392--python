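"""Global thresholding and layer-resolved signal-density estimation.

Detection model: for each animal, pool the pixel values of *all* of its
preprocessed samples (every layer together) and call signal any pixel
strictly above ``mean + k·SD`` of that pool (default k = 6). The pooled SD
is the population SD — at millions of pooled pixels the n vs n−1 choice is
negligible, but fixing it keeps runs bit-reproducible. Because the
threshold is fitted to each animal's own data, scaling an animal's images
by any positive constant leaves its detections unchanged.

Signal density is the number of detected pixels over the number analysed,
times 100: the μm² conversions of numerator and denominator cancel, so the
reported unit μm²/100 μm² equals percent area; the calibration is still
carried on each record for traceability.

Group comparison follows the field's convention: one observation per
animal per layer, one-way ANOVA across layers, Tukey HSD post-hoc
pairwise tests, and per-layer mean ± SEM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegreesOfFreedomError, NoDataError

__all__ = [
    "ThresholdModel",
    "DensityRecord",
    "LayerComparison",
    "fit_threshold",
    "detect_signal",
    "layer_density",
    "compare_layers",
    "threshold_sensitivity",
]


@dataclass(frozen=True)
class ThresholdModel:
    """Per-animal global detection threshold ``mean + k·SD``."""

    global_mean: float
    global_sd: float
    k: float = 6.0

    @property
    def threshold(self) -> float:
        return self.global_mean + self.k * self.global_sd


@dataclass(frozen=True)
class DensityRecord:
    """Layer-resolved signal density for one animal.

    ``density`` is in μm²/100 μm² (= 100 × detected/total pixel fraction).
    """

    animal: str
    layer: str
    detected_px: int
    total_px: int
    density: float
    resolution: float


def fit_threshold(samples: Sequence[np.ndarray], k: float = 6.0) -> ThresholdModel:
    """Fit the pooled mean/SD threshold over all samples of one animal.

    ``samples`` are the preprocessed sample rasters of every layer of one
    animal, pooled together into the per-animal "global" statistics.
    """
    if len(samples) == 0:
        raise NoDataError("fit_threshold needs at least one sample")
    pooled = np.concatenate([np.asarray(s, dtype=np.float64).ravel() for s in samples])
    if pooled.size == 0:
        raise NoDataError("fit_threshold received only empty samples")
    return ThresholdModel(global_mean=float(pooled.mean()), global_sd=float(pooled.std(ddof=0)), k=float(k))


def detect_signal(sample: np.ndarray, model: ThresholdModel) -> np.ndarray:
    """Binary detection raster: pixel is signal iff *strictly* above threshold."""
    return np.asarray(sample) > model.threshold


def layer_density(
    detections: Iterable[np.ndarray],
    resolution: float,
    animal: str = "",
    layer: str = "",
) -> DensityRecord:
    """Aggregate binary detections of one animal × one layer into a density."""
    detected = 0
    total = 0
    for det in detections:
        det = np.asarray(det, dtype=bool)
        detected += int(np.count_nonzero(det))
        total += int(det.size)
    if total == 0:
        raise NoDataError("layer_density needs at least one non-empty detection raster")
    return DensityRecord(
        animal=animal,
        layer=layer,
        detected_px=detected,
        total_px=total,
        density=100.0 * detected / total,
        resolution=resolution,
    )


@dataclass
class LayerComparison:
    """One-way ANOVA across layers plus Tukey HSD pairwise post-hoc tests."""

    anova_f: float
    anova_p: float
    summary: pd.DataFrame  # per-layer mean, sem, n
    tukey: pd.DataFrame  # pairwise: layer_a, layer_b, meandiff, p_adj, reject


def _records_to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame(
        [
            {"animal": r.animal, "layer": r.layer, "density": r.density}
            for r in records
        ]
    )


def compare_layers(records, alpha: float = 0.05) -> LayerComparison:
    """Compare per-animal densities across layers (animal = unit of analysis).

    ``records`` is an iterable of :class:`DensityRecord` or a DataFrame with
    ``layer`` and ``density`` columns. Requires at least two layers and two
    animals per layer. Degenerate all-equal data yields F = 0, p = 1.
    """
    df = _records_to_frame(records)
    groups = {layer: g["density"].to_numpy(dtype=float) for layer, g in df.groupby("layer")}
    if len(groups) < 2:
        raise DegreesOfFreedomError("compare_layers needs at least two layers")
    for layer, vals in groups.items():
        if len(vals) < 2:
            raise DegreesOfFreedomError(f"layer {layer!r} has fewer than two animals")

    values = [v for v in groups.values()]
    grand = np.concatenate(values).mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in values)
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in values)
    df_between = len(values) - 1
    df_within = sum(len(v) for v in values) - len(values)
    if ss_within == 0.0:
        if ss_between == 0.0:
            f_stat, p_val = 0.0, 1.0
        else:
            f_stat, p_val = float("inf"), 0.0
    else:
        f_stat = (ss_between / df_between) / (ss_within / df_within)
        p_val = float(stats.f.sf(f_stat, df_between, df_within))

    summary = (
        df.groupby("layer")["density"]
        .agg(mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)), n="count")
        .reset_index()
    )

    if ss_within > 0.0:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        res = pairwise_tukeyhsd(df["density"].to_numpy(float), df["layer"].to_numpy(), alpha=alpha)
        tukey = pd.DataFrame(
            data=res.summary().data[1:], columns=[str(c) for c in res.summary().data[0]]
        ).rename(columns={"group1": "layer_a", "group2": "layer_b", "p-adj": "p_adj"})
    else:
        names = sorted(groups)
        rows = []
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                diff = groups[b].mean() - groups[a].mean()
                rows.append(
                    dict(layer_a=a, layer_b=b, meandiff=diff, p_adj=1.0 if diff == 0 else 0.0, reject=diff != 0)
                )
        tukey = pd.DataFrame(rows)
    return LayerComparison(anova_f=float(f_stat), anova_p=float(p_val), summary=summary, tukey=tukey)


def threshold_sensitivity(
    samples_by_layer: dict[str, list[np.ndarray]],
    ks: Sequence[float] = (4.0, 5.0, 6.0, 7.0, 8.0),
    resolution: float = 7.0,
    animal: str = "",
) -> pd.DataFrame:
    """Sweep the threshold multiplier k and report per-layer densities.

    A convenience report for checking that conclusions are not sensitive to
    the exact cutoff; the threshold is refitted on the pooled samples for
    each k (the pooled mean/SD do not change, only the multiplier).
    """
    pooled = [s for samples in samples_by_layer.values() for s in samples]
    rows = []
    for k in ks:
        model = fit_threshold(pooled, k=k)
        for layer, samples in samples_by_layer.items():
            rec = layer_density(
                [detect_signal(s, model) for s in samples], resolution, animal=animal, layer=layer
            )
            rows.append(dict(k=k, layer=layer, density=rec.density, detected_px=rec.detected_px))
    return pd.DataFrame(rows)
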