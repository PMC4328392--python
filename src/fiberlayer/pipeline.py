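"""End-to-end runs wiring the stages into the two experiment shapes.

``run_synthesize`` writes a complete runnable cohort (masks, channels,
ground truth); ``run_density`` executes sampling → per-sample preprocessing
→ pooled thresholding → layer densities → across-layer statistics;
``run_coloc`` computes shift-correlation curves with rotated controls and
the paired test; ``run_associate`` correlates projection composition with
infection composition. Every run persists its intermediates, writes a
provenance YAML (config snapshot, package version, seed), and is
bit-identical when repeated with the same config and inputs.

All stage randomness derives from the single top-level ``seed`` via
``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import copy
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .coloc import coloc_curves, coloc_test
from .core import LAYER_NAMES, CalibratedImage
from .density import compare_layers, detect_signal, fit_threshold, layer_density
from .errors import NoDataError, PlacementFailureError
from .preprocess import PreprocessConfig, preprocess
from .sampling import SamplingConfig, extract_samples, place_rois
from .synthetic import (
    FiberFieldSpec,
    NoiseSpec,
    SectionGeometry,
    apply_noise,
    generate_channel_pair,
    generate_cohort_summaries,
    generate_fiber_channel,
    generate_section,
    uniform_mask,
)

log = logging.getLogger("fiberlayer")

__all__ = ["DEFAULT_CONFIG", "load_config", "run_synthesize", "run_density", "run_coloc", "run_associate"]


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "resolution": 7.0,
    "geometry": {"layer_radii_um": [250.0, 430.0, 610.0]},
    "cohort": {
        "n_animals": 3,
        "densities": {"GL": 0.014, "EPL": 0.0007, "GCL": 0.0008},
    },
    "fiber": {
        "fiber_width_um": 0.7,
        "fiber_amplitude": 600.0,
        "fiber_length_um": 1.0,
        "step_length_um": 2.0,
        "turn_sd": 0.35,
        "density_tolerance": 0.10,
        "render": "puncta",
    },
    "noise": {
        "gaussian_sd": 30.0,
        "speckle_rate": 5e-4,
        "impulse_amplitude": 4000.0,
        "background": [100.0, 40.0, 25.0],
    },
    "preprocess": {"despeckle_window": 3, "ball_radius_um": 30.0},
    "sampling": {
        "roi_side_um": 120.0,
        "n_per_layer": 10,
        "sector_deg": 36.0,
        "max_attempts_per_sector": 1000,
    },
    "density": {"k": 6.0},
    "coloc": {
        "n_samples": 20,
        "sample_side_um": 120.0,
        "density_um2_per_100um2": 1.5,
        "shared_fraction": 0.8,
        "jitter_sd_um": 0.3,
        "max_shift_px": 50,
        "cutoff_um": 12.0,
    },
    "association": {
        "n_drn_animals": 4,
        "n_mrn_animals": 3,
        "noise_cv": 0.10,
        "count_pseudocount": 1.0,
        "density_pseudocount": 1.0e-4,
        "infection_form": "log_ratio",
    },
    "plot": True,
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in (override or {}).items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Merge the default config with a YAML file and explicit overrides."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        loaded = io.load_yaml(path)
        if loaded:
            cfg = _deep_merge(cfg, loaded)
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    return cfg


def _sub_seed(seed: int, *path: int) -> int:
    """Deterministic, independent integer sub-seed below 2**31."""
    return int(np.random.SeedSequence([int(seed), *path]).generate_state(1)[0] % (2**31))


def _provenance(cfg: dict, stage: str) -> dict:
    return {"stage": stage, "package": "fiberlayer", "version": __version__, "config": copy.deepcopy(cfg)}


def _fiber_spec(cfg: dict, seed: int, densities: dict | None = None) -> FiberFieldSpec:
    fib = dict(cfg["fiber"])
    return FiberFieldSpec(
        per_layer_density=densities if densities is not None else dict(cfg["cohort"]["densities"]),
        seed=seed,
        **fib,
    )


def _noise_spec(cfg: dict) -> NoiseSpec:
    noi = dict(cfg["noise"])
    noi["background"] = tuple(noi.get("background", (0.0, 0.0, 0.0)))
    return NoiseSpec(**noi)


# ---------------------------------------------------------------------------
# synthesize
# ---------------------------------------------------------------------------


def run_synthesize(cfg: dict, out_dir: str | Path) -> Path:
    """Write a complete synthetic cohort: sections, channel pairs, summaries.

    Layout: ``animal_XX/`` directories with ``mask.tif`` (+ legend),
    ``dapi.tif``, ``egfp.tif`` and ``truth.csv``; a ``coloc/`` directory of
    paired-channel samples with their truth; ``summary.csv`` with the
    mixed-injection per-animal composition table; ``provenance.yaml``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    res = float(cfg["resolution"])
    geometry = SectionGeometry(
        layer_radii_um=tuple(cfg["geometry"]["layer_radii_um"]), resolution=res
    )
    noise = _noise_spec(cfg)

    truth_rows = []
    for i in range(int(cfg["cohort"]["n_animals"])):
        animal = f"animal_{i + 1:02d}"
        adir = out / animal
        adir.mkdir(exist_ok=True)
        mask, dapi = generate_section(geometry, seed=_sub_seed(seed, 1, i))
        spec = _fiber_spec(cfg, seed=_sub_seed(seed, 2, i))
        fiber, truth = generate_fiber_channel(mask, spec)
        fiber = apply_noise(fiber, noise, rng=_sub_seed(seed, 3, i))
        dapi = apply_noise(dapi, noise, rng=_sub_seed(seed, 4, i))
        io.write_mask(adir / "mask.tif", mask)
        io.write_image(adir / "dapi.tif", dapi)
        io.write_image(adir / "egfp.tif", fiber)
        for layer in LAYER_NAMES:
            truth_rows.append(
                dict(
                    animal=animal,
                    layer=layer,
                    true_density_um2_per_100um2=truth.per_layer_true_density[layer],
                    n_fibers=(truth.n_fibers or {}).get(layer, 0),
                )
            )
        log.info("synthesized %s (densities %s)", animal, truth.per_layer_true_density)
    pd.DataFrame(truth_rows).to_csv(out / "truth.csv", index=False)

    # paired-channel colocalization samples on plain single-layer patches
    ccfg = cfg["coloc"]
    cdir = out / "coloc"
    cdir.mkdir(exist_ok=True)
    side_px = int(round(float(ccfg["sample_side_um"]) * res))
    coloc_truth = []
    for j in range(int(ccfg["n_samples"])):
        patch = uniform_mask(side_px, res, layer="GL")
        spec = _fiber_spec(
            cfg,
            seed=_sub_seed(seed, 5, j),
            densities={"GL": float(ccfg["density_um2_per_100um2"])},
        )
        a, b, truth = generate_channel_pair(
            patch,
            spec,
            shared_fraction=float(ccfg["shared_fraction"]),
            jitter_sd_um=float(ccfg["jitter_sd_um"]),
            noise=noise,
        )
        io.write_image(cdir / f"sample_{j:02d}_egfp.tif", a)
        io.write_image(cdir / f"sample_{j:02d}_5ht.tif", b)
        coloc_truth.append(
            dict(
                sample=j,
                shared_fraction=truth.shared_fiber_fraction,
                n_fibers=sum((truth.n_fibers or {}).values()),
                n_shared=truth.n_shared_fibers,
            )
        )
    pd.DataFrame(coloc_truth).to_csv(cdir / "truth.csv", index=False)

    acfg = cfg["association"]
    summaries = generate_cohort_summaries(
        n_drn_animals=int(acfg["n_drn_animals"]),
        n_mrn_animals=int(acfg["n_mrn_animals"]),
        seed=_sub_seed(seed, 6),
        noise_cv=float(acfg["noise_cv"]),
    )
    summaries.to_csv(out / "summary.csv", index=False)
    io.save_yaml(out / "provenance.yaml", _provenance(cfg, "synthesize"))
    return out


# ---------------------------------------------------------------------------
# density
# ---------------------------------------------------------------------------


def run_density(cfg: dict, data_dir: str | Path, out_dir: str | Path):
    """Layer-density profiling of every animal in ``data_dir``.

    Expects ``animal_*/mask.tif`` and ``animal_*/egfp.tif``. Persists
    per-animal ROI tables, the density table, and the across-layer ANOVA /
    Tukey report. Returns ``(records, LayerComparison | None)``.
    """
    data = Path(data_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res = float(cfg["resolution"])
    pcfg = PreprocessConfig(**cfg["preprocess"])
    k = float(cfg["density"]["k"])
    seed = int(cfg["seed"])

    animal_dirs = sorted(d for d in data.glob("animal_*") if d.is_dir())
    if not animal_dirs:
        raise NoDataError(f"no animal_* directories under {data}")
    records = []
    for ai, adir in enumerate(animal_dirs):
        animal = adir.name
        mask = io.read_mask(adir / "mask.tif", resolution=res)
        img = io.read_image(adir / "egfp.tif", resolution=res, channel="EGFP")
        mask.check_same_grid(img)
        scfg = SamplingConfig(seed=_sub_seed(seed, 11, ai), **cfg["sampling"])
        samples_by_layer: dict[str, list[np.ndarray]] = {}
        all_rois = []
        for layer in mask.layer_names:
            placement = place_rois(mask, layer, scfg)
            if not placement.rois:
                raise PlacementFailureError(
                    f"{animal}: no ROI could be placed in layer {layer!r} "
                    f"(failed sectors: {placement.failed_sectors})"
                )
            if placement.failed_sectors:
                log.warning(
                    "%s layer %s: placement failed in sectors %s",
                    animal,
                    layer,
                    placement.failed_sectors,
                )
            samples = extract_samples(img, placement.rois)
            samples_by_layer[layer] = [
                preprocess(CalibratedImage(s.pixels, res, img.channel), pcfg).pixels
                for s in samples
            ]
            all_rois.extend(placement.rois)
        io.write_rois_csv(out / f"{animal}_rois.csv", all_rois)
        if cfg.get("plot", True):
            _plot_roi_overlay(mask, all_rois, out / f"{animal}_rois.png")
        model = fit_threshold([s for ss in samples_by_layer.values() for s in ss], k=k)
        log.info("%s threshold: mean=%.3f sd=%.3f thr=%.3f", animal, model.global_mean, model.global_sd, model.threshold)
        for layer, samples in samples_by_layer.items():
            detections = [detect_signal(s, model) for s in samples]
            records.append(layer_density(detections, res, animal=animal, layer=layer))
    io.write_density_csv(out / "density.csv", records)

    comparison = None
    animals_per_layer = min(
        sum(1 for r in records if r.layer == layer) for layer in LAYER_NAMES
    )
    if animals_per_layer >= 2:
        comparison = compare_layers(records)
        comparison.summary.to_csv(out / "layer_summary.csv", index=False)
        comparison.tukey.to_csv(out / "tukey.csv", index=False)
        report = [
            "Layer-density comparison (unit: animal; density in um^2/100 um^2)",
            f"one-way ANOVA across layers: F = {comparison.anova_f:.4g}, p = {comparison.anova_p:.4g}",
            comparison.summary.to_string(index=False),
            comparison.tukey.to_string(index=False),
        ]
        (out / "stats.txt").write_text("\n\n".join(report) + "\n")
    io.save_yaml(out / "provenance.yaml", _provenance(cfg, "density"))
    return records, comparison


def _plot_roi_overlay(mask, rois, path: Path) -> None:
    """Visual audit: layer mask with sampled ROI footprints outlined."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    step = max(1, mask.shape[0] // 1200)  # keep the rendered raster small
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(mask.labels[::step, ::step], cmap="viridis", interpolation="nearest")
    for roi in rois:
        r0, c0, r1, c1 = roi.bounds
        ax.add_patch(
            Rectangle(
                (c0 / step, r0 / step),
                (c1 - c0) / step,
                (r1 - r0) / step,
                fill=False,
                edgecolor="white",
                linewidth=0.8,
            )
        )
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=120, metadata={"Software": "fiberlayer"})
    plt.close(fig)


# ---------------------------------------------------------------------------
# coloc
# ---------------------------------------------------------------------------


def run_coloc(cfg: dict, data_dir: str | Path, out_dir: str | Path):
    """Shift-correlation assay over paired-channel samples in ``data_dir``.

    Expects ``sample_*_egfp.tif`` / ``sample_*_5ht.tif`` pairs (a ``coloc/``
    subdirectory is used when present). Returns ``(curves, ColocReport)``.
    """
    data = Path(data_dir)
    if (data / "coloc").is_dir():
        data = data / "coloc"
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res = float(cfg["resolution"])
    pcfg = PreprocessConfig(**cfg["preprocess"])
    max_shift = int(cfg["coloc"]["max_shift_px"])

    a_paths = sorted(data.glob("sample_*_egfp.tif"))
    if not a_paths:
        raise NoDataError(f"no sample_*_egfp.tif files under {data}")
    curves = []
    for a_path in a_paths:
        b_path = a_path.with_name(a_path.name.replace("_egfp", "_5ht"))
        if not b_path.exists():
            raise NoDataError(f"missing second channel for {a_path.name}: {b_path.name}")
        a = preprocess(io.read_image(a_path, resolution=res, channel="EGFP"), pcfg)
        b = preprocess(io.read_image(b_path, resolution=res, channel="5-HT"), pcfg)
        curves.append(coloc_curves(a.pixels, b.pixels, max_shift=max_shift))
    report = coloc_test(curves)
    io.write_curves_csv(out / "curves.csv", curves)
    io.save_yaml(
        out / "coloc_report.yaml",
        {
            "n_samples": report.n,
            "mean_peak_dx_px": report.mean_peak_dx,
            "sem_peak_dx_px": report.sem_peak_dx,
            "mean_peak_r": report.mean_peak_r,
            "mean_control_peak_r": report.mean_control_peak_r,
            "paired_t": report.t_stat,
            "p_value": report.p_value,
            "degenerate": report.degenerate,
        },
    )
    if cfg.get("plot", True):
        _plot_curves(curves, out / "curves.png")
    io.save_yaml(out / "provenance.yaml", _provenance(cfg, "coloc"))
    return curves, report


def _plot_curves(curves, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    dx = curves[0].dx
    test = np.stack([c.r for c in curves])
    ctrl = np.stack([c.control_r for c in curves])
    for mat, color, label in ((test, "tab:green", "test"), (ctrl, "0.5", "90° rotated control")):
        mean = mat.mean(axis=0)
        sem = mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0])
        ax.plot(dx, mean, color=color, label=label)
        ax.fill_between(dx, mean - sem, mean + sem, color=color, alpha=0.3, lw=0)
    ax.set_xlabel("dx (px)")
    ax.set_ylabel("Pearson r")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150, metadata={"Software": "fiberlayer"})
    plt.close(fig)


# ---------------------------------------------------------------------------
# associate
# ---------------------------------------------------------------------------


def run_associate(cfg: dict, summary_csv: str | Path, out_dir: str | Path):
    """Correlate projection composition with infection composition.

    ``summary_csv`` needs columns ``animal, n_drn, n_mrn, d_gl, d_gcl``.
    Returns the :class:`~fiberlayer.association.AssociationResult`.
    """
    from .association import correlate

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    acfg = cfg["association"]
    df = pd.read_csv(summary_csv)
    result = correlate(
        df,
        count_pseudocount=float(acfg["count_pseudocount"]),
        density_pseudocount=float(acfg["density_pseudocount"]),
        infection_form=str(acfg["infection_form"]),
    )
    result.table.to_csv(out / "association.csv", index=False)
    io.save_yaml(
        out / "association_report.yaml",
        {
            "r": result.r,
            "p": result.p,
            "n": result.n,
            "infection_form": str(acfg["infection_form"]),
            "count_pseudocount": float(acfg["count_pseudocount"]),
            "density_pseudocount": float(acfg["density_pseudocount"]),
        },
    )
    if cfg.get("plot", True):
        _plot_association(result, out / "association.png")
    io.save_yaml(out / "provenance.yaml", _provenance(cfg, "associate"))
    return result


def _plot_association(result, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from .association import abundance_rgb

    fig, ax = plt.subplots(figsize=(4.5, 4))
    colors = [abundance_rgb(v) for v in result.abundance]
    ax.scatter(result.infection, result.abundance, c=colors, edgecolors="k", s=60)
    ax.set_xlabel("log10 MRN/DRN infection ratio")
    ax.set_ylabel("log10 GL/GCL label ratio")
    ax.set_title(f"r = {result.r:.2f}, p = {result.p:.3g}, n = {result.n}")
    fig.tight_layout()
    fig.savefig(path, dpi=150, metadata={"Software": "fiberlayer"})
    plt.close(fig)
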