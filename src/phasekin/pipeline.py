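"""End-to-end PVM and AFM pipelines with file outputs.

Configuration is a plain mapping (read from YAML/JSON); each pipeline
consumes either an input path or a synthetic-generation block, runs the
corresponding stages, and writes CSV tables, a JSON summary with an output
manifest, and PNG plots.  All randomness flows from the single config
seed, so reruns are byte-identical in the CSV outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import afm as afm_mod
from . import synthetic
from .detect import PeakFindParams, detect_pixel_transitions, trace_summary
from .synchrony import (
    SuperpixelScheme,
    bivariate_histogram,
    classify_transitions,
    resample_superpixels,
    synchrony_fraction,
    synchrony_profile,
)
from .video import RoiSpec, extract_roi, load_video_frames

logger = logging.getLogger(__name__)


@dataclass
class PvmConfig:
    """PVM pipeline configuration: exactly one of ``input_path`` or
    ``synthetic`` (SyntheticVideoParams) must be set."""

    input_path: str | None = None
    frame_interval: float = synthetic.DEFAULT_FRAME_INTERVAL
    pixel_size_nm: float = 24.75
    start_frame: int = 0
    roi: tuple[int, int, int] | None = None
    synthetic: synthetic.SyntheticVideoParams | None = None
    trace_smooth_seconds: float = 15.2
    deriv_smooth_seconds: float = 7.78
    peaks: PeakFindParams = field(default_factory=PeakFindParams)
    sampling_areas: tuple[int, ...] | None = None
    k: int = 3
    n_restarts: int = 10
    synchrony_window_s: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.synthetic is None):
            raise ValueError("config must set exactly one of input_path / synthetic")


def _kmeans_seed(seed: int) -> int:
    return int(seed) % (2**31 - 1)


def run_pvm_pipeline(config: PvmConfig, outdir: str | Path) -> dict:
    """Full PVM analysis: load/generate -> detect -> classify -> synchrony.

    Writes events.csv, catalog.csv, synchrony.csv, histogram.csv,
    summary.json and plots; returns the summary dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("PVM pipeline starting (outdir=%s)", outdir)

    if config.synthetic is not None:
        video, _truth = synthetic.generate_video(config.synthetic)
    else:
        video = load_video_frames(
            config.input_path,
            frame_interval=config.frame_interval,
            pixel_size=config.pixel_size_nm,
            start_frame=config.start_frame,
        )
    if config.roi is not None:
        video = extract_roi(video, RoiSpec(*config.roi))

    roi_side = video.height
    if video.height != video.width:
        raise ValueError("PVM analysis expects a square ROI; pass config.roi")
    areas = config.sampling_areas or tuple(
        a for a in SuperpixelScheme().sampling_areas if roi_side % a == 0
    )
    scheme = SuperpixelScheme(roi_side=roi_side, sampling_areas=areas)

    detections = detect_pixel_transitions(
        video,
        trace_smooth_seconds=config.trace_smooth_seconds,
        deriv_smooth_seconds=config.deriv_smooth_seconds,
        params=config.peaks,
    )
    logger.info(
        "detected %d events over %d pixels (%d failed)",
        len(detections.events),
        video.height * video.width,
        detections.n_failed,
    )
    catalog = classify_transitions(
        detections.events,
        k=config.k,
        n_restarts=config.n_restarts,
        seed=_kmeans_seed(config.seed),
        n_pixels=roi_side**2,
    )

    catalogs = {1: catalog} if 1 in areas else {}
    for area in areas:
        if area == 1:
            continue
        sub = resample_superpixels(video, area)
        det = detect_pixel_transitions(
            sub,
            trace_smooth_seconds=config.trace_smooth_seconds,
            deriv_smooth_seconds=config.deriv_smooth_seconds,
            params=config.peaks,
        )
        catalogs[area] = classify_transitions(
            det.events,
            k=config.k,
            n_restarts=config.n_restarts,
            seed=_kmeans_seed(config.seed),
            n_pixels=(roi_side // area) ** 2,
        )
    profile = synchrony_profile(catalogs)
    hist = bivariate_histogram(catalog.events)
    fractions = {}
    for label in catalog.summary.index:
        if catalog.summary.loc[label, "n_events"] > 0:
            fractions[label] = synchrony_fraction(
                catalog.events,
                label,
                window_seconds=config.synchrony_window_s,
                bin_width_s=video.frame_interval,
            )

    center = video.data[:, video.height // 2, video.width // 2].astype(np.float64)
    initial, final, loss = trace_summary(center)

    files = {
        "events": outdir / "events.csv",
        "catalog": outdir / "catalog.csv",
        "synchrony": outdir / "synchrony.csv",
        "histogram": outdir / "histogram.csv",
    }
    catalog.events.to_csv(files["events"], index=False, float_format="%.6f")
    catalog.summary.to_csv(files["catalog"], float_format="%.6f")
    profile.table.to_csv(files["synchrony"], index=False, float_format="%.6f")
    pd.DataFrame(
        hist.counts,
        index=pd.Index(0.5 * (hist.time_edges[:-1] + hist.time_edges[1:]), name="time_s"),
        columns=0.5 * (hist.width_edges[:-1] + hist.width_edges[1:]),
    ).to_csv(files["histogram"], float_format="%.6f")
    plot_files = _plot_pvm(outdir, video, catalog, profile, hist)
    files.update(plot_files)

    summary = {
        "pipeline": "pvm",
        "seed": config.seed,
        "roi_side_px": roi_side,
        "n_pixels": roi_side**2,
        "n_frames": video.n_frames,
        "frame_interval_s": video.frame_interval,
        "n_events": int(len(catalog.events)),
        "n_failed_pixels": detections.n_failed,
        "transitions": json.loads(catalog.summary.to_json(orient="index")),
        "synchrony_fractions": fractions,
        "scale_invariance_max_dev_s": profile.invariance,
        "center_trace": {"initial": initial, "final": final, "fractional_loss": loss},
        "outputs": {k: str(v) for k, v in files.items()},
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary


def _plot_pvm(outdir, video, catalog, profile, hist) -> dict:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    files = {}
    fig, ax = plt.subplots(figsize=(6, 4))
    center = video.data[:, video.height // 2, video.width // 2]
    ax.plot(video.times, center, lw=0.8)
    ax.set(xlabel="time (s)", ylabel="intensity (a.u.)", title="center-pixel trace")
    files["trace_plot"] = outdir / "center_trace.png"
    fig.savefig(files["trace_plot"], dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    extent = [
        hist.time_edges[0],
        hist.time_edges[-1],
        hist.width_edges[0],
        hist.width_edges[-1],
    ]
    ax.imshow(
        np.log1p(hist.counts.T), origin="lower", aspect="auto", extent=extent, cmap="viridis"
    )
    ax.set(xlabel="transition time (s)", ylabel="half-width (s)", title="event histogram")
    files["histogram_plot"] = outdir / "bivariate_histogram.png"
    fig.savefig(files["histogram_plot"], dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, sub in profile.table.groupby("label"):
        ax.errorbar(
            sub["sampling_area_px"], sub["mean_time_s"], yerr=sub["sd_time_s"],
            marker="o", capsize=3, label=label,
        )
    ax.set(xscale="log", xlabel="sampling area side (px)", ylabel="transition time (s)")
    ax.legend()
    files["synchrony_plot"] = outdir / "synchrony_profile.png"
    fig.savefig(files["synchrony_plot"], dpi=120)
    plt.close(fig)
    return files


# ---------------------------------------------------------------------------
# AFM


@dataclass
class AfmSyntheticImage:
    """One synthetic image in an AFM series: lattice params plus optional
    mixed-phase regions (used instead of ``lattice`` when present)."""

    index: int
    lattice: synthetic.SyntheticLatticeParams | None = None
    regions: list[synthetic.RegionSpec] | None = None
    time_s: float | None = None


@dataclass
class AfmConfig:
    """AFM pipeline configuration: file inputs or a synthetic series."""

    input_paths: list[str] | None = None
    nm_per_px: float = synthetic.DEFAULT_NM_PER_PX
    synthetic_series: list[AfmSyntheticImage] | None = None
    min_spacing_nm: float = 2.0
    max_spacing_nm: float = 20.0
    references_nm: dict[str, float] = field(
        default_factory=lambda: dict(afm_mod.PHASE_REFERENCES_NM)
    )
    noise_sd_nm: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_paths is None) == (self.synthetic_series is None):
            raise ValueError("config must set exactly one of input_paths / synthetic_series")


def run_afm_pipeline(config: AfmConfig, outdir: str | Path) -> dict:
    """Measure unit cells over an AFM image series and build the c-axis
    time series.  Unreadable or unmeasurable images become flagged gap
    rows; the run continues."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    measurements: list[afm_mod.UnitCellMeasurement] = []

    if config.synthetic_series is not None:
        for i, item in enumerate(config.synthetic_series):
            if item.regions:
                topo, _ = synthetic.generate_mixed_topograph(
                    item.regions, noise_sd=config.noise_sd_nm, seed=config.seed + i
                )
                topo.index = item.index
                measurements += [
                    _with_time(m, item.time_s)
                    for m in afm_mod.measure_regions(
                        topo,
                        [r.bounds for r in item.regions],
                        config.min_spacing_nm,
                        config.max_spacing_nm,
                    )
                ]
            else:
                from dataclasses import replace as _replace

                lat = _replace(item.lattice, seed=config.seed + i)
                topo, _ = synthetic.generate_topograph(lat)
                topo.index = item.index
                measurements.append(_measure_one(topo, config, item.time_s))
    else:
        for i, path in enumerate(config.input_paths):
            try:
                topo = afm_mod.load_topograph(path, config.nm_per_px, index=i)
            except Exception:
                logger.warning("unreadable AFM image %s; flagged as gap", path, exc_info=True)
                measurements.append(afm_mod.UnitCellMeasurement.failure(index=i))
                continue
            measurements.append(_measure_one(topo, config, None))

    cells = pd.DataFrame(
        [
            {
                "image_index": m.index,
                "region": m.region,
                "a_len_nm": m.a_len_nm,
                "c_len_nm": m.c_len_nm,
                "angle_deg": m.angle_deg,
                "ok": m.ok,
            }
            for m in measurements
        ],
        columns=["image_index", "region", "a_len_nm", "c_len_nm", "angle_deg", "ok"],
    )
    files = {"unit_cells": outdir / "unit_cells.csv", "caxis": outdir / "caxis_timeseries.csv"}
    cells.to_csv(files["unit_cells"], index=False, float_format="%.4f")
    if measurements:
        series = afm_mod.caxis_timeseries(measurements, config.references_nm)
        series.table.to_csv(files["caxis"], index=False, float_format="%.4f")
        files.update(_plot_afm(outdir, series))
        n_gaps = int((series.table["phase"] == "gap").sum())
    else:
        pd.DataFrame(
            columns=["image_index", "time_s", "region", "c_len_nm", "a_len_nm", "angle_deg", "phase"]
        ).to_csv(files["caxis"], index=False)
        series, n_gaps = None, 0

    summary = {
        "pipeline": "afm",
        "seed": config.seed,
        "n_images": len({m.index for m in measurements}) if measurements else 0,
        "n_measurements": len(measurements),
        "n_gaps": n_gaps,
        "phase_changes": series.phase_changes() if series is not None else 0,
        "outputs": {k: str(v) for k, v in files.items()},
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary


def _with_time(m: afm_mod.UnitCellMeasurement, time_s):
    m.time_s = time_s
    return m


def _measure_one(topo, config: AfmConfig, time_s):
    try:
        acf = afm_mod.autocorrelate(afm_mod.flatten_lines(topo))
        m = afm_mod.measure_unit_cell(
            acf, config.min_spacing_nm, config.max_spacing_nm, index=topo.index
        )
    except Exception:
        logger.warning("image %s failed; flagged as gap", topo.index, exc_info=True)
        m = afm_mod.UnitCellMeasurement.failure(index=topo.index)
    return _with_time(m, time_s)


def _plot_afm(outdir, series) -> dict:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    tab = series.table.dropna(subset=["c_len_nm"])
    for phase, sub in tab.groupby("phase"):
        ax.plot(sub["image_index"], sub["c_len_nm"], "o", label=phase)
    ax.set(xlabel="serial image number", ylabel="c-axis (nm)", title="c-axis time series")
    if len(tab):
        ax.legend()
    path = outdir / "caxis_timeseries.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return {"caxis_plot": path}
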