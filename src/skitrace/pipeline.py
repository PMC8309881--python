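"""End-to-end analysis pipeline and its configuration.

run_pipeline ties the stages together: read tracks, build the terrain
model, split and resample laps, compare against a reference group,
classify sub-techniques from the IMU stream, and summarise technique usage
over speed bins.  Every stage logs its parameters and row counts; outputs
are plain CSV/JSON so a re-run with the same config and inputs is
byte-identical (plots excluded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from skitrace import course as course_mod
from skitrace import distribution as dist_mod
from skitrace import performance as perf_mod
from skitrace import subtechnique as st_mod
from skitrace import track_io

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """All pipeline parameters in one place.

    Defaults match the analysis conventions of the framework: a 4 m minimum
    elevation difference for terrain segments, a 5 m distance grid, a 5 Hz
    low-pass cutoff, k = 5 neighbours and 0.25 m/s speed bins.
    """

    gnss: str = ""
    imu: str | None = None
    reference: list[str] = field(default_factory=list)
    course: str | None = None  # pre-built course JSON; else built from gnss
    train: str | None = None  # training-set CSV; else the packaged set
    out_dir: str = "out"
    lap_length: float = 2465.0
    n_laps: int = 4
    min_elev_diff_m: float = 4.0
    grid_m: float = 5.0
    cutoff_hz: float = 5.0
    filter_order: int = 4
    k: int = 5
    bin_width: float = 0.25
    seed: int = 0
    skip_classification: bool = False
    make_plots: bool = False

    def __post_init__(self):
        for name in ("lap_length", "n_laps", "min_elev_diff_m", "grid_m",
                     "cutoff_hz", "filter_order", "k", "bin_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError("config must be a mapping of key: value pairs")
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _load_series(path: str, cfg: AnalysisConfig) -> perf_mod.LapSeries:
    traj = track_io.read_gnss(path)
    traj = track_io.derive_speed(traj)
    laps = perf_mod.split_laps(traj, cfg.lap_length, cfg.n_laps)
    return perf_mod.interpolate_by_distance(laps, cfg.grid_m, cfg.lap_length)


def run_pipeline(cfg: AnalysisConfig) -> dict[str, Path]:
    """Run every configured stage; returns a name -> path map of outputs.

    Raises with a stage-named message on failure; nothing is written until
    all computation has succeeded, so a failed run leaves no partial bundle.
    """
    outputs: dict[str, object] = {}
    out = Path(cfg.out_dir)

    stage = "track_io"
    try:
        traj = track_io.read_gnss(cfg.gnss)
        traj = track_io.derive_speed(traj)
        logger.info("[%s] %d fixes, %.0f m total", stage, len(traj), traj.cum_dist[-1])

        stage = "course_segmentation"
        if cfg.course:
            model = course_mod.CourseModel.from_json(Path(cfg.course))
        else:
            profile = course_mod.build_profile(traj, cfg.lap_length, cfg.grid_m)
            model = course_mod.detect_segments(profile, cfg.min_elev_diff_m)
        logger.info("[%s] %d segments", stage, len(model.segments))

        stage = "lap_performance"
        laps = perf_mod.split_laps(traj, cfg.lap_length, cfg.n_laps)
        series = perf_mod.interpolate_by_distance(laps, cfg.grid_m, cfg.lap_length)
        comparison = None
        if cfg.reference:
            members = [_load_series(p, cfg) for p in cfg.reference]
            ref = perf_mod.group_reference(members)
            comparison = perf_mod.compare(series, ref, model)
        logger.info("[%s] %d laps on %d grid points", stage, len(laps), len(series.d))

        labels = distribution = summary = track = None
        if cfg.imu and not cfg.skip_classification:
            stage = "subtechnique"
            imu = track_io.read_imu_csv(cfg.imu)
            rec = track_io.SessionRecording("skier", traj, imu, n_laps=cfg.n_laps)
            rec = track_io.align_imu(rec)
            fspec = st_mod.FilterSpec(cfg.cutoff_hz, cfg.filter_order)
            windows = st_mod.make_windows(rec.imu, fspec)
            train = (
                st_mod.training_set_from_csv(cfg.train)
                if cfg.train
                else st_mod.default_training_set(seed=cfg.seed or 42, spec=fspec)
            )
            track = st_mod.classify_windows(train, windows, cfg.k)
            labels = st_mod.labels_to_distance(track, series.d, cfg.lap_length)
            logger.info("[%s] %d windows, %d cells", stage, len(windows), len(labels))

            stage = "distribution"
            binning = dist_mod.SpeedBinning(
                edges=np.arange(2.0, 11.0 + 1e-9, cfg.bin_width)
            )
            distribution = dist_mod.bin_by_speed(labels, series, binning)
            summary = dist_mod.range_summary(distribution)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc

    # all computation done: write the bundle
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["course"] = out / "course.json"
    model.to_json(paths["course"])
    paths["series"] = out / "series.csv"
    pd.DataFrame({"d": series.d, "speed": series.speed, "time": series.time}).to_csv(
        paths["series"], index=False
    )
    if comparison is not None:
        paths["comparison"] = out / "comparison.csv"
        table = comparison.per_terrain.copy()
        table["time_in_terrain_pct"] = [
            comparison.time_in_terrain.get(t, np.nan) for t in table.index
        ]
        table.to_csv(paths["comparison"])
        paths["continuous"] = out / "continuous.csv"
        pd.DataFrame(
            {
                "d": comparison.d,
                "speed": series.speed,
                "abs_speed_diff": comparison.abs_speed_diff,
                "rel_speed_diff_pct": comparison.rel_speed_diff,
                "accum_time_diff_s": comparison.accum_time_diff,
            }
        ).to_csv(paths["continuous"], index=False)
    if labels is not None:
        paths["labels"] = out / "labels.csv"
        pd.DataFrame(
            {"d_low": series.d[:-1], "d_high": series.d[1:], "label": labels}
        ).to_csv(paths["labels"], index=False)
        paths["window_labels"] = out / "window_labels.csv"
        pd.DataFrame(
            {"window_start": np.arange(len(track.window_labels)) * st_mod.HOP_SAMPLES,
             "cum_dist": track.window_dists, "label": track.window_labels}
        ).to_csv(paths["window_labels"], index=False)
        paths["distribution"] = out / "distribution.csv"
        distribution.to_frame().to_csv(paths["distribution"], index=False)
        paths["range_summary"] = out / "range_summary.csv"
        summary.to_csv(paths["range_summary"])
    if cfg.make_plots:
        paths.update(_make_plots(out, series, model, comparison, distribution))
    return paths


def _make_plots(out, series, model, comparison, distribution):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = {}
    fig, axes = plt.subplots(3 if comparison is not None else 1, 1,
                             figsize=(10, 8), sharex=True, squeeze=False)
    axes = axes.ravel()
    shade = {"UPHILL": "0.55", "FLAT": "0.8", "DOWNHILL": "0.93"}
    for ax in axes:
        for seg in model.segments:
            ax.axvspan(seg.start_m, seg.end_m, color=shade[seg.terrain.value], alpha=0.4)
    axes[0].plot(series.d, series.speed, lw=1.2)
    axes[0].set_ylabel("speed (m/s)")
    if comparison is not None:
        axes[1].plot(comparison.d, comparison.rel_speed_diff, lw=1.2)
        axes[1].set_ylabel("rel. speed diff (%)")
        axes[2].plot(comparison.d, comparison.accum_time_diff, lw=1.2)
        axes[2].set_ylabel("accum. time diff (s)")
    axes[-1].set_xlabel("lap distance (m)")
    paths["plot_pacing"] = out / "pacing.png"
    fig.tight_layout()
    fig.savefig(paths["plot_pacing"], dpi=120)
    plt.close(fig)

    if distribution is not None:
        from skitrace.subtechnique import CLASSES

        fig, ax = plt.subplots(figsize=(9, 4))
        e = distribution.binning.edges
        pct = distribution.pct("distance")
        bottom = np.zeros(distribution.binning.n_bins)
        for c, cls in enumerate(CLASSES):
            vals = np.nan_to_num(pct[:, c])
            ax.bar(e[:-1], vals, width=np.diff(e), align="edge",
                   bottom=bottom, label=cls)
            bottom += vals
        ax.set_xlabel("speed (m/s)")
        ax.set_ylabel("% of distance")
        ax.legend()
        paths["plot_distribution"] = out / "distribution.png"
        fig.tight_layout()
        fig.savefig(paths["plot_distribution"], dpi=120)
        plt.close(fig)
    return paths
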