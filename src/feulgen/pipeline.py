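"""End-to-end orchestration: simulate or ingest, measure, analyze, report.

A single :class:`RunConfig` (YAML-serializable) carries every tunable of the
pipeline with the instrument-protocol defaults pre-filled: background OD
threshold 0.020, condensed-chromatin cutoff 0.100, 0.5 µm pixel pitch, 200
nuclei and 1000 TUNEL cells per condition, 60–100 dark-spot gray window,
5/50% area thresholds and alpha 0.05.  Runs are deterministic given the
config seed, and a JSON manifest (config echo, library versions, per-stage
counts) is written beside the outputs so any run can be reproduced.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import densitometry, image, simulate, stats, tunel

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """Pipeline failure with the stage it occurred in."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _default_tunel_conditions() -> dict[str, dict[str, Any]]:
    # control: rare, mostly weak positives; treated: frequent, larger spots —
    # the direction of a cytotoxic response without copying any measured table
    return {
        "control": {"positive_prob": 0.06, "coverage_beta": [1.2, 8.0]},
        "treated": {"positive_prob": 0.35, "coverage_beta": [1.5, 4.0]},
    }


@dataclass
class RunConfig:
    """All pipeline tunables in one place; defaults match the measurement protocol."""

    background_threshold: float = densitometry.DEFAULT_BACKGROUND_THRESHOLD
    condensed_cutoff: float = densitometry.DEFAULT_CONDENSED_CUTOFF
    pixel_pitch_um: float = image.DEFAULT_PIXEL_PITCH_UM
    min_nucleus_area_px: int = densitometry.DEFAULT_MIN_AREA_PX
    nuclei_per_condition: int = 200
    tunel_cells_per_condition: int = 1000
    tunel_gray_window: tuple[int, int] = tunel.DEFAULT_GRAY_WINDOW
    tunel_area_thresholds: tuple[float, float] = tunel.DEFAULT_AREA_THRESHOLDS
    alpha: float = stats.DEFAULT_ALPHA
    seed: int = 0
    conditions: tuple[str, ...] = ("control", "decondensed")
    tunel_conditions: dict[str, dict[str, Any]] = field(default_factory=_default_tunel_conditions)
    input_dir: str | None = None
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.background_threshold <= 0 or self.condensed_cutoff <= 0:
            raise ValueError("thresholds must be positive")
        self.tunel_gray_window = tuple(self.tunel_gray_window)  # type: ignore[assignment]
        self.tunel_area_thresholds = tuple(self.tunel_area_thresholds)  # type: ignore[assignment]
        self.conditions = tuple(self.conditions)  # type: ignore[assignment]

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["tunel_gray_window"] = list(self.tunel_gray_window)
        d["tunel_area_thresholds"] = list(self.tunel_area_thresholds)
        d["conditions"] = list(self.conditions)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _write_manifest(
    out_dir: Path, config: RunConfig, stage_counts: dict[str, int], name: str = "manifest.json"
) -> Path:
    import scipy
    import skimage

    from . import __version__

    manifest = {
        "config": config.to_dict(),
        "versions": {
            "feulgen": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "scikit-image": skimage.__version__,
            "pandas": pd.__version__,
        },
        "stage_counts": stage_counts,
    }
    path = out_dir / name
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def _measure_population(
    config: RunConfig, condition: str, cond_seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one condition and push every nucleus through the measurement path."""
    sims = simulate.generate_population(condition, config.nuclei_per_condition, cond_seed)
    meas_rows: list[densitometry.NucleusMeasurement] = []
    ids: list[str] = []
    for i, (img, _mask, _truth) in enumerate(sims):
        found = densitometry.measure_image(
            img,
            background_threshold=config.background_threshold,
            cutoff=config.condensed_cutoff,
            min_area_px=config.min_nucleus_area_px,
        )
        if not found:
            logger.warning("condition %s nucleus %d: nothing segmented", condition, i)
            continue
        # one simulated nucleus per image; keep the dominant component
        meas_rows.append(max(found, key=lambda m: m.n_pixels))
        ids.append(f"{condition}_{i:04d}")
    frame = densitometry.measurements_to_frame(meas_rows, image_ids=ids)
    frame.insert(0, "condition", condition)
    truths = simulate.truth_table([t for _, _, t in sims], ids=[f"{condition}_{i:04d}" for i in range(len(sims))])
    truths.insert(0, "condition", condition)
    return frame, truths


def _measure_input_dir(config: RunConfig) -> pd.DataFrame:
    """Measure real images laid out as <input_dir>/<condition>/*.tif|*.png."""
    root = Path(config.input_dir)  # type: ignore[arg-type]
    if not root.is_dir():
        raise PipelineError("ingest", f"input directory {root} does not exist")
    frames = []
    for cond_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        meas, ids = [], []
        for img_path in sorted(cond_dir.glob("*")):
            if img_path.suffix.lower() in (".tif", ".tiff"):
                img = image.read_absorbance_tiff(img_path, config.pixel_pitch_um)
            elif img_path.suffix.lower() == ".png":
                img = image.read_transmittance_image(img_path, pixel_pitch_um=config.pixel_pitch_um)
            else:
                continue
            for m in densitometry.measure_image(
                img,
                background_threshold=config.background_threshold,
                cutoff=config.condensed_cutoff,
                min_area_px=config.min_nucleus_area_px,
            ):
                meas.append(m)
                ids.append(img_path.stem)
        if meas:
            frame = densitometry.measurements_to_frame(meas, image_ids=ids)
            frame.insert(0, "condition", cond_dir.name)
            frames.append(frame)
    if not frames:
        raise PipelineError("ingest", f"no measurable images under {root}")
    return pd.concat(frames, ignore_index=True)


def analyze_measurements(
    measurements: pd.DataFrame,
    config: RunConfig,
    out_dir: Path,
    *,
    reference_condition: str | None = None,
) -> dict[str, Path]:
    """Group summaries, pairwise comparisons, C-class histograms, scatter plot."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    conditions = list(dict.fromkeys(measurements["condition"]))
    ref = reference_condition or conditions[0]
    variables = ["Sc_pct", "AAR", "A_T", "S_T_um2", "Ac_pct"]

    summary_rows = []
    for cond in conditions:
        sub = measurements[measurements["condition"] == cond]
        for var in variables:
            s = stats.summarize(sub[var].to_numpy())
            summary_rows.append(
                {"condition": cond, "variable": var, "n": s.n, "X": s.mean, "S": s.sd, "Md": s.median}
            )
    summaries = pd.DataFrame(summary_rows)

    comparison_rows = []
    ref_sub = measurements[measurements["condition"] == ref]
    for cond in conditions:
        if cond == ref:
            continue
        sub = measurements[measurements["condition"] == cond]
        for var in variables:
            c = stats.compare_groups(
                ref_sub[var].to_numpy(), sub[var].to_numpy(), alpha=config.alpha
            )
            comparison_rows.append(
                {
                    "group_a": ref,
                    "group_b": cond,
                    "variable": var,
                    "test": c.test,
                    "statistic": c.statistic,
                    "p": c.p_two_sided,
                    "significant": c.significant,
                }
            )
    comparisons = pd.DataFrame(comparison_rows)

    hist_rows = []
    ref_at = ref_sub["A_T"].to_numpy()
    for cond in conditions:
        sub = measurements[measurements["condition"] == cond]
        h = stats.c_class_histogram(sub["A_T"].to_numpy(), ref_at)
        hf = h.to_frame()
        hf.insert(0, "condition", cond)
        hf["anchor_2C"] = h.anchor_2C
        hist_rows.append(hf)
    histograms = pd.concat(hist_rows, ignore_index=True)

    by_group = {
        cond: [
            densitometry.NucleusMeasurement(
                a_t=r.A_T, a_c=r.A_C, ac_pct=r.Ac_pct, s_t_um2=r.S_T_um2, s_c_um2=r.S_C_um2,
                sc_pct=r.Sc_pct, aar=r.AAR, cutoff=r.cutoff,
                background_threshold=r.background_threshold, n_pixels=0, n_condensed_pixels=0,
            )
            for r in measurements[measurements["condition"] == cond].itertuples()
        ]
        for cond in conditions
    }
    _, ax = stats.scatter_diagram(by_group)
    scatter_path = out_dir / "scatter_sc_vs_aar.png"
    ax.figure.savefig(scatter_path, dpi=150)
    plt.close(ax.figure)

    paths = {
        "summaries": out_dir / "summaries.csv",
        "comparisons": out_dir / "comparisons.csv",
        "c_class_histograms": out_dir / "c_class_histograms.csv",
        "scatter": scatter_path,
    }
    _write_csv(summaries, paths["summaries"])
    _write_csv(comparisons, paths["comparisons"])
    _write_csv(histograms, paths["c_class_histograms"])
    return paths


def run_karyometry(config: RunConfig) -> dict[str, Path]:
    """Simulate (or ingest), measure and analyze a karyometry experiment.

    Writes the per-nucleus measurement CSV, group summaries, pairwise
    comparisons, C-class histograms, the Sc%-vs-AAR scatter plot and a run
    manifest into ``config.output_dir``; returns the paths keyed by stage.
    Deterministic given ``config.seed``.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage_counts: dict[str, int] = {}

    if config.input_dir is not None:
        measurements = _measure_input_dir(config)
        truth_frames = None
    else:
        rng = np.random.default_rng(config.seed)
        cond_seeds = rng.integers(0, 2**31, size=len(config.conditions))
        frames, truths = [], []
        for cond, cseed in zip(config.conditions, cond_seeds):
            try:
                frame, truth = _measure_population(config, cond, int(cseed))
            except ValueError as exc:
                raise PipelineError("simulate", str(exc)) from exc
            frames.append(frame)
            truths.append(truth)
            stage_counts[f"simulated_{cond}"] = len(truth)
            stage_counts[f"measured_{cond}"] = len(frame)
        measurements = pd.concat(frames, ignore_index=True)
        truth_frames = pd.concat(truths, ignore_index=True)

    paths: dict[str, Path] = {"measurements": out_dir / "measurements.csv"}
    _write_csv(measurements, paths["measurements"])
    if truth_frames is not None:
        paths["truth"] = out_dir / "truth.csv"
        _write_csv(truth_frames, paths["truth"])

    try:
        paths.update(analyze_measurements(measurements, config, out_dir))
    except ValueError as exc:
        raise PipelineError("stats", str(exc)) from exc
    stage_counts["nuclei_analyzed"] = len(measurements)
    paths["manifest"] = _write_manifest(out_dir, config, stage_counts, "manifest_karyometry.json")
    return paths


def run_tunel(config: RunConfig) -> dict[str, Path]:
    """Simulate TUNEL conditions, score every cell, and write the positivity tables.

    Each simulated cell goes through the full scoring path (nucleus
    segmentation, gray-window spot detection, area-rank classification).
    """
    if not config.tunel_conditions:
        raise PipelineError("tunel", "no TUNEL conditions configured")
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(config.seed + 1)  # distinct stream from karyometry
    cond_seeds = rng.integers(0, 2**31, size=len(config.tunel_conditions))
    scores: dict[str, list[tunel.TunelScore]] = {}
    stage_counts: dict[str, int] = {}
    for (cond, recipe), cseed in zip(config.tunel_conditions.items(), cond_seeds):
        try:
            cells = simulate.generate_tunel_condition(
                config.tunel_cells_per_condition,
                int(cseed),
                positive_prob=float(recipe["positive_prob"]),
                coverage_beta=tuple(recipe["coverage_beta"]),
            )
            scores[cond] = [
                tunel.score_tunel_image(
                    img,
                    gray_window=config.tunel_gray_window,
                    thresholds=config.tunel_area_thresholds,
                )
                for img, _rel, _rank in cells
            ]
        except (KeyError, ValueError) as exc:
            raise PipelineError("tunel", f"condition {cond!r}: {exc}") from exc
        stage_counts[f"tunel_{cond}"] = len(scores[cond])

    paths = {
        "tunel_cells": out_dir / "tunel_cells.csv",
        "tunel_table": out_dir / "tunel_positivity.csv",
    }
    _write_csv(tunel.scores_to_frame(scores), paths["tunel_cells"])
    _write_csv(tunel.positivity_table(scores), paths["tunel_table"])
    paths["manifest"] = _write_manifest(out_dir, config, stage_counts, "manifest_tunel.json")
    return paths
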