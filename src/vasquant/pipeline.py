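"""Batch orchestration: config, per-image pipeline, CSV aggregation.

A batch run applies the full measurement chain to each input image —
load, optional projection, denoise, binarize, clean, skeleton metrics,
optional pericyte coverage, heatmap — and appends one row per image to a
results table.  Failing images are logged and skipped; the run fails only
if every image fails.  The effective configuration (all defaults
resolved) is written verbatim into the output directory so a run can be
reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from vasquant.errors import ConfigurationError
from vasquant.heatmap import compute_heatmap, render_heatmap
from vasquant.io import load_image, load_stack, max_project, save_mask
from vasquant.metrics import compute_metrics
from vasquant.pericytes import pericyte_coverage
from vasquant.preprocess import segment
from vasquant.skeleton import skeletonize

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Validated parameters of one batch run.

    Every CLI flag mirrors a config key; CLI values override the file.
    ``pixel_size_um`` has no default on purpose: the calibration must be
    an explicit decision of the analyst.
    """

    pixel_size_um: float
    vessel_channel: int = 0
    pericyte_channel: int | None = None
    project_stack: bool = False
    denoise_method: str = "median"
    denoise_radius_px: float = 1
    threshold_method: str = "otsu"
    threshold_value: float | None = None
    min_object_area_um2: float = 25.0
    fill_holes_below_um2: float = 0.0
    invert: bool = False
    nnd_mode: str = "centroid"
    tiles_per_row: int = 10
    restrict_to_vessel_um: float = 0.0
    heatmap_vmax: float | None = None
    output_dir: str = "vasquant_out"
    seed: int = 0

    def validate(self) -> None:
        if not self.pixel_size_um > 0:
            raise ConfigurationError("pixel_size_um must be positive")
        if self.vessel_channel < 0:
            raise ConfigurationError("vessel_channel must be >= 0")
        if self.pericyte_channel is not None and self.pericyte_channel < 0:
            raise ConfigurationError("pericyte_channel must be >= 0")
        if self.denoise_method not in ("median", "gaussian"):
            raise ConfigurationError(f"unknown denoise_method {self.denoise_method!r}")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ConfigurationError(f"unknown threshold_method {self.threshold_method!r}")
        if self.threshold_method == "fixed" and self.threshold_value is None:
            raise ConfigurationError("threshold_method 'fixed' requires threshold_value")
        if self.nnd_mode not in ("centroid", "skeleton"):
            raise ConfigurationError(f"unknown nnd_mode {self.nnd_mode!r}")
        if self.tiles_per_row < 1:
            raise ConfigurationError("tiles_per_row must be >= 1")
        if self.min_object_area_um2 < 0 or self.fill_holes_below_um2 < 0:
            raise ConfigurationError("area thresholds must be non-negative")
        if self.restrict_to_vessel_um < 0:
            raise ConfigurationError("restrict_to_vessel_um must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "pixel_size_um" not in data:
            raise ConfigurationError("pixel_size_um is required")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _segment_from_config(img, cfg: AnalysisConfig):
    return segment(
        img,
        denoise_method=cfg.denoise_method,
        denoise_radius_px=cfg.denoise_radius_px,
        threshold_method=cfg.threshold_method,
        threshold_value=cfg.threshold_value,
        min_object_area_um2=cfg.min_object_area_um2,
        fill_holes_below_um2=cfg.fill_holes_below_um2,
        invert=cfg.invert,
    )


def analyze_image(path: str | Path, cfg: AnalysisConfig, outdir: Path | None = None) -> dict:
    """Measure one image; returns the per-image CSV row as a dict.

    When ``outdir`` is given, QC artifacts (mask and skeleton TIFFs,
    heatmap PNG + tile CSV) are written alongside.
    """
    path = Path(path)
    if cfg.project_stack and path.suffix.lower() in (".tif", ".tiff"):
        stack = load_stack(path, cfg.pixel_size_um, cfg.vessel_channel)
        img = max_project(stack)
    else:
        img = load_image(path, cfg.pixel_size_um, cfg.vessel_channel)
    mask = _segment_from_config(img, cfg)
    metrics = compute_metrics(mask, nnd_mode=cfg.nnd_mode)
    row: dict = {"image": path.name}
    row.update(
        {
            "field_area_mm2": metrics.field_area_mm2,
            "area_fraction": metrics.area_fraction,
            "length_density_mm_per_mm2": metrics.length_density_mm_per_mm2,
            "branch_density_per_mm2": metrics.branch_density_per_mm2,
            "mean_nnd_um": metrics.mean_nnd_um,
            "nnd_sd_um": metrics.nnd_sd_um,
            "nnd_mode": metrics.nnd_mode,
            "n_objects": metrics.n_objects,
            "n_segments": metrics.n_segments,
            "mean_segment_um": metrics.mean_segment_um,
            "max_segment_um": metrics.max_segment_um,
            "n_branch_points": metrics.n_branch_points,
        }
    )
    if cfg.pericyte_channel is not None:
        peri_img = load_image(path, cfg.pixel_size_um, cfg.pericyte_channel)
        peri_mask = _segment_from_config(peri_img, cfg)
        cov = pericyte_coverage(mask, peri_mask, cfg.restrict_to_vessel_um)
        row.update(
            {
                "pericyte_af": cov.pericyte_af,
                "coverage_ratio": cov.coverage_ratio,
                "restricted": cov.restricted,
                "dilation_um": cov.dilation_um,
            }
        )
    if outdir is not None:
        stem = path.stem
        save_mask(mask, outdir / f"{stem}_mask.tif")
        save_mask(skeletonize(mask), outdir / f"{stem}_skeleton.tif")
        grid = compute_heatmap(mask, cfg.tiles_per_row)
        render_heatmap(grid, outdir / f"{stem}_heatmap.png", vmax=cfg.heatmap_vmax)
    return row


def run_batch(cfg: AnalysisConfig, inputs: list[str | Path]) -> pd.DataFrame:
    """Analyze a batch of images and write results + artifacts.

    Writes ``results.csv``, per-image QC artifacts, ``run.log`` and the
    effective config into ``cfg.output_dir``.  Raises if the input list
    is empty or every image fails.
    """
    if not inputs:
        raise ValueError("run_batch requires at least one input image")
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("vasquant")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        from vasquant import __version__

        logger.info("vasquant %s", __version__)
        logger.info("effective config: %s", json.dumps(cfg.to_dict()))
        with open(outdir / "effective_config.yaml", "w") as fh:
            yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)

        rows = []
        for p in inputs:
            try:
                rows.append(analyze_image(p, cfg, outdir))
                logger.info("analyzed %s", p)
            except Exception as exc:  # noqa: BLE001 — per-image isolation
                logger.error("failed %s: %s", p, exc)
        if not rows:
            raise RuntimeError("all input images failed to analyze")
        df = pd.DataFrame(rows)
        df.to_csv(outdir / "results.csv", index=False)
        return df
    finally:
        root.removeHandler(handler)
        handler.close()


def summarize_groups(results_csv: str | Path, group_column: str) -> pd.DataFrame:
    """Per-group n, mean and SD of every numeric metric column.

    Descriptive only — inferential statistics are the study's business,
    not the tool's.
    """
    df = pd.read_csv(results_csv)
    if group_column not in df.columns:
        raise ValueError(f"column {group_column!r} not in {results_csv}")
    numeric = df.select_dtypes("number").columns
    agg = df.groupby(group_column)[list(numeric)].agg(["count", "mean", "std"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    return agg.reset_index()
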