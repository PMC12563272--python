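"""End-to-end orchestration: simulate → detect → segment → count → curve.

``run_pipeline`` executes any contiguous span of the stage chain from a
validated :class:`RunConfig`, writing every artifact (images, ROIs, masks,
coverage records, growth curves) plus a manifest capturing parameters and
seeds, so a re-run with the same config reproduces identical CSVs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from . import io as wio
from .counting import CoverageRecord, count_flat, count_u_bottom, make_cell_model
from .geometry import (
    DEVICE_PRESETS,
    CircleROI,
    DeviceSpec,
    WellImage,
    detect_well_roi,
)
from .growth import aggregate
from .segmentation import SegMask, SegModel, predict, segment_baseline
from .synth import (
    ArtifactSpec,
    CellRenderSpec,
    GrowthModel,
    render_well,
    simulate_seeding,
    simulate_timeseries,
)

__all__ = ["RunConfig", "ConfigError", "run_pipeline", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "detect", "segment", "count", "curve")


class ConfigError(ValueError):
    """Invalid run configuration; the message names the offending field."""


@dataclass
class RunConfig:
    """Validated parameters for a pipeline run."""

    out_dir: str
    device: str = "ibidi"
    #: explicit well geometry overriding the preset's WellSpec, as a dict of
    #: WellSpec fields (shape, top_radius_um, ...)
    well: dict | None = None
    stages: Sequence[str] = STAGES
    seed: int = 0
    # simulate
    n_wells_per_channel: int = 7
    n_channels: int = 1
    mean_seed_cells: float = 60.0
    doubling_time_h: float = 24.0
    noise_cv: float = 0.05
    drying_onset_h: float | None = None
    interval_h: float = 3.0
    horizon_h: float = 24.0
    bubble_probability: float = 0.0
    # segment
    backend: str = "baseline"
    model_path: str | None = None
    # detect
    roi_tolerance_frac: float = 0.2
    cell_diameter_um: float = 15.0

    def validate(self) -> None:
        if self.device not in DEVICE_PRESETS:
            raise ConfigError(
                f"device: unknown preset {self.device!r}; "
                f"choose from {sorted(DEVICE_PRESETS)}"
            )
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ConfigError(f"stages: unknown stage(s) {bad}; valid: {STAGES}")
        idx = [STAGES.index(s) for s in self.stages]
        if idx != sorted(idx) or idx != list(range(idx[0], idx[-1] + 1)):
            raise ConfigError("stages: must be a contiguous, ordered span of "
                              f"{STAGES}")
        if self.n_wells_per_channel < 1:
            raise ConfigError("n_wells_per_channel: must be >= 1")
        if self.n_channels < 1:
            raise ConfigError("n_channels: must be >= 1")
        if self.backend not in ("baseline", "trained"):
            raise ConfigError(f"backend: unknown {self.backend!r}")
        if self.backend == "trained" and not self.model_path:
            raise ConfigError("model_path: required for the trained backend")
        if self.interval_h <= 0 or self.horizon_h < self.interval_h:
            raise ConfigError("interval_h/horizon_h: need 0 < interval <= horizon")
        if self.well is not None:
            try:
                self.well_spec()
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"well: {exc}") from exc

    def well_spec(self):
        from .geometry import WellSpec

        if self.well is not None:
            return WellSpec(**self.well)
        return DEVICE_PRESETS[self.device].well_spec


def _mask_cluster_areas(mask: SegMask, pixel_area_um2: float) -> list[float]:
    labels, n = ndimage.label(mask.pixels)
    if n == 0:
        return []
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    return [float(s) * pixel_area_um2 for s in np.atleast_1d(sizes)]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stage span; returns paths of written artifacts."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    device: DeviceSpec = DEVICE_PRESETS[config.device]
    spec = config.well_spec()
    rng = np.random.default_rng(config.seed)
    artifacts: dict = {}

    images_dir = out / "images"
    masks_dir = out / "masks"

    if "simulate" in config.stages:
        images_dir.mkdir(exist_ok=True)
        cells = CellRenderSpec(
            diameter_um=config.cell_diameter_um,
            placement=(
                "center_clustered" if spec.shape == "u_bottom" else "uniform_in_well"
            ),
        )
        art = ArtifactSpec(bubble_probability=config.bubble_probability)
        truth_rows = []
        for ch in range(1, config.n_channels + 1):
            channel_id = f"ch{ch}"
            seeds0 = simulate_seeding(
                "by_channel",
                config.mean_seed_cells,
                config.n_wells_per_channel,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            for w, n0 in enumerate(seeds0, start=1):
                well_id = f"w{w:02d}"
                series = simulate_timeseries(
                    GrowthModel(
                        n0_cells=n0,
                        doubling_time_h=config.doubling_time_h,
                        drying_onset_h=config.drying_onset_h,
                        noise_cv=config.noise_cv,
                        seed=int(rng.integers(0, 2**31 - 1)),
                    ),
                    config.interval_h,
                    config.horizon_h,
                )
                for t, n_true in series:
                    img, truth = render_well(
                        spec,
                        cells,
                        int(round(n_true)),
                        art,
                        seed=int(rng.integers(0, 2**31 - 1)),
                        well_id=well_id,
                        channel_id=channel_id,
                        time_h=t,
                    )
                    fname = wio.image_filename(channel_id, well_id, t)
                    wio.write_image(img, images_dir / fname)
                    truth_rows.append(
                        {
                            "well_id": well_id,
                            "channel_id": channel_id,
                            "time_h": t,
                            "n_cells": truth.n_cells,
                            "covered_area_um2": round(truth.covered_area_um2, 2),
                        }
                    )
        import pandas as pd

        pd.DataFrame(truth_rows).to_csv(out / "ground_truth.csv", index=False)
        artifacts["images"] = str(images_dir)
        artifacts["ground_truth"] = str(out / "ground_truth.csv")

    image_paths = sorted(images_dir.glob("*.tif")) + sorted(images_dir.glob("*.png"))

    rois: dict[str, CircleROI] = {}
    if "detect" in config.stages:
        for p in image_paths:
            img = wio.read_image(p, spec.pixel_scale_um_per_px)
            key = f"{img.channel_id}_{img.well_id}"
            if key in rois:
                continue  # the well does not move between frames
            rois[key] = detect_well_roi(
                img, spec.floor_radius_um, config.roi_tolerance_frac
            )
        wio.write_rois_csv(rois, out / "rois.csv")
        artifacts["rois"] = str(out / "rois.csv")
    elif (out / "rois.csv").exists():
        rois = wio.read_rois_csv(out / "rois.csv")

    if "segment" in config.stages:
        masks_dir.mkdir(exist_ok=True)
        model: SegModel | None = None
        if config.backend == "trained":
            model = wio.load_model(config.model_path)  # type: ignore[arg-type]
        for p in image_paths:
            img = wio.read_image(p, spec.pixel_scale_um_per_px)
            roi = rois[f"{img.channel_id}_{img.well_id}"]
            mask = (
                predict(model, img, roi) if model else segment_baseline(img, roi)
            )
            wio.write_mask(mask, masks_dir / (p.stem + ".png"))
        artifacts["masks"] = str(masks_dir)

    if "count" in config.stages:
        cell = make_cell_model(config.cell_diameter_um)
        pixel_area = spec.pixel_scale_um_per_px**2
        records: list[CoverageRecord] = []
        for p in sorted(masks_dir.glob("*.png")):
            channel_id, well_id, time_h = wio.parse_image_filename(
                p.stem + ".tif"
            )
            mask = wio.read_mask(p)
            areas = _mask_cluster_areas(mask, pixel_area)
            total = float(sum(areas))
            if spec.shape == "flat":
                n_est = count_flat(total, cell)
            else:
                n_est = count_u_bottom(areas, spec, cell).n_cells_est
            records.append(
                CoverageRecord(
                    well_id=well_id,
                    channel_id=channel_id,
                    time_h=time_h,
                    covered_area_um2=total,
                    n_cells_est=n_est,
                )
            )
        wio.write_records_csv(records, out / "coverage.csv")
        artifacts["coverage"] = str(out / "coverage.csv")

    if "curve" in config.stages:
        records = wio.read_records_csv(out / "coverage.csv")
        curve = aggregate(records)
        wio.write_curve_csv(curve, out / "growth_curve.csv")
        artifacts["growth_curve"] = str(out / "growth_curve.csv")

    manifest = {
        "config": {k: getattr(config, k) for k in config.__dataclass_fields__},
        "stages_run": list(config.stages),
        "device": device.name,
    }
    manifest["config"]["stages"] = list(config.stages)
    wio.write_manifest(manifest, out / "manifest.yaml")
    artifacts["manifest"] = str(out / "manifest.yaml")
    return artifacts
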