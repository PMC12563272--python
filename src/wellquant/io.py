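"""Readers/writers shared by all stages: images, masks, CSVs, manifests.

Conventions: comma-separated UTF-8 CSVs with "." decimals and a header
row; units embedded in column names (hours, µm², µL). Images are
single-channel TIFF or PNG (8- or 16-bit); masks are PNG with 0/255.
Image filenames follow ``{channel}_{well}_{time}h.tif`` (or ``.png``).
"""

from __future__ import annotations

import json
import pickle
import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image

from .counting import CoverageRecord
from .geometry import (
    DEFAULT_PIXEL_SCALE_UM_PER_PX,
    CircleROI,
    WellImage,
)
from .growth import GrowthCurvePoint
from .segmentation import SegMask, SegModel

__all__ = [
    "FILENAME_RE",
    "parse_image_filename",
    "image_filename",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "write_rois_csv",
    "read_rois_csv",
    "write_records_csv",
    "read_records_csv",
    "write_curve_csv",
    "write_manifest",
    "save_model",
    "load_model",
]

#: ``{channel}_{well}_{time_h}h.{tif|tiff|png}`` — e.g. ``ch1_w03_24h.tif``.
FILENAME_RE = re.compile(
    r"^(?P<channel>[^_]+)_(?P<well>[^_]+)_(?P<time>\d+(?:\.\d+)?)h\.(?:tiff?|png)$"
)


def parse_image_filename(name: str) -> tuple[str, str, float]:
    """Return (channel_id, well_id, time_h) from a conventional filename."""
    m = FILENAME_RE.match(name)
    if m is None:
        raise ValueError(
            f"filename {name!r} does not match '{{channel}}_{{well}}_{{time}}h.tif'"
        )
    return m["channel"], m["well"], float(m["time"])


def image_filename(channel_id: str, well_id: str, time_h: float, ext: str = "tif") -> str:
    t = f"{time_h:g}"
    return f"{channel_id}_{well_id}_{t}h.{ext}"


def read_image(
    path: str | Path,
    pixel_scale_um_per_px: float = DEFAULT_PIXEL_SCALE_UM_PER_PX,
) -> WellImage:
    """Load a grayscale TIFF/PNG as a WellImage, metadata from the filename."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim == 3:  # tolerate RGB(A) by taking the first plane
        arr = arr[..., 0]
    try:
        channel, well, time_h = parse_image_filename(path.name)
    except ValueError:
        channel, well, time_h = "", path.stem, 0.0
    return WellImage(
        pixels=arr,
        pixel_scale_um_per_px=pixel_scale_um_per_px,
        well_id=well,
        channel_id=channel,
        time_h=time_h,
    )


def write_image(image: WellImage, path: str | Path) -> None:
    path = Path(path)
    arr = image.pixels
    if arr.dtype not in (np.uint8, np.uint16):
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)


def read_mask(path: str | Path) -> SegMask:
    arr = np.asarray(Image.open(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return SegMask(arr > 127)


def write_mask(mask: SegMask, path: str | Path) -> None:
    Image.fromarray(mask.pixels.astype(np.uint8) * 255).save(Path(path))


def write_rois_csv(
    rois: dict[str, CircleROI], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "well_id": wid,
                "center_x_px": r.center_x_px,
                "center_y_px": r.center_y_px,
                "radius_px": r.radius_px,
            }
            for wid, r in rois.items()
        ]
    ).to_csv(path, index=False)


def read_rois_csv(path: str | Path) -> dict[str, CircleROI]:
    df = pd.read_csv(path)
    return {
        str(row.well_id): CircleROI(
            center_x_px=row.center_x_px,
            center_y_px=row.center_y_px,
            radius_px=row.radius_px,
        )
        for row in df.itertuples()
    }


def write_records_csv(records: Iterable[CoverageRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "well_id": r.well_id,
                "channel_id": r.channel_id,
                "time_h": r.time_h,
                "covered_area_um2": round(r.covered_area_um2, 2),
                "n_cells_est": round(r.n_cells_est, 2),
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def read_records_csv(path: str | Path) -> list[CoverageRecord]:
    df = pd.read_csv(path)
    return [
        CoverageRecord(
            well_id=str(row.well_id),
            channel_id=str(row.channel_id),
            time_h=float(row.time_h),
            covered_area_um2=float(row.covered_area_um2),
            n_cells_est=float(row.n_cells_est),
        )
        for row in df.itertuples()
    ]


def write_curve_csv(curve: Sequence[GrowthCurvePoint], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "channel_id": p.channel_id,
                "time_h": p.time_h,
                "mean_count": round(p.mean_count, 2),
                "sem_count": round(p.sem_count, 4),
                "n_wells": p.n_wells,
            }
            for p in curve
        ]
    ).to_csv(path, index=False)


def write_manifest(manifest: dict, path: str | Path) -> None:
    """Write a run manifest (parameters and every seed) as YAML or JSON."""
    path = Path(path)
    text = (
        json.dumps(manifest, indent=2, sort_keys=True)
        if path.suffix == ".json"
        else yaml.safe_dump(manifest, sort_keys=True)
    )
    path.write_text(text)


def save_model(model: SegModel, path: str | Path) -> None:
    """Persist a model checkpoint plus a sidecar JSON manifest."""
    path = Path(path)
    with open(path, "wb") as fh:
        pickle.dump(model, fh)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps({"backend": model.backend, **model.training_manifest}, indent=2)
    )


def load_model(path: str | Path) -> SegModel:
    with open(path, "rb") as fh:
        model = pickle.load(fh)
    if not isinstance(model, SegModel):
        raise TypeError(f"{path} does not contain a SegModel")
    return model
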