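"""Well and device geometry, circular ROI detection, and exterior masking.

A lab-on-chip (LOC) culture plate is an array of microwells imaged one well
per frame in brightfield. Every downstream stage (segmentation, counting)
operates inside a circular region of interest (ROI) that isolates the well
from the surrounding chip material, so this module owns the geometry types
and the ROI detection/masking primitives.

Two well shapes are supported:

* ``flat``      — cylindrical well with a flat bottom of known diameter
                  (e.g. the commercial ibidi device, bottom Ø 800 µm);
* ``u_bottom``  — the lower half of a prolate spheroid with equatorial
                  (top) radius ``R`` and polar depth ``c`` (e.g. the custom
                  PDMS device, R = 750 µm, c = 248 µm), which makes settling
                  suspension cells cluster at the well centre.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from skimage import feature, transform

__all__ = [
    "WellSpec",
    "DeviceSpec",
    "CircleROI",
    "WellImage",
    "WellNotFoundError",
    "DEVICE_PRESETS",
    "DEFAULT_PIXEL_SCALE_UM_PER_PX",
    "detect_well_roi",
    "mask_outside",
    "roi_area_um2",
]

#: Fallback pixel size for a typical 4x widefield objective, in µm per pixel.
#: Used only when image metadata carries no scale; always overridable.
DEFAULT_PIXEL_SCALE_UM_PER_PX = 1.6


@dataclass(frozen=True)
class WellSpec:
    """Physical geometry of a single well plus the imaging pixel scale.

    Parameters
    ----------
    shape:
        ``"flat"`` or ``"u_bottom"``.
    top_radius_um:
        Radius ``R`` of the well opening, µm.
    depth_um:
        Polar depth ``c`` of the spheroidal cavity, µm. Required for
        ``u_bottom`` wells.
    bottom_diameter_um:
        Diameter of the flat floor, µm. Required for ``flat`` wells.
    pixel_scale_um_per_px:
        Image calibration, µm per pixel.
    """

    shape: Literal["flat", "u_bottom"]
    top_radius_um: float
    depth_um: float | None = None
    bottom_diameter_um: float | None = None
    pixel_scale_um_per_px: float = DEFAULT_PIXEL_SCALE_UM_PER_PX

    def __post_init__(self) -> None:
        if self.shape not in ("flat", "u_bottom"):
            raise ValueError(f"unknown well shape {self.shape!r}")
        if self.top_radius_um <= 0:
            raise ValueError("top_radius_um must be > 0")
        if self.pixel_scale_um_per_px <= 0:
            raise ValueError("pixel_scale_um_per_px must be > 0")
        if self.shape == "u_bottom":
            if self.depth_um is None or self.depth_um <= 0:
                raise ValueError("u_bottom wells require depth_um > 0")
        if self.shape == "flat":
            if self.bottom_diameter_um is None or self.bottom_diameter_um <= 0:
                raise ValueError("flat wells require bottom_diameter_um > 0")

    @property
    def floor_radius_um(self) -> float:
        """Radius of the region cells can occupy in a top-down view, µm.

        For flat wells this is the bottom radius; for U-bottom wells the
        full top radius (cells are visible anywhere over the cavity).
        """
        if self.shape == "flat":
            assert self.bottom_diameter_um is not None
            return self.bottom_diameter_um / 2.0
        return self.top_radius_um

    @property
    def floor_radius_px(self) -> float:
        return self.floor_radius_um / self.pixel_scale_um_per_px

    def with_pixel_scale(self, scale_um_per_px: float) -> "WellSpec":
        return replace(self, pixel_scale_um_per_px=scale_um_per_px)


@dataclass(frozen=True)
class DeviceSpec:
    """A whole LOC device: how many wells, channels, and channel volume."""

    name: str
    wells: int
    channels: int
    channel_volume_ul: float
    well_spec: WellSpec

    def __post_init__(self) -> None:
        if self.wells < 1:
            raise ValueError("wells must be >= 1")
        if self.channels < 1:
            raise ValueError("channels must be >= 1")
        if self.channel_volume_ul <= 0:
            raise ValueError("channel_volume_ul must be > 0")


#: Device presets for the two platforms the package models.
#: "ibidi": 3 channels x 7 flat-bottom wells (Ø 800 µm), 45 µL per channel.
#: "pdms": ~150 U-bottom wells (R = 750 µm, c = 248 µm), one 200 µL cistern.
DEVICE_PRESETS: dict[str, DeviceSpec] = {
    "ibidi": DeviceSpec(
        name="ibidi",
        wells=21,
        channels=3,
        channel_volume_ul=45.0,
        well_spec=WellSpec(
            shape="flat",
            top_radius_um=400.0,
            bottom_diameter_um=800.0,
        ),
    ),
    "pdms": DeviceSpec(
        name="pdms",
        wells=150,
        channels=1,
        channel_volume_ul=200.0,
        well_spec=WellSpec(
            shape="u_bottom",
            top_radius_um=750.0,
            depth_um=248.0,
        ),
    ),
}


@dataclass(frozen=True)
class CircleROI:
    """A circular region of interest in pixel coordinates.

    Coordinates are 0-based with ``x`` = column and ``y`` = row; a pixel
    belongs to the ROI iff its *centre* lies within the circle.
    """

    center_x_px: float
    center_y_px: float
    radius_px: float

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise ValueError("radius_px must be > 0")

    def contains(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean membership grid for an image of the given (rows, cols)."""
        yy, xx = np.ogrid[: shape[0], : shape[1]]
        d2 = (xx - self.center_x_px) ** 2 + (yy - self.center_y_px) ** 2
        return d2 <= self.radius_px**2


@dataclass
class WellImage:
    """A single-well grayscale frame with acquisition metadata."""

    pixels: np.ndarray
    pixel_scale_um_per_px: float = DEFAULT_PIXEL_SCALE_UM_PER_PX
    well_id: str = ""
    channel_id: str = ""
    time_h: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D grid")
        if not np.all(np.isfinite(self.pixels.astype(float))):
            raise ValueError("pixel intensities must be finite")
        if self.pixel_scale_um_per_px <= 0:
            raise ValueError("pixel_scale_um_per_px must be > 0")
        if self.time_h < 0:
            raise ValueError("time_h must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


class WellNotFoundError(RuntimeError):
    """Raised when circle detection finds no well above the score threshold."""

    def __init__(self, best_score: float, threshold: float):
        self.best_score = best_score
        self.threshold = threshold
        super().__init__(
            f"well not found: best Hough score {best_score:.3f} "
            f"below threshold {threshold:.3f}"
        )


def detect_well_roi(
    image: WellImage,
    expected_radius_um: float,
    tolerance_frac: float = 0.2,
    *,
    score_threshold: float = 0.25,
) -> CircleROI:
    """Locate the circular well outline in a brightfield frame.

    Canny edges are voted into a circular Hough accumulator over radii
    within ``±tolerance_frac`` of the expected radius; the best-scoring
    circle is returned. Ties are broken by smallest ``(y, x, radius)`` so
    detection is deterministic for a fixed image.

    Raises
    ------
    WellNotFoundError
        If no accumulator peak reaches ``score_threshold`` (e.g. a uniform
        frame with no edges).
    """
    if not 0 < tolerance_frac < 1:
        raise ValueError("tolerance_frac must be in (0, 1)")
    expected_radius_px = expected_radius_um / image.pixel_scale_um_per_px
    if expected_radius_px < 8:
        raise ValueError(
            f"expected radius {expected_radius_px:.1f} px is below the "
            "8 px minimum for reliable circle detection"
        )

    img = image.pixels.astype(float)
    lo, hi = img.min(), img.max()
    if hi > lo:
        img = (img - lo) / (hi - lo)
    edges = feature.canny(img, sigma=2.0)
    if not edges.any():
        raise WellNotFoundError(0.0, score_threshold)

    r_lo = max(8, int(math.floor(expected_radius_px * (1 - tolerance_frac))))
    r_hi = int(math.ceil(expected_radius_px * (1 + tolerance_frac)))
    radii = np.arange(r_lo, r_hi + 1)
    accum = transform.hough_circle(edges, radii)

    # Normalized peak score: fraction of the circle perimeter supported by
    # edge votes (hough_circle already normalizes per radius).
    best_score = float(accum.max())
    if best_score < score_threshold:
        raise WellNotFoundError(best_score, score_threshold)

    # Deterministic tie-break: among all maxima choose smallest (y, x, r).
    ridx, yidx, xidx = np.nonzero(accum == accum.max())
    order = np.lexsort((radii[ridx], xidx, yidx))
    k = order[0]
    return CircleROI(
        center_x_px=float(xidx[k]),
        center_y_px=float(yidx[k]),
        radius_px=float(radii[ridx[k]]),
    )


def mask_outside(
    image: WellImage,
    roi: CircleROI,
    fill_value: float | None = None,
) -> WellImage:
    """Replace everything outside the ROI circle with a flat fill value.

    A pixel is kept iff its centre is within ``roi.radius_px`` of the ROI
    centre. ``fill_value`` defaults to the image's 5th-percentile intensity,
    mimicking the dark chip material around a well. Idempotent.
    """
    if fill_value is None:
        fill_value = float(np.percentile(image.pixels, 5))
    inside = roi.contains(image.shape)
    out = image.pixels.copy()
    out[~inside] = np.asarray(fill_value, dtype=out.dtype)
    return WellImage(
        pixels=out,
        pixel_scale_um_per_px=image.pixel_scale_um_per_px,
        well_id=image.well_id,
        channel_id=image.channel_id,
        time_h=image.time_h,
    )


def roi_area_um2(roi: CircleROI, scale_um_per_px: float) -> float:
    """Physical area of the ROI disk, π·(radius_px·scale)², in µm²."""
    if scale_um_per_px <= 0:
        raise ValueError("scale must be > 0")
    return math.pi * (roi.radius_px * scale_um_per_px) ** 2
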