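"""Synthetic brightfield well images, ground truth, and growth series.

No public microwell image set accompanies the analysis this package
implements, so this generator is the test bed for every stage. It emulates
the statistical structure the pipeline assumes rather than the physics of
the optics:

* a bright circular well interior on a darker chip background;
* Jurkat-like cells (~15 µm across) drawn as a bright centre disk with a
  dark rim — the contrast structure a texture segmenter keys on in
  brightfield;
* central clustering of settled cells in U-bottom wells (truncated 2-D
  Gaussian, sigma = 0.25 R) versus uniform scatter on flat floors;
* occasional bubble artifacts: large, very bright disks with a dark shadow
  ring, which are *not* part of the cell ground truth;
* exponential growth with multiplicative log-normal noise and an optional
  drying collapse (one-time drop to a floor fraction, no recovery);
* seeding dispersion differing between channel-based and per-well seeding.

All randomness flows from explicit integer seeds; fixed seed implies
bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .geometry import CircleROI, WellImage, WellSpec

__all__ = [
    "CellRenderSpec",
    "ArtifactSpec",
    "GrowthModel",
    "GroundTruth",
    "WellOverfullError",
    "render_well",
    "simulate_seeding",
    "simulate_timeseries",
    "benchmark_dataset",
]

# Intensity levels on the unit scale (converted to uint8 on output).
_BG_OUTSIDE = 0.25   # chip material around the well
_BG_WELL = 0.55      # empty well interior (mid-gray)
_CELL_CORE = 0.85    # bright cell centre
_CELL_RIM = 0.20     # dark halo rim
_BUBBLE_CORE = 0.98  # near-white bubble interior
_BUBBLE_RIM = 0.05   # bubble shadow ring
_NOISE_SD = 0.02     # additive Gaussian sensor noise

#: Seeding dispersion (coefficient of variation) by protocol. Channel-based
#: seeding distributes a mixed suspension evenly; per-well pipetting is much
#: noisier. These are calibration knobs, not measured values.
SEEDING_CV = {"by_channel": 0.05, "by_well": 0.25}


@dataclass(frozen=True)
class CellRenderSpec:
    """How to draw cells: size, appearance, and placement statistics."""

    diameter_um: float = 15.0
    intensity_profile: Literal["bright_ring_dark_center", "flat_disk"] = (
        "bright_ring_dark_center"
    )
    placement: Literal["uniform_in_well", "center_clustered"] = "uniform_in_well"
    overlap_allowed: bool = False

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ValueError("diameter_um must be > 0")


@dataclass(frozen=True)
class ArtifactSpec:
    """Bubble artifact statistics; defaults produce artifact-free frames."""

    bubble_probability: float = 0.0
    bubble_radius_um: tuple[float, float] = (40.0, 90.0)
    bubble_shadow: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.bubble_probability <= 1:
            raise ValueError("bubble_probability must be in [0, 1]")


@dataclass(frozen=True)
class GrowthModel:
    """Exponential growth with noise and an optional drying collapse."""

    n0_cells: float
    doubling_time_h: float
    drying_onset_h: float | None = None
    drying_floor_frac: float = 0.2
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n0_cells < 0:
            raise ValueError("n0_cells must be >= 0")
        if self.doubling_time_h <= 0:
            raise ValueError("doubling_time_h must be > 0")
        if not 0 <= self.drying_floor_frac <= 1:
            raise ValueError("drying_floor_frac must be in [0, 1]")


@dataclass
class GroundTruth:
    """Per-frame truth: binary cell mask, count, covered area, and true ROI."""

    mask: np.ndarray
    n_cells: int
    covered_area_um2: float
    roi: CircleROI


class WellOverfullError(RuntimeError):
    """Non-overlapping placement failed: too many cells for the well."""


def _place_centers(
    rng: np.random.Generator,
    n: int,
    well_radius_px: float,
    cell_radius_px: float,
    placement: str,
    overlap_allowed: bool,
    max_attempts_per_cell: int = 200,
) -> np.ndarray:
    """Draw n cell centres (x, y offsets from well centre) in pixels."""
    r_max = well_radius_px - cell_radius_px
    if r_max <= 0:
        raise WellOverfullError("cell larger than well")
    sigma = 0.25 * well_radius_px
    centers: list[tuple[float, float]] = []
    min_d2 = (2 * cell_radius_px) ** 2
    for _ in range(n):
        for attempt in range(max_attempts_per_cell):
            if placement == "center_clustered":
                # truncated 2-D Gaussian: redraw until inside the disk
                x, y = rng.normal(0.0, sigma, size=2)
                if x * x + y * y > r_max * r_max:
                    continue
            else:
                rad = r_max * math.sqrt(rng.uniform())
                theta = rng.uniform(0, 2 * math.pi)
                x, y = rad * math.cos(theta), rad * math.sin(theta)
            if overlap_allowed or all(
                (x - cx) ** 2 + (y - cy) ** 2 >= min_d2 for cx, cy in centers
            ):
                centers.append((x, y))
                break
        else:
            raise WellOverfullError(
                f"could not place cell {len(centers) + 1}/{n} after "
                f"{max_attempts_per_cell} attempts"
            )
    return np.asarray(centers, dtype=float).reshape(n, 2)


def _disk_membership(
    shape: tuple[int, int], cx: float, cy: float, radius: float
) -> np.ndarray:
    """Pixel-centre-in-circle membership, on a local bounding box for speed."""
    y0 = max(0, int(math.floor(cy - radius - 1)))
    y1 = min(shape[0], int(math.ceil(cy + radius + 2)))
    x0 = max(0, int(math.floor(cx - radius - 1)))
    x1 = min(shape[1], int(math.ceil(cx + radius + 2)))
    out = np.zeros(shape, dtype=bool)
    if y1 <= y0 or x1 <= x0:
        return out
    yy, xx = np.ogrid[y0:y1, x0:x1]
    out[y0:y1, x0:x1] = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
    return out


def render_well(
    spec: WellSpec,
    cells: CellRenderSpec,
    n_cells: int,
    artifacts: ArtifactSpec | None = None,
    seed: int = 0,
    *,
    well_id: str = "",
    channel_id: str = "",
    time_h: float = 0.0,
    margin_frac: float = 0.15,
) -> tuple[WellImage, GroundTruth]:
    """Render one synthetic well frame plus its ground truth.

    The frame is sized to the well with a ``margin_frac`` border of chip
    background. The ground-truth mask marks exactly the rendered cell
    pixels; bubbles are drawn into the image but never into the mask.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    artifacts = artifacts or ArtifactSpec()
    rng = np.random.default_rng(seed)

    scale = spec.pixel_scale_um_per_px
    well_r_px = spec.floor_radius_px
    half = int(math.ceil(well_r_px * (1 + margin_frac)))
    size = 2 * half + 1
    c0 = float(half)  # well centre at the frame centre
    cell_r_px = cells.diameter_um / 2.0 / scale

    img = np.full((size, size), _BG_OUTSIDE, dtype=float)
    well = _disk_membership((size, size), c0, c0, well_r_px)
    img[well] = _BG_WELL

    placement = cells.placement
    if placement == "center_clustered" and spec.shape == "flat":
        placement = "uniform_in_well"  # flat floors do not focus cells

    mask = np.zeros((size, size), dtype=bool)
    if n_cells > 0:
        centers = _place_centers(
            rng, n_cells, well_r_px, cell_r_px, placement, cells.overlap_allowed
        )
        for dx, dy in centers:
            cx, cy = c0 + dx, c0 + dy
            cell = _disk_membership((size, size), cx, cy, cell_r_px)
            if cells.intensity_profile == "bright_ring_dark_center":
                core = _disk_membership((size, size), cx, cy, cell_r_px * 0.6)
                img[cell] = _CELL_RIM
                img[core] = _CELL_CORE
            else:
                img[cell] = _CELL_CORE
            mask |= cell

    if artifacts.bubble_probability > 0 and rng.uniform() < artifacts.bubble_probability:
        b_r = rng.uniform(*artifacts.bubble_radius_um) / scale
        rad = max(0.0, well_r_px - b_r)
        d = rad * math.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * math.pi)
        bx, by = c0 + d * math.cos(th), c0 + d * math.sin(th)
        bubble = _disk_membership((size, size), bx, by, b_r)
        if artifacts.bubble_shadow:
            img[bubble] = _BUBBLE_RIM  # shadow ring = outer annulus
        inner = _disk_membership((size, size), bx, by, b_r * 0.85)
        img[inner] = _BUBBLE_CORE
        # the bubble occludes anything beneath it; the mask marks only the
        # cell pixels actually rendered in the frame
        mask &= ~bubble

    img = img + rng.normal(0.0, _NOISE_SD, img.shape)
    img8 = np.clip(np.round(img * 255), 0, 255).astype(np.uint8)

    pixel_area = scale * scale
    truth = GroundTruth(
        mask=mask,
        n_cells=n_cells,
        covered_area_um2=float(mask.sum()) * pixel_area,
        roi=CircleROI(center_x_px=c0, center_y_px=c0, radius_px=well_r_px),
    )
    image = WellImage(
        pixels=img8,
        pixel_scale_um_per_px=scale,
        well_id=well_id,
        channel_id=channel_id,
        time_h=time_h,
    )
    return image, truth


def simulate_seeding(
    mode: Literal["by_channel", "by_well"],
    mean_cells_per_well: float,
    n_wells: int,
    seed: int = 0,
) -> list[int]:
    """Draw per-well initial cell counts for one seeding event.

    Channel-based seeding distributes cells evenly (CV ~ 5%); per-well
    pipetting is far more variable (CV ~ 25%). Counts are truncated-normal
    draws rounded to integers; the mean equals ``mean_cells_per_well`` in
    expectation.
    """
    if n_wells < 1:
        raise ValueError("n_wells must be >= 1")
    if mode not in SEEDING_CV:
        raise ValueError(f"unknown seeding mode {mode!r}")
    if mean_cells_per_well == 0:
        return [0] * n_wells
    rng = np.random.default_rng(seed)
    sd = SEEDING_CV[mode] * mean_cells_per_well
    draws = rng.normal(mean_cells_per_well, sd, size=n_wells)
    return [int(round(max(0.0, d))) for d in draws]


def simulate_timeseries(
    growth: GrowthModel,
    interval_h: float,
    horizon_h: float,
) -> list[tuple[float, float]]:
    """Sample a growth curve at regular imaging intervals.

    Counts follow ``n0 * 2**(t / doubling_time)`` with multiplicative
    log-normal noise of coefficient of variation ``noise_cv``. If a drying
    onset is set, the count collapses once to ``drying_floor_frac`` of its
    value at onset and growth ceases — there is no recovery.
    """
    if interval_h <= 0:
        raise ValueError("interval_h must be > 0")
    if horizon_h < interval_h:
        raise ValueError("horizon_h must be >= interval_h")
    rng = np.random.default_rng(growth.seed)
    times = np.arange(0.0, horizon_h + 1e-9, interval_h)
    out: list[tuple[float, float]] = []
    for t in times:
        if growth.drying_onset_h is not None and t >= growth.drying_onset_h:
            base = (
                growth.n0_cells
                * 2 ** (growth.drying_onset_h / growth.doubling_time_h)
                * growth.drying_floor_frac
            )
        else:
            base = growth.n0_cells * 2 ** (t / growth.doubling_time_h)
        if growth.noise_cv > 0 and base > 0:
            # log-normal with unit mean and the requested CV
            sigma = math.sqrt(math.log(1 + growth.noise_cv**2))
            base *= rng.lognormal(-(sigma**2) / 2, sigma)
        out.append((float(t), float(base)))
    return out


def benchmark_dataset(
    spec: WellSpec,
    n_initial: int = 7,
    n_pool: int = 30,
    n_validation: int = 10,
    mean_cells: int = 40,
    seed: int = 0,
    bubble_probability: float = 0.0,
):
    """Build a labeled/pool/validation split for segmenter benchmarks.

    All frames share one well geometry (and therefore one true ROI). Cell
    counts vary uniformly in [mean_cells/2, 3*mean_cells/2]. Returns
    ``(initial_pairs, pool_images, truth_by_image_id, validation_pairs,
    roi)`` where ``truth_by_image_id`` maps ``id(image)`` to its
    ground-truth mask — the ready-made "perfect corrector" lookup for
    self-training runs.
    """
    # local import: SegMask lives downstream of this module's public types
    from .segmentation import SegMask

    rng = np.random.default_rng(seed)
    cells = CellRenderSpec(
        placement=(
            "center_clustered" if spec.shape == "u_bottom" else "uniform_in_well"
        )
    )
    art = ArtifactSpec(bubble_probability=bubble_probability)

    def make(n_frames: int):
        pairs = []
        for _ in range(n_frames):
            n = int(rng.integers(mean_cells // 2, (3 * mean_cells) // 2 + 1))
            img, truth = render_well(
                spec, cells, n, art, seed=int(rng.integers(0, 2**31 - 1))
            )
            pairs.append((img, truth))
        return pairs

    initial = [(img, SegMask(t.mask)) for img, t in make(n_initial)]
    pool_pairs = make(n_pool)
    pool = [img for img, _ in pool_pairs]
    truth_lookup = {id(img): SegMask(t.mask) for img, t in pool_pairs}
    validation = [(img, SegMask(t.mask)) for img, t in make(n_validation)]
    # the true ROI is identical across frames; take it from any ground truth
    roi = pool_pairs[0][1].roi if pool_pairs else make(1)[0][1].roi
    return initial, pool, truth_lookup, validation, roi
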