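"""Cell-count estimation from segmented cell-covered area.

Flat-bottom wells: settled suspension cells form a monolayer, so the count
is simply

    N = total cell-covered area / average single-cell area,

with the single-cell area taken as the projected disk of a spherical
Jurkat cell, pi d^2 / 4 (176.71 µm² at d = 15 µm).

U-bottom wells (lower half of a prolate spheroid, top radius R, depth c):
cells pile into a central 3-D colony, so area alone undercounts. The
segmented cluster areas are summed and treated as one circular colony of
radius r = sqrt(sum(areas) / pi) centred at the bottom of the well. The gap
between colony top and well top is

    h' = c * sqrt(1 - r^2 / R^2),

the colony height is h = c - h', and the occupied volume is

    V_cells = pi r^2 h - pi r^2 h^3 / (3 c^2).

Dividing V_cells by the single-cell volume (pi d^3 / 6) gives the count.
The V_cells formula above is kept verbatim as the method's defining
arithmetic even though it is not the exact spheroidal-cap volume at
intermediate fill heights; an off-by-default ``exact_cap`` mode provides
the exact solid-of-revolution volume for sensitivity analysis (the two
coincide at h = 0 and h = c).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

from .geometry import WellSpec

__all__ = [
    "CellModel",
    "ColonyEstimate",
    "CoverageRecord",
    "make_cell_model",
    "count_flat",
    "gap_height",
    "colony_height",
    "colony_volume",
    "count_u_bottom",
]

#: Tolerance for colony radius exceeding the well top radius before a
#: warning is raised (overlapping masks can slightly overshoot).
_CLAMP_TOL = 0.01


@dataclass(frozen=True)
class CellModel:
    """Spherical single-cell geometry: diameter, projected area, volume."""

    diameter_um: float
    projected_area_um2: float
    volume_um3: float


@dataclass(frozen=True)
class ColonyEstimate:
    """Intermediate U-bottom geometry values and the resulting count."""

    r_um: float
    h_prime_um: float
    h_um: float
    v_cells_um3: float
    n_cells_est: float
    clamped: bool = False


@dataclass(frozen=True)
class CoverageRecord:
    """One well at one time point: covered area and estimated count."""

    well_id: str
    channel_id: str
    time_h: float
    covered_area_um2: float
    n_cells_est: float

    def __post_init__(self) -> None:
        if self.covered_area_um2 < 0:
            raise ValueError("covered_area_um2 must be >= 0")


def make_cell_model(diameter_um: float = 15.0) -> CellModel:
    """Build the spherical cell model from its diameter."""
    if diameter_um <= 0:
        raise ValueError("diameter_um must be > 0")
    return CellModel(
        diameter_um=diameter_um,
        projected_area_um2=math.pi * diameter_um**2 / 4.0,
        volume_um3=math.pi * diameter_um**3 / 6.0,
    )


def count_flat(total_area_um2: float, cell: CellModel) -> float:
    """Monolayer count: covered area divided by single-cell projected area."""
    if total_area_um2 < 0:
        raise ValueError("total_area_um2 must be >= 0")
    return total_area_um2 / cell.projected_area_um2


def gap_height(c_um: float, r_um: float, R_um: float) -> float:
    """Height h' of the space above the colony, h' = c sqrt(1 - r²/R²)."""
    if c_um <= 0:
        raise ValueError("depth c must be > 0")
    if r_um < 0 or r_um > R_um:
        raise ValueError(f"colony radius {r_um} outside [0, {R_um}]")
    return c_um * math.sqrt(1.0 - (r_um / R_um) ** 2)


def colony_height(c_um: float, h_prime_um: float) -> float:
    """Colony height from the well floor, h = c - h'."""
    if not 0 <= h_prime_um <= c_um * (1 + 1e-12):
        raise ValueError(f"gap height {h_prime_um} outside [0, {c_um}]")
    return c_um - min(h_prime_um, c_um)


def colony_volume(
    r_um: float,
    h_um: float,
    c_um: float,
    mode: Literal["as_printed", "exact_cap"] = "as_printed",
) -> float:
    """Colony volume from radius r, height h, and well depth c.

    ``as_printed`` (default) is the defining formula
    ``pi r^2 h - pi r^2 h^3 / (3 c^2)``. ``exact_cap`` is the exact volume
    of revolution of the spheroidal cap with top radius r and height h,
    ``pi r^2 h (3c - h) / (3 (2c - h))``; both modes agree at h = 0 and
    h = c.
    """
    if r_um < 0:
        raise ValueError("r must be >= 0")
    if not 0 <= h_um <= c_um * (1 + 1e-12):
        raise ValueError(f"height {h_um} outside [0, {c_um}]")
    h = min(h_um, c_um)
    if mode == "as_printed":
        return math.pi * r_um**2 * h - math.pi * r_um**2 * h**3 / (3.0 * c_um**2)
    if mode == "exact_cap":
        if h == 0:
            return 0.0
        return math.pi * r_um**2 * h * (3.0 * c_um - h) / (3.0 * (2.0 * c_um - h))
    raise ValueError(f"unknown mode {mode!r}")


def count_u_bottom(
    cluster_areas_um2: Sequence[float],
    spec: WellSpec,
    cell: CellModel,
    mode: Literal["as_printed", "exact_cap"] = "as_printed",
) -> ColonyEstimate:
    """Estimate the cell count in a U-bottom well from segmented areas.

    Cluster areas are summed into one equivalent circular colony
    (r = sqrt(sum/pi), clamped to the top radius R), run through the
    gap-height / colony-height / colony-volume chain, and divided by the
    single-cell volume. A summed area exceeding the well's top cross
    section by more than 1% triggers a warning and clamps r to R.
    """
    if spec.shape != "u_bottom":
        raise ValueError("count_u_bottom requires a u_bottom WellSpec")
    if any(a < 0 for a in cluster_areas_um2):
        raise ValueError("cluster areas must be >= 0")
    assert spec.depth_um is not None
    R = spec.top_radius_um
    c = spec.depth_um
    total = float(sum(cluster_areas_um2))
    r = math.sqrt(total / math.pi)
    clamped = False
    if r > R:
        if total > math.pi * R**2 * (1 + _CLAMP_TOL):
            warnings.warn(
                f"summed cluster area {total:.0f} µm² exceeds the well top "
                f"cross-section {math.pi * R**2:.0f} µm²; colony radius "
                "clamped to R",
                stacklevel=2,
            )
        r = R
        clamped = True
    h_prime = gap_height(c, r, R)
    h = colony_height(c, h_prime)
    v = colony_volume(r, h, c, mode=mode)
    return ColonyEstimate(
        r_um=r,
        h_prime_um=h_prime,
        h_um=h,
        v_cells_um3=v,
        n_cells_est=v / cell.volume_um3,
        clamped=clamped,
    )
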