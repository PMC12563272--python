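"""Perfusion protocols, medium-consumption budgets, and dispense schedules.

Three feeding regimens are modeled for microfluidic culture:

* ``static``       — no flow, no medium exchange (the control);
* ``constant``     — continuous laminar flow at a fixed rate
                     (e.g. 2 µL/min, the lowest stable sensor-readable rate);
* ``intermittent`` — a short pulse at a higher rate, then a no-flow
                     interval, repeated every period (e.g. 10 µL/min for
                     5 min every 3 h → 50 µL per cycle per channel).

Budget arithmetic answers "how much medium does an experiment consume",
the practical argument for intermittent perfusion and for chips over
conventional well plates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

__all__ = [
    "FlowProtocol",
    "Schedule",
    "volume_per_cycle",
    "consumption",
    "consumption_ratio",
    "plate_budget",
    "build_schedule",
]


@dataclass(frozen=True)
class FlowProtocol:
    """A feeding regimen for one device.

    ``period_h`` is required for intermittent protocols and optional for
    constant ones (where it only defines the reporting cycle length).
    """

    mode: Literal["static", "constant", "intermittent"]
    rate_ul_per_min: float = 0.0
    pulse_min: float | None = None
    period_h: float | None = None
    channels: int = 1
    name: str = ""

    def __post_init__(self) -> None:
        if self.channels < 1:
            raise ValueError("channels must be >= 1")
        if self.mode == "static":
            if self.rate_ul_per_min != 0:
                raise ValueError("static protocols have rate 0")
        elif self.mode == "constant":
            if self.rate_ul_per_min <= 0:
                raise ValueError("constant protocols require rate > 0")
        elif self.mode == "intermittent":
            if self.rate_ul_per_min <= 0:
                raise ValueError("intermittent protocols require rate > 0")
            if self.pulse_min is None or self.pulse_min <= 0:
                raise ValueError("intermittent protocols require pulse_min > 0")
            if self.period_h is None or self.period_h <= 0:
                raise ValueError("intermittent protocols require period_h > 0")
            if self.pulse_min >= self.period_h * 60:
                raise ValueError("pulse must be shorter than the period")
        else:
            raise ValueError(f"unknown mode {self.mode!r}")


#: Protocols used with the two devices: ibidi channels get a 5-min pulse at
#: 10 µL/min every 3 h (50 µL/cycle); the faster-drying PDMS device gets a
#: 20-min pulse at 10 µL/min every 2 h (200 µL/cycle).
PROTOCOL_PRESETS: dict[str, FlowProtocol] = {
    "static": FlowProtocol(mode="static", name="static"),
    "constant_2ul": FlowProtocol(
        mode="constant", rate_ul_per_min=2.0, period_h=3.0, name="constant_2ul"
    ),
    "intermittent_ibidi": FlowProtocol(
        mode="intermittent",
        rate_ul_per_min=10.0,
        pulse_min=5.0,
        period_h=3.0,
        name="intermittent_ibidi",
    ),
    "intermittent_pdms": FlowProtocol(
        mode="intermittent",
        rate_ul_per_min=10.0,
        pulse_min=20.0,
        period_h=2.0,
        name="intermittent_pdms",
    ),
}


@dataclass(frozen=True)
class Schedule:
    """Dispense events plus imaging timestamps over an experiment horizon."""

    imaging_interval_h: float
    dispense_events: tuple[tuple[float, float, float], ...]  # (start_h, duration_min, rate)
    imaging_times_h: tuple[float, ...]
    horizon_h: float


def volume_per_cycle(p: FlowProtocol) -> float:
    """Medium dispensed per period in one channel, µL.

    static → 0; constant → rate x period; intermittent → rate x pulse.
    """
    if p.mode == "static":
        return 0.0
    if p.mode == "constant":
        if p.period_h is None:
            raise ValueError("constant protocol needs period_h to define a cycle")
        return p.rate_ul_per_min * p.period_h * 60.0
    assert p.pulse_min is not None
    return p.rate_ul_per_min * p.pulse_min


def consumption(p: FlowProtocol, horizon_h: float) -> float:
    """Total medium consumed over a horizon across all channels, µL.

    Constant flow integrates exactly over the horizon; intermittent flow
    counts every pulse whose start falls strictly within the horizon (the
    t = 0 pulse counts, a pulse starting exactly at the horizon does not).
    """
    if horizon_h < 0:
        raise ValueError("horizon_h must be >= 0")
    if horizon_h == 0 or p.mode == "static":
        return 0.0
    if p.mode == "constant":
        return p.rate_ul_per_min * horizon_h * 60.0 * p.channels
    assert p.period_h is not None and p.pulse_min is not None
    n_pulses = math.ceil(horizon_h / p.period_h - 1e-12)
    return n_pulses * p.rate_ul_per_min * p.pulse_min * p.channels


def consumption_ratio(a: FlowProtocol, b: FlowProtocol, horizon_h: float) -> float:
    """consumption(a) / consumption(b) over the same horizon."""
    denom = consumption(b, horizon_h)
    if denom == 0:
        name = b.name or b.mode
        raise ZeroDivisionError(
            f"protocol {name!r} consumes no medium over {horizon_h} h"
        )
    return consumption(a, horizon_h) / denom


def plate_budget(wells: int, volume_per_well_ul: float) -> float:
    """Total medium to fill a plate or device, µL (wells x volume per well)."""
    if wells < 1:
        raise ValueError("wells must be >= 1")
    if volume_per_well_ul <= 0:
        raise ValueError("volume_per_well_ul must be > 0")
    return wells * volume_per_well_ul


def build_schedule(
    p: FlowProtocol,
    imaging_interval_h: float,
    horizon_h: float,
    *,
    imaging_offset_min: float = 10.0,
) -> Schedule:
    """Interleave dispense events and imaging over an experiment.

    Intermittent pulses start at each period boundary; imaging is offset
    ``imaging_offset_min`` after each imaging-interval boundary so frames
    are never captured while medium is moving. Constant flow is continuous
    (one event spanning the horizon), so only the imaging cadence applies.
    """
    if imaging_interval_h <= 0:
        raise ValueError("imaging_interval_h must be > 0")
    if horizon_h < imaging_interval_h:
        raise ValueError("horizon must cover at least one imaging interval")

    events: list[tuple[float, float, float]] = []
    if p.mode == "constant":
        events.append((0.0, horizon_h * 60.0, p.rate_ul_per_min))
    elif p.mode == "intermittent":
        assert p.period_h is not None and p.pulse_min is not None
        if p.pulse_min >= p.period_h * 60:
            raise ValueError("pulse longer than period")
        t = 0.0
        while t < horizon_h - 1e-12:
            events.append((t, p.pulse_min, p.rate_ul_per_min))
            t += p.period_h

    imaging: list[float] = []
    t = 0.0
    offset_h = imaging_offset_min / 60.0
    while t <= horizon_h + 1e-12:
        imaging.append(round(t + offset_h, 9))
        t += imaging_interval_h
    if p.mode == "intermittent":
        assert p.pulse_min is not None
        for ti in imaging:
            for start, dur_min, _ in events:
                if start <= ti < start + dur_min / 60.0:
                    raise ValueError(
                        f"imaging at {ti} h falls inside the dispense window "
                        f"starting at {start} h; adjust imaging_offset_min"
                    )
    return Schedule(
        imaging_interval_h=imaging_interval_h,
        dispense_events=tuple(events),
        imaging_times_h=tuple(imaging),
        horizon_h=horizon_h,
    )
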