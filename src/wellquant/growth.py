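"""Growth-curve aggregation, collapse detection, and condition comparison.

Per-well count estimates are grouped by (channel, time point) into a mean
± SEM growth curve — the "row statistics" view of a multi-well experiment.
SEM uses the sample (n-1) standard deviation divided by sqrt(n); a time
point backed by a single well reports SEM 0 and is flagged.

``detect_collapse`` flags drying-like events: an abrupt drop below a
fraction of the running maximum with no subsequent recovery, the signature
of a chip losing its medium.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .counting import CoverageRecord

__all__ = [
    "GrowthCurvePoint",
    "aggregate",
    "detect_collapse",
    "compare_conditions",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GrowthCurvePoint:
    """Mean ± SEM of the per-well counts in one channel at one time point."""

    channel_id: str
    time_h: float
    mean_count: float
    sem_count: float
    n_wells: int
    single_well: bool = False  # n = 1: SEM is 0 by convention, not precision


def aggregate(records: Sequence[CoverageRecord]) -> list[GrowthCurvePoint]:
    """Group records by (channel, time) into mean ± SEM curve points.

    Points are ordered by channel then time. Wells missing at a time point
    simply reduce that point's n (with a log note when channels are ragged).
    """
    if len(records) == 0:
        raise ValueError("no records to aggregate")
    df = pd.DataFrame(
        {
            "channel_id": [r.channel_id for r in records],
            "time_h": [r.time_h for r in records],
            "n": [r.n_cells_est for r in records],
        }
    )
    out: list[GrowthCurvePoint] = []
    grouped = df.groupby(["channel_id", "time_h"], sort=True)["n"]
    counts = grouped.size()
    if counts.nunique() > 1:
        logger.warning(
            "uneven well counts across time points (min %d, max %d); "
            "missing wells are dropped from their point's n",
            counts.min(),
            counts.max(),
        )
    for (channel, time_h), vals in grouped:
        n = len(vals)
        sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        out.append(
            GrowthCurvePoint(
                channel_id=str(channel),
                time_h=float(time_h),
                mean_count=float(vals.mean()),
                sem_count=sem,
                n_wells=n,
                single_well=(n == 1),
            )
        )
    return out


def detect_collapse(
    curve: Sequence[GrowthCurvePoint],
    drop_frac: float = 0.5,
) -> float | None:
    """Earliest time the mean count drops below ``drop_frac`` x running max
    and never again exceeds that maximum; ``None`` if no such event.

    A dip followed by recovery above the prior maximum is growth noise, not
    a drying event, and is not reported.
    """
    if not 0 < drop_frac < 1:
        raise ValueError("drop_frac must be in (0, 1)")
    pts = sorted(curve, key=lambda p: p.time_h)
    means = np.array([p.mean_count for p in pts])
    times = [p.time_h for p in pts]
    running_max = np.maximum.accumulate(means)
    for i in range(1, len(pts)):
        prior_max = running_max[i - 1]
        if prior_max > 0 and means[i] < drop_frac * prior_max:
            if not np.any(means[i + 1 :] > prior_max):
                return times[i]
    return None


def compare_conditions(
    curves: Mapping[str, Sequence[GrowthCurvePoint]],
    reference: str,
) -> pd.DataFrame:
    """Final-time-point comparison table across experimental conditions.

    All curves must share the same final time point. Returns one row per
    condition with the final mean, SEM, n, and fold-change relative to the
    named reference condition.
    """
    if len(curves) < 2:
        raise ValueError("need at least two conditions")
    if reference not in curves:
        raise KeyError(f"reference condition {reference!r} not among curves")
    finals = {}
    for name, curve in curves.items():
        if len(curve) == 0:
            raise ValueError(f"condition {name!r} has an empty curve")
        finals[name] = max(curve, key=lambda p: p.time_h)
    final_times = {p.time_h for p in finals.values()}
    if len(final_times) != 1:
        raise ValueError(f"conditions end at different times: {sorted(final_times)}")
    ref_mean = finals[reference].mean_count
    rows = []
    for name, p in finals.items():
        rows.append(
            {
                "condition": name,
                "time_h": p.time_h,
                "mean_count": p.mean_count,
                "sem_count": p.sem_count,
                "n_wells": p.n_wells,
                "fold_change_vs_ref": (
                    p.mean_count / ref_mean if ref_mean > 0 else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)
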