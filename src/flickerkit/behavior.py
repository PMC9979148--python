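"""Open-field behavioral analysis: inactivity bouts and center-zone occupancy.

Inactivity is defined as the tracked position staying within 0.01% of the
total arena area for longer than 0.5 s (strictly).  The footprint of a
candidate interval is the bounding box of its positions by default, with a
bounding-disc alternative that is rotation-invariant.  Frame gaps (lost
tracking) split candidate bouts.  Center-zone occupancy is the fraction of
frames falling inside the zone rectangle (boundary inclusive).  Condition
comparisons use a one-way repeated-measures ANOVA.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.anova import AnovaRM

from .synthneuro import Trajectory

__all__ = [
    "BehaviorReport",
    "classify_inactivity",
    "percent_time_active",
    "percent_time_in_zone",
    "analyze_trajectory",
    "compare_conditions",
    "DEFAULT_AREA_FRACTION",
    "DEFAULT_MIN_BOUT_S",
]

DEFAULT_AREA_FRACTION = 1e-4  # 0.01% of the total arena
DEFAULT_MIN_BOUT_S = 0.5


@dataclass
class BehaviorReport:
    """Summary of one open-field session."""

    percent_time_active: float
    percent_time_in_center: float
    bouts: list[tuple[float, float]]  # (start_s, end_s) inactivity bouts
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for p in (self.percent_time_active, self.percent_time_in_center):
            if not 0.0 <= p <= 100.0:
                raise ValueError("percentages must lie in [0, 100]")

    @property
    def percent_time_inactive(self) -> float:
        return 100.0 - self.percent_time_active

    def bouts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.bouts, columns=["start_s", "end_s"])

    def to_csv(self, path) -> None:
        summary = pd.DataFrame(
            [
                {
                    "percent_time_active": self.percent_time_active,
                    "percent_time_in_center": self.percent_time_in_center,
                    "n_inactivity_bouts": len(self.bouts),
                    **{f"param_{k}": v for k, v in self.params.items()},
                }
            ]
        )
        summary.to_csv(path, index=False)


class _SlidingExtrema:
    """Monotonic deques tracking min/max of a sliding index window."""

    def __init__(self, values: np.ndarray):
        self.values = values
        self.maxq: deque[int] = deque()
        self.minq: deque[int] = deque()

    def push(self, j: int) -> None:
        v = self.values[j]
        while self.maxq and self.values[self.maxq[-1]] <= v:
            self.maxq.pop()
        self.maxq.append(j)
        while self.minq and self.values[self.minq[-1]] >= v:
            self.minq.pop()
        self.minq.append(j)

    def drop_before(self, i: int) -> None:
        while self.maxq and self.maxq[0] < i:
            self.maxq.popleft()
        while self.minq and self.minq[0] < i:
            self.minq.popleft()

    @property
    def range(self) -> float:
        return self.values[self.maxq[0]] - self.values[self.minq[0]]


def _footprint_ok(xr: float, yr: float, limit: float, shape: str) -> bool:
    if shape == "box":
        return xr * yr <= limit
    if shape == "disc":
        # disc circumscribing the bounding box
        r = 0.5 * np.hypot(xr, yr)
        return np.pi * r * r <= limit
    raise ValueError(f"unknown footprint shape {shape!r}")


def _min_valid_start(x: np.ndarray, y: np.ndarray, limit: float, footprint: str) -> np.ndarray:
    """For each frame j, the smallest i such that frames i..j stay confined."""
    n = len(x)
    xs, ys = _SlidingExtrema(x), _SlidingExtrema(y)
    min_start = np.empty(n, dtype=int)
    i = 0
    for j in range(n):
        xs.push(j)
        ys.push(j)
        while not _footprint_ok(xs.range, ys.range, limit, footprint):
            i += 1
            xs.drop_before(i)
            ys.drop_before(i)
        min_start[j] = i
    return min_start


def classify_inactivity(
    traj: Trajectory,
    area_fraction: float = DEFAULT_AREA_FRACTION,
    min_duration: float = DEFAULT_MIN_BOUT_S,
    footprint: str = "box",
) -> list[tuple[float, float]]:
    """Maximal intervals of confinement longer than ``min_duration``.

    An interval is an inactivity bout iff the footprint (bounding box by
    default, ``footprint="disc"`` for the rotation-invariant bounding-disc
    variant) of its positions covers at most ``area_fraction`` of the arena
    AND its duration exceeds ``min_duration`` strictly.  Gaps in the frame
    clock larger than 1.5x the median frame interval split candidates.
    Returns (start_s, end_s) pairs of maximal, non-overlapping bouts.
    """
    n = len(traj.t)
    if n < 2:
        raise ValueError("need at least 2 frames to classify inactivity")
    limit = area_fraction * traj.arena_area
    dts = np.diff(traj.t)
    gap_after = np.flatnonzero(dts > 1.5 * np.median(dts))

    bouts: list[tuple[float, float]] = []
    chunk_edges = np.concatenate([[0], gap_after + 1, [n]])
    for c0, c1 in zip(chunk_edges[:-1], chunk_edges[1:]):
        if c1 - c0 < 2:
            continue
        t = traj.t[c0:c1]
        min_start = _min_valid_start(traj.x[c0:c1], traj.y[c0:c1], limit, footprint)
        m = c1 - c0
        i = 0
        j = 0
        while i < m:
            if j < i:
                j = i
            while j + 1 < m and min_start[j + 1] <= i:
                j += 1
            if t[j] - t[i] > min_duration:
                bouts.append((float(t[i]), float(t[j])))
                i = j + 1
            else:
                i += 1
    return bouts


def percent_time_active(traj: Trajectory, bouts: Sequence[tuple[float, float]]) -> float:
    """100 x (1 - total inactivity-bout time / record time)."""
    record = traj.duration
    if record <= 0:
        raise ValueError("trajectory has no duration")
    inactive = sum(e - s for s, e in bouts)
    return 100.0 * (1.0 - inactive / record)


def percent_time_in_zone(traj: Trajectory, zone: Optional[tuple] = None) -> float:
    """Percentage of frames inside the zone rectangle (boundary inclusive)."""
    if zone is None:
        zone = traj.center_zone
    x0, y0, x1, y1 = zone
    if x1 <= x0 or y1 <= y0:
        raise ValueError("degenerate zone rectangle")
    if x0 < 0 or y0 < 0 or x1 > traj.arena_width or y1 > traj.arena_height:
        raise ValueError("zone must lie within the arena")
    inside = (traj.x >= x0) & (traj.x <= x1) & (traj.y >= y0) & (traj.y <= y1)
    return 100.0 * float(inside.mean())


def analyze_trajectory(
    traj: Trajectory,
    area_fraction: float = DEFAULT_AREA_FRACTION,
    min_duration: float = DEFAULT_MIN_BOUT_S,
    footprint: str = "box",
    zone: Optional[tuple] = None,
) -> BehaviorReport:
    """Full behavioral report for one session."""
    bouts = classify_inactivity(traj, area_fraction, min_duration, footprint)
    return BehaviorReport(
        percent_time_active=percent_time_active(traj, bouts),
        percent_time_in_center=percent_time_in_zone(traj, zone),
        bouts=bouts,
        params={
            "area_fraction": area_fraction,
            "min_duration_s": min_duration,
            "footprint": footprint,
        },
    )


def compare_conditions(values_by_condition: dict[str, Sequence[float]]) -> dict:
    """One-way repeated-measures ANOVA across stimulation conditions.

    ``values_by_condition`` maps condition label -> per-subject values, with
    subjects aligned by position (a balanced within-subject design).
    Returns ``{"F", "df", "p"}`` with ``df = (df_condition, df_error)``.
    """
    lengths = {len(v) for v in values_by_condition.values()}
    if len(lengths) != 1:
        raise ValueError("unbalanced design: all conditions need the same subjects")
    (n_subjects,) = lengths
    if n_subjects < 2 or len(values_by_condition) < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    rows = [
        {"subject": s, "condition": cond, "value": float(v)}
        for cond, vals in values_by_condition.items()
        for s, v in enumerate(vals)
    ]
    long = pd.DataFrame(rows)
    if long["value"].var() == 0:  # identical values everywhere: F = 0 by definition
        k = len(values_by_condition)
        return {"F": 0.0, "df": (k - 1, (k - 1) * (n_subjects - 1)), "p": 1.0}
    res = AnovaRM(long, depvar="value", subject="subject", within=["condition"]).fit()
    row = res.anova_table.iloc[0]
    return {
        "F": float(row["F Value"]),
        "df": (float(row["Num DF"]), float(row["Den DF"])),
        "p": float(row["Pr > F"]),
    }
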