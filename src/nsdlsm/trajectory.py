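"""Trajectory container and temporal preprocessing.

A trajectory is a time-ordered sequence of projected (metric) GPS fixes for
one animal.  Broad-scale strategy classification works on one position per
day, so sub-daily fixes are first collapsed to daily means.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Minimum number of daily positions a series must retain to be usable for
#: model fitting: two encamped modes plus their transitions are not
#: estimable on shorter records.
MIN_SERIES_DAYS = 90


@dataclass(frozen=True)
class Trajectory:
    """Timestamped planar positions for a single animal.

    Parameters
    ----------
    animal_id : str
        Identifier of the tracked individual.
    times : np.ndarray
        Fix timestamps as ``datetime64[ns]`` (UTC), strictly increasing.
    x, y : np.ndarray
        Projected coordinates in meters.
    """

    animal_id: str
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    daily: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype="datetime64[ns]")
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if times.size == 0:
            raise ValueError("no fixes")
        if not (times.size == x.size == y.size):
            raise ValueError("times, x and y must have equal length")
        if times.size > 1 and not np.all(np.diff(times).astype(np.int64) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return self.times.size

    @property
    def dates(self) -> np.ndarray:
        """UTC calendar date of each fix (``datetime64[D]``)."""
        return self.times.astype("datetime64[D]")


def daily_average(traj: Trajectory) -> Trajectory:
    """Collapse a trajectory to one fix per UTC calendar day.

    Each day's position is the arithmetic mean of that day's fixes and is
    timestamped at noon UTC.  Days with no fixes are simply absent; they
    become missing slots on the contiguous day grid downstream.
    """
    if len(traj) == 0:  # pragma: no cover - constructor forbids this
        raise ValueError("no fixes")
    days = traj.dates
    uniq, inverse = np.unique(days, return_inverse=True)
    n = np.bincount(inverse)
    mx = np.bincount(inverse, weights=traj.x) / n
    my = np.bincount(inverse, weights=traj.y) / n
    noon = uniq.astype("datetime64[ns]") + np.timedelta64(12, "h")
    return Trajectory(traj.animal_id, noon, mx, my, daily=True)


def shift_origin(traj: Trajectory, offset_days: int) -> Trajectory:
    """Drop the first ``offset_days`` calendar days of a trajectory.

    Re-anchors the path so that displacement is measured from a later
    starting point; used to probe how sensitive a classification is to the
    (often arbitrary) start of the monitoring record.
    """
    if offset_days < 0:
        raise ValueError("offset_days must be non-negative")
    if offset_days == 0:
        return traj
    cutoff = traj.dates[0] + np.timedelta64(offset_days, "D")
    keep = traj.dates >= cutoff
    if keep.sum() < MIN_SERIES_DAYS:
        raise ValueError(
            f"shifted series too short: {int(keep.sum())} fixes remain, "
            f"need at least {MIN_SERIES_DAYS}"
        )
    return Trajectory(
        traj.animal_id, traj.times[keep], traj.x[keep], traj.y[keep], daily=traj.daily
    )
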