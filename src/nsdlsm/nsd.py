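"""Net squared displacement (NSD) series on a contiguous daily grid.

NSD_t is the squared Euclidean distance between the position on day t and
the first daily position of the path.  The series is laid out on a
contiguous calendar-day grid so that days without data keep an explicit
slot: a first-order Markov chain on the latent modes can then bridge gaps
instead of pretending consecutive observations are one day apart.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np

from .trajectory import Trajectory


@dataclass(frozen=True)
class NSDSeries:
    """Daily NSD values with missing-day mask.

    Attributes
    ----------
    day_index : np.ndarray
        1-based day index on the contiguous grid (1..T).
    dates : np.ndarray
        Calendar date of each slot (``datetime64[D]``).
    nsd_raw : np.ndarray
        NSD in m^2; NaN where the day is unobserved.
    nsd_std : np.ndarray or None
        Range-standardized NSD in [0, 1]; None until ``standardize``.
    observed : np.ndarray
        Boolean mask, True where the day has data.
    origin : tuple
        (x, y) of the first daily position, in meters.
    std_range : tuple or None
        (min, max) of observed nsd_raw used by the standardization;
        retained so posterior mode means can be mapped back to m^2.
    """

    animal_id: str
    day_index: np.ndarray
    dates: np.ndarray
    nsd_raw: np.ndarray
    observed: np.ndarray
    origin: Tuple[float, float]
    nsd_std: Optional[np.ndarray] = None
    std_range: Optional[Tuple[float, float]] = None

    @property
    def T(self) -> int:
        """Number of days spanned, including gaps."""
        return self.day_index.size

    @property
    def n_observed(self) -> int:
        return int(self.observed.sum())


def compute_nsd(traj: Trajectory) -> NSDSeries:
    """Build the contiguous daily NSD series of a daily-averaged trajectory.

    The origin is the first daily-averaged position.  Every calendar day
    between the first and last fix gets a slot; days without a fix are
    marked unobserved and carry NaN.
    """
    if not traj.daily:
        raise ValueError("trajectory must be daily-averaged (run daily_average first)")
    if len(traj) < 2:
        raise ValueError("series too short: need at least two daily positions")
    days = traj.dates
    t0, t1 = days[0], days[-1]
    T = int((t1 - t0).astype(np.int64)) + 1
    grid = t0 + np.arange(T).astype("timedelta64[D]")
    slot = (days - t0).astype(np.int64)

    nsd = np.full(T, np.nan)
    observed = np.zeros(T, dtype=bool)
    dx = traj.x - traj.x[0]
    dy = traj.y - traj.y[0]
    nsd[slot] = dx * dx + dy * dy
    observed[slot] = True
    return NSDSeries(
        animal_id=traj.animal_id,
        day_index=np.arange(1, T + 1),
        dates=grid,
        nsd_raw=nsd,
        observed=observed,
        origin=(float(traj.x[0]), float(traj.y[0])),
    )


def standardize(series: NSDSeries) -> NSDSeries:
    """Range-standardize the observed NSD values to [0, 1].

    The observed minimum maps to 0 and the maximum to 1.  The (min, max)
    pair is retained on the returned series so the transform can be
    inverted (e.g. to express fitted mode means in m^2).
    """
    obs = series.nsd_raw[series.observed]
    lo = float(np.min(obs))
    hi = float(np.max(obs))
    if hi <= lo:
        raise ValueError(
            "degenerate NSD range: all observed values identical "
            "(perfectly stationary animal)"
        )
    std = (series.nsd_raw - lo) / (hi - lo)
    return replace(series, nsd_std=std, std_range=(lo, hi))


def inverse_standardize(series: NSDSeries, values: np.ndarray) -> np.ndarray:
    """Map standardized values back to raw NSD in m^2."""
    if series.std_range is None:
        raise ValueError("series has not been standardized")
    lo, hi = series.std_range
    return np.asarray(values, dtype=float) * (hi - lo) + lo


def trajectory_to_series(traj: Trajectory) -> NSDSeries:
    """Daily-average, compute NSD and standardize in one step."""
    from .trajectory import daily_average

    d = traj if traj.daily else daily_average(traj)
    return standardize(compute_nsd(d))
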