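"""Synthetic daily trajectories for the four stereotyped movement strategies.

Each simulator produces 365 daily positions (by default) in projected
meters, one of:

* **sedentary** — a mean-reverting (discrete Ornstein-Uhlenbeck-style)
  walk around a fixed center: Gaussian steps plus a pull of strength
  ``attraction_strength`` toward the center.  NSD fluctuates within the
  home range with no trend.
* **nomadic** — an unbiased patch-hopping walk: the animal jitters around
  a temporary center, and each day with probability ``relocation_prob``
  it abandons the center and traverses (over a few days) to a new one a
  long hop away in a uniformly random direction.  The hop directions are
  isotropic, so the centers themselves perform an unbiased random walk
  and expected NSD still grows linearly with time; individual paths
  drift through a succession of temporary plateaus punctuated by short
  traverses — the continual-drift structure of nomadism, as opposed to
  the single clean ramp a constant-step walk tends to produce.
* **dispersal** — encamped (mean-reverting) at center A until the
  departure day, a biased walk with a constant drift toward a distant
  center B for a fixed number of travel days, then encamped at B.
* **migration** — dispersal plus a second travel phase after the return
  day that brings the animal back to A, where it re-encamps.

Per-trajectory movement parameters are drawn uniformly from configurable
ranges so the batch exhibits overlap between strategies rather than four
clean stereotypes.  All randomness is driven by per-trajectory integer
seeds derived by counter from a single master seed, so batches are
reproducible and order-independent.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np

from .trajectory import Trajectory

STRATEGIES = ("sedentary", "nomadic", "dispersal", "migration")

#: First calendar day of every simulated trajectory (arbitrary but fixed).
SIM_EPOCH = np.datetime64("2000-01-01", "D")


@dataclass
class SimulationSpec:
    """Fully resolved parameters of one simulated trajectory.

    ``step_scale`` is the standard deviation (meters) of each day's
    Gaussian step noise; ``attraction_strength`` the fraction of the
    distance to the range center recovered per day while encamped;
    ``travel_bias`` the drift magnitude (meters/day) during travel;
    ``departure_day``/``return_day`` the 1-based days on which the travel
    phases begin; ``travel_days`` the length of each travel phase.
    """

    strategy: str
    n_steps: int = 365
    step_scale: float = 500.0
    attraction_strength: float = 0.5
    travel_bias: float = 0.0
    departure_day: int = 0
    return_day: int = 0
    travel_days: int = 0
    heading: float = 0.0           # direction of the A->B axis, radians
    relocation_prob: float = 0.0   # nomadic: daily chance of a long step
    relocation_scale: float = 0.0  # nomadic: long-step sd, meters
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(
                f"unknown strategy {self.strategy!r}; expected one of {STRATEGIES}"
            )
        if self.n_steps < 2:
            raise ValueError("n_steps must be at least 2")
        if self.step_scale < 0:
            raise ValueError("step_scale must be non-negative")
        if not (0.0 <= self.attraction_strength <= 1.0):
            raise ValueError("attraction_strength must lie in [0, 1]")
        if self.strategy in ("dispersal", "migration"):
            if not (1 < self.departure_day < self.n_steps):
                raise ValueError("departure_day must lie strictly inside the series")
            if self.travel_days < 1 or self.travel_bias <= 0:
                raise ValueError("travel phase requires travel_days and travel_bias")
        if self.strategy == "migration" and not (
            self.departure_day < self.return_day < self.n_steps
        ):
            raise ValueError("return_day must follow departure_day inside the series")


@dataclass
class SimulatedDataset:
    trajectories: List[Tuple[Trajectory, str, SimulationSpec]]

    def __len__(self) -> int:
        return len(self.trajectories)

    def labels(self) -> List[str]:
        return [lab for _, lab, _ in self.trajectories]


def _ou_step(pos, center, a, s, rng):
    return pos + a * (center - pos) + rng.normal(0.0, s, size=2)


def simulate_trajectory(spec: SimulationSpec) -> Trajectory:
    """Generate one daily trajectory from a fully resolved spec."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_steps
    a = spec.attraction_strength
    s = spec.step_scale
    pos = np.zeros(2)
    center_a = np.zeros(2)
    xy = np.empty((n, 2))
    xy[0] = pos

    if spec.strategy == "sedentary":
        for t in range(1, n):
            pos = _ou_step(pos, center_a, a, s, rng)
            xy[t] = pos
    elif spec.strategy == "nomadic":
        if spec.relocation_prob <= 0.0:
            # degenerate configuration: plain unbiased walk
            steps = rng.normal(0.0, s, size=(n - 1, 2))
            xy[1:] = np.cumsum(steps, axis=0)
        else:
            center = np.zeros(2)
            trip_left = 0
            trip_step = np.zeros(2)
            a_nom = 0.5  # pull toward the current temporary center
            for t in range(1, n):
                if trip_left > 0:
                    pos = pos + trip_step + rng.normal(0.0, s, size=2)
                    trip_left -= 1
                    if trip_left == 0:
                        center = center + trip_step * spec.travel_days
                else:
                    if rng.random() < spec.relocation_prob:
                        ang = rng.uniform(0.0, 2.0 * np.pi)
                        hop = spec.relocation_scale * np.array(
                            [np.cos(ang), np.sin(ang)]
                        )
                        trip_left = spec.travel_days
                        trip_step = hop / spec.travel_days
                        pos = pos + trip_step + rng.normal(0.0, s, size=2)
                        trip_left -= 1
                        if trip_left == 0:
                            center = center + hop
                    else:
                        pos = _ou_step(pos, center, a_nom, s, rng)
                xy[t] = pos
    else:
        u = np.array([np.cos(spec.heading), np.sin(spec.heading)])
        center_b = center_a + u * spec.travel_bias * spec.travel_days
        dep = spec.departure_day
        t = 1
        while t < n and t < dep:
            pos = _ou_step(pos, center_a, a, s, rng)
            xy[t] = pos
            t += 1
        end_travel = min(dep + spec.travel_days, n)
        while t < n and t < end_travel:
            pos = pos + u * spec.travel_bias + rng.normal(0.0, s, size=2)
            xy[t] = pos
            t += 1
        if spec.strategy == "dispersal":
            while t < n:
                pos = _ou_step(pos, center_b, a, s, rng)
                xy[t] = pos
                t += 1
        else:  # migration
            ret = max(spec.return_day, t)
            while t < n and t < ret:
                pos = _ou_step(pos, center_b, a, s, rng)
                xy[t] = pos
                t += 1
            end_return = min(ret + spec.travel_days, n)
            while t < n and t < end_return:
                pos = pos - u * spec.travel_bias + rng.normal(0.0, s, size=2)
                xy[t] = pos
                t += 1
            while t < n:
                pos = _ou_step(pos, center_a, a, s, rng)
                xy[t] = pos
                t += 1

    times = (
        SIM_EPOCH + np.arange(n).astype("timedelta64[D]")
    ).astype("datetime64[ns]") + np.timedelta64(12, "h")
    return Trajectory(
        animal_id=f"sim_{spec.strategy}_{spec.seed}",
        times=times, x=xy[:, 0], y=xy[:, 1], daily=True,
    )


#: Default per-trajectory parameter ranges.  ``radius_m`` is the 95%
#: home-range radius of an encamped phase (2.448 per-coordinate standard
#: deviations of the stationary mean-reverting walk).  Range centers are
#: 5-20 km apart and at least 12 home-range radii, so the two encamped
#: NSD clusters stay tight relative to the standardized range and the
#: travel days in between fall to the exploratory mode; travel takes
#: 25-60 days (long enough that the exploratory occupancy identifies the
#: q33 cut-off), departures fall mid-year and migrants spend a full
#: second-range residency before returning.  Nomadic walks hop to a new
#: temporary center (a 1-day traverse of 2.5-5 km) on 3-7% of days —
#: residencies of two to five weeks — and use their temporary range
#: diffusely (within-range spread comparable to the hop length, so that
#: successive ranges blur into broad displacement bands rather than
#: forming a staircase of tight plateaus).
DEFAULT_RANGES: Dict[str, Tuple[float, float]] = {
    "radius_m": (500.0, 2000.0),
    "range_radius_m": (500.0, 1500.0),   # dispersal/migration encamped phases
    "attraction": (0.3, 0.7),
    "distance_m": (5000.0, 20000.0),
    "travel_days": (25, 60),
    "departure_day": (100, 180),
    "residency_days": (60, 150),         # second-range occupancy (migration)
    "relocation_prob": (0.03, 0.07),
    "relocation_step_m": (2500.0, 5000.0),
    "trip_days": (1, 1),
    "local_step_m": (1000.0, 1700.0),
}

#: 95% home-range radius in units of per-coordinate standard deviation
#: for an isotropic bivariate Gaussian: sqrt(-2 ln 0.05).
_UD95 = 2.4477

#: Minimum ratio of inter-center distance to encamped 95% radius.
MIN_SEPARATION_RATIO = 12.0


def draw_spec(
    strategy: str,
    seed: int,
    n_steps: int = 365,
    ranges: Optional[Dict[str, Tuple[float, float]]] = None,
) -> SimulationSpec:
    """Draw randomized movement parameters for one trajectory.

    The integer ``seed`` drives both the parameter draws and (stored on
    the returned spec) the path noise, so a spec alone reproduces its
    trajectory exactly.
    """
    r = dict(DEFAULT_RANGES)
    if ranges:
        r.update(ranges)
    for k, (lo, hi) in r.items():
        if hi < lo:
            raise ValueError(f"empty range for {k!r}")
    # parameter draws use a sub-stream distinct from the path-noise stream
    rng = np.random.default_rng(np.random.SeedSequence((seed, 1)))
    a = rng.uniform(*r["attraction"])
    if strategy == "sedentary":
        radius = rng.uniform(*r["radius_m"])
        # step noise giving a stationary 95% home-range radius ~= radius
        s_enc = radius / _UD95 * np.sqrt(a * (2.0 - a))
        return SimulationSpec(
            strategy=strategy, n_steps=n_steps,
            step_scale=s_enc, attraction_strength=a, seed=seed,
        )
    if strategy == "nomadic":
        return SimulationSpec(
            strategy=strategy, n_steps=n_steps,
            step_scale=rng.uniform(*r["local_step_m"]),
            attraction_strength=0.0,
            relocation_prob=rng.uniform(*r["relocation_prob"]),
            relocation_scale=rng.uniform(*r["relocation_step_m"]),
            travel_days=int(rng.integers(r["trip_days"][0], r["trip_days"][1] + 1)),
            seed=seed,
        )
    radius = rng.uniform(*r["range_radius_m"])
    s_enc = radius / _UD95 * np.sqrt(a * (2.0 - a))
    lo_d = max(r["distance_m"][0], MIN_SEPARATION_RATIO * radius)
    hi_d = max(r["distance_m"][1], lo_d)
    distance = rng.uniform(lo_d, hi_d)
    travel_days = int(rng.integers(r["travel_days"][0], r["travel_days"][1] + 1))
    departure = int(
        rng.integers(r["departure_day"][0], r["departure_day"][1] + 1)
    )
    heading = rng.uniform(0.0, 2.0 * np.pi)
    if strategy == "dispersal":
        return SimulationSpec(
            strategy=strategy, n_steps=n_steps,
            step_scale=s_enc, attraction_strength=a,
            travel_bias=distance / travel_days,
            departure_day=departure, travel_days=travel_days,
            heading=heading, seed=seed,
        )
    # migration: the return day follows the outbound travel plus a full
    # second-range residency, and the return leg must finish with time to
    # re-encamp in the first range
    lo_ret = departure + travel_days + int(r["residency_days"][0])
    hi_ret = min(
        departure + travel_days + int(r["residency_days"][1]),
        330,
        n_steps - travel_days - 10,
    )
    hi_ret = max(hi_ret, lo_ret)
    ret = int(rng.integers(lo_ret, hi_ret + 1))
    return SimulationSpec(
        strategy=strategy, n_steps=n_steps,
        step_scale=s_enc, attraction_strength=a,
        travel_bias=distance / travel_days,
        departure_day=departure, return_day=ret, travel_days=travel_days,
        heading=heading, seed=seed,
    )


def _derived_seed(master_seed: int, strategy: str, index: int) -> int:
    ss = np.random.SeedSequence((master_seed, STRATEGIES.index(strategy), index))
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_batch(
    n_per_strategy: int,
    seed: int,
    n_steps: int = 365,
    ranges: Optional[Dict[str, Tuple[float, float]]] = None,
    strategies: Tuple[str, ...] = STRATEGIES,
) -> SimulatedDataset:
    """Generate a balanced labeled dataset of simulated trajectories.

    Per-trajectory seeds are derived by counter from ``seed``, so the
    dataset is bit-reproducible and independent of generation order.
    """
    if n_per_strategy < 1:
        raise ValueError("n_per_strategy must be at least 1")
    out: List[Tuple[Trajectory, str, SimulationSpec]] = []
    for strat in strategies:
        for i in range(n_per_strategy):
            spec = draw_spec(
                strat, _derived_seed(seed, strat, i), n_steps=n_steps, ranges=ranges
            )
            out.append((simulate_trajectory(spec), strat, spec))
    return SimulatedDataset(trajectories=out)
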