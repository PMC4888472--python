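"""Readers, writers and run configuration.

Input fixes are delimited text with one row per GPS fix.  The default
column names are ``animal_id,timestamp,x,y`` with ISO-8601 timestamps and
projected coordinates in meters; a column mapping makes Movebank-style
exports (extra columns, different names) readable without editing files.
Geographic coordinates are rejected outright — NSD in squared degrees is
meaningless, and the projection choice belongs to the user.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .trajectory import Trajectory

logger = logging.getLogger("nsdlsm")

DEFAULT_COLUMNS = {
    "animal_id": "animal_id",
    "timestamp": "timestamp",
    "x": "x",
    "y": "y",
}

_GEOGRAPHIC_HINTS = ("lon", "lat", "longitude", "latitude")


@dataclass
class RunConfig:
    """End-to-end settings for a classification run."""

    estimator: str = "em"              # "em" or "gibbs"
    decode_method: str = "posterior"   # or "viterbi"
    tol: float = 1e-6
    max_iter: int = 500
    n_starts: int = 5
    sigma_floor: float = 0.005
    gibbs_chains: int = 3
    gibbs_iter: int = 5000
    gibbs_escalation_iter: int = 20000
    sigma_max: float = 1.0
    seed: Optional[int] = None
    columns: Dict[str, str] = field(default_factory=lambda: dict(DEFAULT_COLUMNS))

    def __post_init__(self) -> None:
        if self.estimator not in ("em", "gibbs"):
            raise ValueError("estimator must be 'em' or 'gibbs'")
        if self.decode_method not in ("posterior", "viterbi"):
            raise ValueError("decode_method must be 'posterior' or 'viterbi'")
        if self.tol <= 0 or self.max_iter < 1 or self.n_starts < 1:
            raise ValueError("tol, max_iter and n_starts must be positive")
        if not (0 < self.sigma_floor < self.sigma_max):
            raise ValueError("need 0 < sigma_floor < sigma_max")

    def fit_config(self, seed: Optional[int] = None):
        from .hmm import FitConfig

        return FitConfig(
            tol=self.tol, max_iter=self.max_iter, n_starts=self.n_starts,
            seed=self.seed if seed is None else seed,
            sigma_floor=self.sigma_floor, decode_method=self.decode_method,
        )

    def gibbs_config(self, seed: Optional[int] = None):
        from .gibbs import GibbsConfig

        return GibbsConfig(
            n_chains=self.gibbs_chains, n_iter=self.gibbs_iter,
            escalation_iter=self.gibbs_escalation_iter,
            seed=self.seed if seed is None else seed,
            sigma_floor=self.sigma_floor, sigma_max=self.sigma_max,
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def read_fixes(
    path, columns: Optional[Dict[str, str]] = None
) -> List[Trajectory]:
    """Read a fixes CSV into one trajectory per animal.

    Rows are sorted by time within animal; rows sharing a timestamp are
    averaged (with a logged warning); rows with unparseable timestamps or
    non-numeric coordinates are counted, logged and dropped.  Extra
    columns are ignored.
    """
    mapping = dict(DEFAULT_COLUMNS)
    if columns:
        mapping.update(columns)
    for role in ("x", "y"):
        src = mapping[role].lower()
        if any(h in src for h in _GEOGRAPHIC_HINTS):
            raise ValueError(
                f"column {mapping[role]!r} looks geographic; coordinates must "
                "be planar meters in a projected CRS (NSD in degrees^2 is "
                "meaningless) - project your data first"
            )
    df = pd.read_csv(path)
    missing = [c for c in mapping.values() if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    df = df[[mapping[r] for r in ("animal_id", "timestamp", "x", "y")]]
    df.columns = ["animal_id", "timestamp", "x", "y"]
    n_in = len(df)
    df["timestamp"] = pd.to_datetime(df["timestamp"], errors="coerce", utc=True)
    df["x"] = pd.to_numeric(df["x"], errors="coerce")
    df["y"] = pd.to_numeric(df["y"], errors="coerce")
    bad = df[["timestamp", "x", "y"]].isna().any(axis=1)
    if bad.any():
        logger.warning("dropping %d malformed row(s) of %d", int(bad.sum()), n_in)
        df = df[~bad]
    if df.empty:
        raise ValueError("no valid rows in input file")
    out: List[Trajectory] = []
    for animal, g in df.groupby("animal_id", sort=True):
        g = g.sort_values("timestamp")
        dup = g["timestamp"].duplicated()
        if dup.any():
            logger.warning(
                "animal %s: averaging %d duplicate-timestamp row(s)",
                animal, int(dup.sum()),
            )
            g = g.groupby("timestamp", as_index=False).mean(numeric_only=True)
        times = g["timestamp"].dt.tz_localize(None).to_numpy("datetime64[ns]")
        out.append(Trajectory(str(animal), times, g["x"].to_numpy(), g["y"].to_numpy()))
    return out


def write_fixes(trajectories: List[Trajectory], path) -> None:
    """Write trajectories back to the canonical fixes CSV."""
    frames = [
        pd.DataFrame(
            {"animal_id": t.animal_id, "timestamp": t.times, "x": t.x, "y": t.y}
        )
        for t in trajectories
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_series(series, path) -> None:
    """Write an NSD series as `day,date,nsd_raw,nsd_std,observed`."""
    pd.DataFrame(
        {
            "day": series.day_index,
            "date": series.dates,
            "nsd_raw": series.nsd_raw,
            "nsd_std": series.nsd_std if series.nsd_std is not None else np.nan,
            "observed": series.observed,
        }
    ).to_csv(path, index=False)


def write_sequence(seq, path) -> None:
    """Write a decoded sequence as `day,mode,p1,p2,p3`."""
    pd.DataFrame(
        {
            "day": np.arange(1, seq.modes.size + 1),
            "mode": seq.modes,
            "p1": seq.posterior[:, 0],
            "p2": seq.posterior[:, 1],
            "p3": seq.posterior[:, 2],
        }
    ).to_csv(path, index=False)


def write_report(results: List, path, format: str = "json",
                 config: Optional[RunConfig] = None) -> None:
    """Write classification results with provenance.

    JSON carries the full evidence plus a config echo and package
    version; CSV is one summary row per animal.
    """
    if not results:
        raise ValueError("no results to write")
    path = Path(path)
    if format == "json":
        payload = {
            "schema_version": 1,
            "package_version": __version__,
            "config": asdict(config) if config else None,
            "results": [r.to_dict() for r in results],
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    elif format == "csv":
        rows = []
        for r in results:
            rows.append(
                {
                    "animal_id": r.animal_id,
                    "label": r.label,
                    "q11": r.q11, "q22": r.q22, "q33": r.q33,
                    "departed_mode2": r.departed_mode2,
                    "n_12_per_year": r.evidence_per_year.n_12,
                    "n_21_per_year": r.evidence_per_year.n_21,
                    "days_mode1_per_year": r.evidence_per_year.time_in_mode[0],
                    "days_mode2_per_year": r.evidence_per_year.time_in_mode[1],
                    "days_mode3_per_year": r.evidence_per_year.time_in_mode[2],
                }
            )
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise ValueError("format must be 'json' or 'csv'")


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())
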