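"""2D migration and 3D invasion metrics.

Speed is the total path length divided by elapsed time (µm/min); persistence
is the net start-to-end displacement divided by the total path length, a
dimensionless number in [0, 1] that is 1 for straight-line motion. 3D
invasion is quantified by a single number per spheroid: the fold change in
projected area on day 5 relative to day 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "MigrationMetrics",
    "SpheroidMeasurement",
    "speed",
    "persistence",
    "migration_metrics",
    "fold_change",
    "metrics_table",
    "spheroid_table",
    "read_trajectories",
    "read_spheroids",
]

#: Tracks shorter than this are excluded from population statistics
#: (persistence of a 2-point track is identically 1 and uninformative).
MIN_TRACK_POINTS = 3


@dataclass(frozen=True)
class Trajectory:
    """One tracked cell: strictly increasing times (min) and (x, y) µm."""

    cell_id: str
    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.positions, dtype=float)
        if p.ndim != 2 or p.shape[1] != 2 or len(t) != len(p):
            raise ValueError("positions must be (n, 2) and match times")
        if len(t) < 2:
            raise ValueError("a trajectory needs at least 2 time points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "positions", p)

    def path_length(self) -> float:
        steps = np.diff(self.positions, axis=0)
        return float(np.hypot(steps[:, 0], steps[:, 1]).sum())

    def net_displacement(self) -> float:
        d = self.positions[-1] - self.positions[0]
        return float(np.hypot(*d))


@dataclass(frozen=True)
class MigrationMetrics:
    speed: float          # µm/min
    persistence: float    # dimensionless, [0, 1]; NaN if path length is 0


@dataclass(frozen=True)
class SpheroidMeasurement:
    condition: str
    replicate: int
    area_day1: float  # µm²
    area_day5: float  # µm²

    def __post_init__(self) -> None:
        if self.area_day1 <= 0 or self.area_day5 <= 0:
            raise ValueError("spheroid areas must be positive")


def speed(traj: Trajectory) -> float:
    """Total path length over elapsed time, µm/min.

    Missing frames simply contribute longer steps between the available
    consecutive samples; elapsed time is last minus first observed time.
    """
    return traj.path_length() / float(traj.times[-1] - traj.times[0])


def persistence(traj: Trajectory) -> float:
    """Net displacement over total path length, in [0, 1].

    A track with zero path length (a cell that never moved) has undefined
    persistence and returns NaN rather than 0.
    """
    total = traj.path_length()
    if total == 0.0:
        return float("nan")
    return min(traj.net_displacement() / total, 1.0)


def migration_metrics(traj: Trajectory) -> MigrationMetrics:
    return MigrationMetrics(speed=speed(traj), persistence=persistence(traj))


def fold_change(m: SpheroidMeasurement) -> float:
    """Day-5 area over day-1 area."""
    return m.area_day5 / m.area_day1


def metrics_table(trajectories: dict[str, list[Trajectory]]) -> pd.DataFrame:
    """Per-cell migration metrics, one row per track of >= 3 points."""
    rows = []
    for condition, trajs in trajectories.items():
        for tr in trajs:
            if len(tr.times) < MIN_TRACK_POINTS:
                continue
            rows.append((condition, tr.cell_id, speed(tr), persistence(tr)))
    return pd.DataFrame(rows, columns=["condition", "cell_id", "speed", "persistence"])


def spheroid_table(spheroids: dict[str, list[SpheroidMeasurement]]) -> pd.DataFrame:
    """Per-replicate fold changes."""
    rows = [
        (s.condition, s.replicate, s.area_day1, s.area_day5, fold_change(s))
        for sph in spheroids.values()
        for s in sph
    ]
    return pd.DataFrame(
        rows,
        columns=["condition", "replicate", "area_day1_um2", "area_day5_um2", "fold_change"],
    )


def read_trajectories(path: str | Path) -> dict[str, list[Trajectory]]:
    """Read a `condition,cell_id,t_min,x_um,y_um` CSV into trajectories."""
    df = pd.read_csv(path)
    out: dict[str, list[Trajectory]] = {}
    for (cond, cid), g in df.groupby(["condition", "cell_id"], sort=False):
        g = g.sort_values("t_min")
        out.setdefault(str(cond), []).append(
            Trajectory(
                cell_id=str(cid),
                times=g["t_min"].to_numpy(),
                positions=g[["x_um", "y_um"]].to_numpy(),
            )
        )
    return out


def read_spheroids(path: str | Path) -> dict[str, list[SpheroidMeasurement]]:
    """Read a `condition,replicate,area_day1_um2,area_day5_um2` CSV."""
    df = pd.read_csv(path)
    out: dict[str, list[SpheroidMeasurement]] = {}
    for row in df.itertuples(index=False):
        m = SpheroidMeasurement(
            condition=str(row.condition),
            replicate=int(row.replicate),
            area_day1=float(row.area_day1_um2),
            area_day5=float(row.area_day5_um2),
        )
        out.setdefault(m.condition, []).append(m)
    return out
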