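"""Reading fix tables, release-site coordinates and trajectory resampling."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO

import numpy as np
import pandas as pd

from beesearch.geometry import Point

logger = logging.getLogger(__name__)

FIX_COLUMNS = ["bee_id", "group", "t_s", "x_m", "y_m"]


@dataclass(frozen=True)
class Fix:
    """One radar position estimate: time since release (s) and location."""

    t: float
    p: Point

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError("fix time must be ≥ 0")


@dataclass
class Trajectory:
    """Time-ordered fixes of one bee, in release-site coordinates.

    ``t``, ``x`` and ``y`` are parallel numpy arrays; ``t`` is strictly
    increasing.
    """

    bee_id: str
    group: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError(f"bee {self.bee_id!r}: timestamps must be strictly increasing")

    @property
    def n_fixes(self) -> int:
        return len(self.t)

    def fixes(self) -> list[Fix]:
        return [Fix(float(t), Point(float(x), float(y))) for t, x, y in zip(self.t, self.x, self.y)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bee_id": self.bee_id,
                "group": self.group,
                "t_s": self.t,
                "x_m": self.x,
                "y_m": self.y,
            }
        )


@dataclass
class Cohort:
    """A labeled collection of trajectories (one per bee)."""

    trajectories: list[Trajectory] = field(default_factory=list)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for tr in self.trajectories:
            seen.setdefault(tr.group, None)
        return list(seen)

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    def by_group(self, group: str) -> list[Trajectory]:
        return [tr for tr in self.trajectories if tr.group == group]

    def counts(self) -> pd.DataFrame:
        """Per group: number of bees (N) and total number of fixes (n)."""
        rows = []
        for g in self.groups:
            trs = self.by_group(g)
            rows.append({"group": g, "N": len(trs), "n": sum(tr.n_fixes for tr in trs)})
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        if not self.trajectories:
            return pd.DataFrame(columns=FIX_COLUMNS)
        return pd.concat([tr.to_frame() for tr in self.trajectories], ignore_index=True)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_fixes(source: str | Path | IO | pd.DataFrame, origin: Point = Point(0.0, 0.0)) -> Cohort:
    """Read a per-bee fix table into a cohort of trajectories.

    Expects columns ``bee_id, group, t_s, x_m, y_m``.  Coordinates are
    shifted by ``origin`` — the release site's coordinates in the input
    frame — so that the release site becomes (0, 0).  Bees whose
    timestamps are not strictly increasing are rejected with a warning.
    """
    df = source.copy() if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    missing = [c for c in FIX_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"fix table is missing columns: {missing}")
    trajectories: list[Trajectory] = []
    for (bee_id, group), sub in df.groupby(["bee_id", "group"], sort=False):
        sub = sub.sort_values("t_s", kind="stable")
        t = sub["t_s"].to_numpy(float)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            logger.warning("bee %r rejected: non-monotone or duplicate timestamps", bee_id)
            continue
        trajectories.append(
            Trajectory(
                bee_id=str(bee_id),
                group=str(group),
                t=t,
                x=sub["x_m"].to_numpy(float) - origin.x,
                y=sub["y_m"].to_numpy(float) - origin.y,
            )
        )
    return Cohort(trajectories)


def resample_trajectory(traj: Trajectory, k_extra: int = 10) -> Trajectory:
    """Insert ``k_extra`` equally spaced points (linear in position and
    time) between each consecutive fix pair; original fixes are kept.

    Output size is n + (n − 1)·k_extra.
    """
    n = traj.n_fixes
    if n < 2:
        raise ValueError("resampling needs at least 2 fixes")
    if k_extra < 0:
        raise ValueError("k_extra must be ≥ 0")
    # fractions 0, 1/(k+1), ..., k/(k+1) per segment, plus the final fix
    frac = np.arange(k_extra + 1) / (k_extra + 1)
    seg_t = traj.t[:-1, None] + frac[None, :] * np.diff(traj.t)[:, None]
    seg_x = traj.x[:-1, None] + frac[None, :] * np.diff(traj.x)[:, None]
    seg_y = traj.y[:-1, None] + frac[None, :] * np.diff(traj.y)[:, None]
    t = np.append(seg_t.ravel(), traj.t[-1])
    x = np.append(seg_x.ravel(), traj.x[-1])
    y = np.append(seg_y.ravel(), traj.y[-1])
    return Trajectory(traj.bee_id, traj.group, t, x, y)


def resample_cohort(cohort: Cohort, k_extra: int = 10) -> Cohort:
    """Resample every trajectory of a cohort (see resample_trajectory)."""
    return Cohort([resample_trajectory(tr, k_extra) for tr in cohort])
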