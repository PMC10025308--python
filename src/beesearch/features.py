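"""Trajectory feature extractors.

Three per-bee summaries of a (resampled) search flight:

* a 16-sector directional profile of time around the release site,
* a spatial occupancy heat map over a 19 × 18 grid of 100-m tiles, and
* edge-proximity features — relative time in distance bands around each
  edge plus the distribution of flight angle relative to the nearest edge.

"Relative time" is the fraction of resampled trajectory points, since
fixes arrive on a near-uniform 3-s cadence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from beesearch.geometry import (
    Landscape,
    WIND_NAMES_16,
    bearing_array,
    nearest_edge_arrays,
    sector_index,
)
from beesearch.preprocess import Cohort, Trajectory

DISTANCE_BOUNDS_M = (10.0, 25.0, 50.0, 75.0, 100.0)
ANGLE_BIN_DEG = 15.0
N_ANGLE_BINS = 6


@dataclass(frozen=True)
class Grid:
    """The occupancy grid: 19 columns (W→E, labels 0–9 then A–I) by
    18 rows (N→S, labels 0–9 then A–H) of 100-m tiles, with tile "99"
    centered at the release site."""

    n_cols: int = 19
    n_rows: int = 18
    tile_m: float = 100.0
    anchor_col: int = 9  # column of the release tile
    anchor_row: int = 9  # row of the release tile

    _LABELS = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"

    @property
    def x_min(self) -> float:
        return -(self.anchor_col + 0.5) * self.tile_m

    @property
    def y_min(self) -> float:
        return -(self.n_rows - self.anchor_row - 0.5) * self.tile_m

    def tile_center(self, col: int, row: int) -> tuple[float, float]:
        return (
            (col - self.anchor_col) * self.tile_m,
            (self.anchor_row - row) * self.tile_m,
        )

    def tile_label(self, col: int, row: int) -> str:
        return self._LABELS[col] + self._LABELS[row]

    def tile_labels(self) -> list[str]:
        """Labels of all tiles in flattening order (row-major, N→S rows)."""
        return [
            self.tile_label(c, r) for r in range(self.n_rows) for c in range(self.n_cols)
        ]

    @property
    def n_tiles(self) -> int:
        return self.n_cols * self.n_rows


@dataclass
class HeatMap:
    """Per-bee spatial occupancy: nonnegative (n_rows × n_cols) matrix
    summing to 1; rows run north→south, columns west→east."""

    values: np.ndarray
    grid: Grid = Grid()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.shape != (self.grid.n_rows, self.grid.n_cols):
            raise ValueError(
                f"heat map must be {self.grid.n_rows}×{self.grid.n_cols}, got {self.values.shape}"
            )
        if np.any(self.values < 0):
            raise ValueError("heat map entries must be nonnegative")

    def flatten(self) -> np.ndarray:
        """Row-major flattening (one row of the predictor matrix X)."""
        return self.values.ravel()


@dataclass
class DirectionalProfile:
    """Fractions of time in each of n angular sectors around the release."""

    freqs: np.ndarray
    sector_names: list[str] = field(default_factory=lambda: list(WIND_NAMES_16))

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, float)


@dataclass
class EdgeFeatureVector:
    """Edge-proximity features of one bee.

    ``time_near[e, r]``: fraction of points whose nearest edge is ``e``
    within distance range ``r``; ``angle_given_zone[e, r, a]``: fraction
    of points in that zone flying at an angle (to the edge) in bin ``a``;
    ``rest``: fraction farther than the last bound from every edge.
    """

    edge_ids: list[str]
    time_near: np.ndarray  # (n_edges, n_ranges)
    angle_given_zone: np.ndarray  # (n_edges, n_ranges, n_angle_bins)
    rest: float
    distance_bounds: tuple[float, ...] = DISTANCE_BOUNDS_M

    def to_vector(self) -> np.ndarray:
        """Flat feature vector: time-near block, angle block, then rest."""
        return np.concatenate(
            [self.time_near.ravel(), self.angle_given_zone.ravel(), [self.rest]]
        )

    def feature_names(self) -> list[str]:
        bounds = (0.0,) + tuple(self.distance_bounds)
        d_names = [f"d{bounds[i]:g}-{bounds[i + 1]:g}" for i in range(len(self.distance_bounds))]
        names = [f"{e}_{d}" for e in self.edge_ids for d in d_names]
        names += [
            f"{e}_{d}_a{int(a * ANGLE_BIN_DEG)}-{int((a + 1) * ANGLE_BIN_DEG)}"
            for e in self.edge_ids
            for d in d_names
            for a in range(N_ANGLE_BINS)
        ]
        names.append("rest")
        return names


def directional_profile(
    traj: Trajectory, n_sectors: int = 16, min_distance_m: float = 1.0
) -> DirectionalProfile:
    """Fraction of trajectory points per angular sector around the release
    site.  Points within ``min_distance_m`` of the release are excluded
    (bearing undefined at the origin)."""
    d = np.hypot(traj.x, traj.y)
    keep = d >= min_distance_m
    if not np.any(keep):
        raise ValueError("all points within 1 m of the release: profile undefined")
    brg = bearing_array(np.zeros(2), traj.x[keep], traj.y[keep])
    idx = sector_index(brg, n_sectors)
    counts = np.bincount(idx, minlength=n_sectors).astype(float)
    names = list(WIND_NAMES_16) if n_sectors == 16 else [f"S{i}" for i in range(n_sectors)]
    return DirectionalProfile(counts / counts.sum(), names)


def normalize_additive(
    profiles: pd.DataFrame | np.ndarray, reference: pd.DataFrame | np.ndarray
) -> pd.DataFrame | np.ndarray:
    """Additively normalize per-bee sector fractions by the reference
    group's per-sector median: 0 means the same probability as the median
    reference bee; values may be negative."""
    ref = np.asarray(reference, float)
    if ref.size == 0:
        raise ValueError("reference profiles are empty")
    med = np.median(ref, axis=0)
    if isinstance(profiles, pd.DataFrame):
        return profiles - med
    return np.asarray(profiles, float) - med


def build_heatmap(traj: Trajectory, grid: Grid = Grid(), half_width_m: float = 50.0) -> HeatMap:
    """Spatial occupancy heat map of one (resampled) trajectory.

    Each point contributes mass 1/n spread uniformly over the axis-aligned
    square of half-width ``half_width_m`` around it; per-tile mass is the
    exact area overlap of that square with the tile.  Mass falling off the
    grid is dropped and the map renormalized to sum to 1.
    """
    n = traj.n_fixes
    if n == 0:
        raise ValueError("cannot build a heat map from an empty trajectory")
    tm = grid.tile_m
    x = traj.x
    y = traj.y
    flat = np.zeros(grid.n_rows * grid.n_cols)
    if half_width_m == 0.0:
        c = np.floor((x - grid.x_min) / tm).astype(int)
        rr = np.floor((y - grid.y_min) / tm).astype(int)
        r = grid.n_rows - 1 - rr
        ok = (c >= 0) & (c < grid.n_cols) & (r >= 0) & (r < grid.n_rows)
        flat += np.bincount(
            r[ok] * grid.n_cols + c[ok], minlength=flat.size
        ) / n
    else:
        hw = half_width_m
        area = (2.0 * hw) ** 2
        c0 = np.floor((x - hw - grid.x_min) / tm).astype(int)
        r0 = np.floor((y - hw - grid.y_min) / tm).astype(int)
        span = int(np.ceil(2.0 * hw / tm)) + 1
        for jc in range(span):
            c = c0 + jc
            lox = grid.x_min + c * tm
            wx = np.minimum(x + hw, lox + tm) - np.maximum(x - hw, lox)
            wx = np.clip(wx, 0.0, None)
            for jr in range(span):
                rr = r0 + jr
                loy = grid.y_min + rr * tm
                wy = np.minimum(y + hw, loy + tm) - np.maximum(y - hw, loy)
                wy = np.clip(wy, 0.0, None)
                r = grid.n_rows - 1 - rr
                ok = (c >= 0) & (c < grid.n_cols) & (r >= 0) & (r < grid.n_rows)
                w = wx * wy / (area * n)
                flat += np.bincount(
                    r[ok] * grid.n_cols + c[ok], weights=w[ok], minlength=flat.size
                )
    H = flat.reshape(grid.n_rows, grid.n_cols)
    total = H.sum()
    if total <= 0:
        raise ValueError("all trajectory mass falls outside the grid")
    return HeatMap(H / total, grid)


def _flight_directions(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-point flight direction vectors (central differences, one-sided
    at the ends).  Zero-displacement points inherit the last defined
    direction; returns (directions (n, 2), defined mask)."""
    n = len(x)
    dx = np.empty(n)
    dy = np.empty(n)
    dx[1:-1] = x[2:] - x[:-2]
    dy[1:-1] = y[2:] - y[:-2]
    dx[0], dy[0] = x[1] - x[0], y[1] - y[0]
    dx[-1], dy[-1] = x[-1] - x[-2], y[-1] - y[-2]
    norm = np.hypot(dx, dy)
    defined = norm > 0
    if not defined.all():
        # carry forward the last defined heading
        idx = np.where(defined, np.arange(n), -1)
        idx = np.maximum.accumulate(idx)
        has = idx >= 0
        src = idx[has]
        dx[has], dy[has] = dx[src], dy[src]
        defined = has & (np.hypot(dx, dy) > 0)
    return np.column_stack([dx, dy]), defined


def edge_features(
    traj: Trajectory,
    landscape: Landscape,
    distance_bounds_m: tuple[float, ...] = DISTANCE_BOUNDS_M,
    n_angle_bins: int = N_ANGLE_BINS,
) -> EdgeFeatureVector:
    """Edge-proximity and flight-angle features of one (resampled)
    trajectory.

    Each point is assigned to its nearest edge and a half-open distance
    range ([0,10), [10,25), [25,50), [50,75), [75,100) m by default), or
    to "rest" beyond the last bound.  The flight angle relative to the
    nearest polyline segment, folded into [0°, 90°], is binned in
    ``n_angle_bins`` equal ranges.
    """
    n = traj.n_fixes
    if n < 2:
        raise ValueError("edge features need at least 2 points (flight direction)")
    edge_ids = landscape.edge_ids()
    n_edges = len(edge_ids)
    n_ranges = len(distance_bounds_m)
    time_near = np.zeros((n_edges, n_ranges))
    angle_given_zone = np.zeros((n_edges, n_ranges, n_angle_bins))
    if n_edges == 0:
        return EdgeFeatureVector([], time_near, angle_given_zone, 1.0, tuple(distance_bounds_m))

    ei, dist, seg = nearest_edge_arrays(traj.x, traj.y, landscape)
    rbin = np.digitize(dist, distance_bounds_m)  # 0..n_ranges; n_ranges = rest
    near = rbin < n_ranges
    rest = float(np.count_nonzero(~near)) / n
    np.add.at(time_near, (ei[near], rbin[near]), 1.0 / n)

    dirs, defined = _flight_directions(traj.x, traj.y)
    # local direction of the nearest polyline segment per point
    seg_vecs = np.empty((n, 2))
    for j, e in enumerate(landscape.edges):
        m = ei == j
        if not np.any(m):
            continue
        v = e.vertex_array()
        sv = v[1:] - v[:-1]
        seg_vecs[m] = sv[seg[m]]
    sel = near & defined
    if np.any(sel):
        d = dirs[sel]
        s = seg_vecs[sel]
        cosang = np.abs(np.einsum("ij,ij->i", d, s)) / (
            np.hypot(d[:, 0], d[:, 1]) * np.hypot(s[:, 0], s[:, 1])
        )
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))  # [0, 90]
        bin_w = 90.0 / n_angle_bins
        abin = np.minimum((ang / bin_w).astype(int), n_angle_bins - 1)
        np.add.at(angle_given_zone, (ei[sel], rbin[sel], abin), 1.0 / n)
    return EdgeFeatureVector(edge_ids, time_near, angle_given_zone, rest, tuple(distance_bounds_m))


# ---------------------------------------------------------------------------
# Cohort-level feature matrices


def _cohort_matrix(cohort: Cohort, rows: list[np.ndarray], columns: list[str]) -> tuple[pd.DataFrame, pd.Series]:
    ids = [tr.bee_id for tr in cohort]
    X = pd.DataFrame(np.vstack(rows), index=ids, columns=columns)
    groups = pd.Series([tr.group for tr in cohort], index=ids, name="group")
    return X, groups


def directional_matrix(cohort: Cohort, n_sectors: int = 16) -> tuple[pd.DataFrame, pd.Series]:
    """Per-bee directional profiles as a (bees × sectors) DataFrame plus
    the group labels."""
    profs = [directional_profile(tr, n_sectors) for tr in cohort]
    return _cohort_matrix(cohort, [p.freqs for p in profs], profs[0].sector_names)


def heatmap_matrix(
    cohort: Cohort, grid: Grid = Grid(), half_width_m: float = 50.0
) -> tuple[pd.DataFrame, pd.Series]:
    """Flattened per-bee heat maps: the (bees × tiles) predictor matrix X."""
    maps = [build_heatmap(tr, grid, half_width_m) for tr in cohort]
    return _cohort_matrix(cohort, [m.flatten() for m in maps], grid.tile_labels())


def edge_feature_matrix(
    cohort: Cohort,
    landscape: Landscape,
    distance_bounds_m: tuple[float, ...] = DISTANCE_BOUNDS_M,
    n_angle_bins: int = N_ANGLE_BINS,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-bee edge feature vectors (time-near + angle blocks + rest)."""
    vecs = [edge_features(tr, landscape, distance_bounds_m, n_angle_bins) for tr in cohort]
    return _cohort_matrix(cohort, [v.to_vector() for v in vecs], vecs[0].feature_names())
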