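"""Geometric substrate: compass conventions, sectors, edges and radar visibility.

All coordinates are Cartesian meters relative to the release site
(x east, y north).  Bearings follow the compass convention: degrees
clockwise from north, so 0° = N, 90° = E.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

WIND_NAMES_16 = [
    "N", "NNE", "NE", "ENE", "E", "ESE", "SE", "SSE",
    "S", "SSW", "SW", "WSW", "W", "WNW", "NW", "NNW",
]


@dataclass(frozen=True)
class Point:
    """A location in release-site coordinates (meters east / north)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("Point coordinates must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class Edge:
    """An elongated ground structure (irrigation channel, borderline, bushes)
    represented as a polyline of ≥ 2 vertices."""

    id: str
    vertices: tuple[Point, ...]

    def __post_init__(self) -> None:
        if len(self.vertices) < 2:
            raise ValueError(f"edge {self.id!r} needs at least 2 vertices")
        arr = self.vertex_array()
        seg = np.diff(arr, axis=0)
        if np.any(np.hypot(seg[:, 0], seg[:, 1]) == 0.0):
            raise ValueError(f"edge {self.id!r} has coincident consecutive vertices")

    def vertex_array(self) -> np.ndarray:
        return np.array([[p.x, p.y] for p in self.vertices], dtype=float)


@dataclass(frozen=True)
class RadarSpec:
    """Harmonic radar position, range and blanking sector.

    The blanking sector is the unscanned wedge, swept clockwise from
    ``blank_from_deg`` to ``blank_to_deg`` (compass bearings seen from the
    radar).  The default is a 150°-wide sector centered on SW.
    """

    position: Point = Point(-38.0, -162.0)
    range_m: float = 900.0
    blank_from_deg: float = 150.0
    blank_to_deg: float = 300.0

    def __post_init__(self) -> None:
        if self.range_m <= 0:
            raise ValueError("radar range must be positive")
        if self.blank_width_deg <= 0 or self.blank_width_deg >= 360:
            raise ValueError("blanking sector width must lie in (0°, 360°)")

    @property
    def blank_width_deg(self) -> float:
        return (self.blank_to_deg - self.blank_from_deg) % 360.0

    @property
    def scanned_width_deg(self) -> float:
        return 360.0 - self.blank_width_deg


@dataclass(frozen=True)
class Landscape:
    """Edges, radar and release site of one study area.

    The release site is the coordinate origin by convention.
    """

    edges: tuple[Edge, ...] = ()
    radar: RadarSpec = RadarSpec()
    release: Point = Point(0.0, 0.0)

    def __post_init__(self) -> None:
        if (self.release.x, self.release.y) != (0.0, 0.0):
            raise ValueError("release site must be the origin (0, 0)")
        ids = [e.id for e in self.edges]
        if len(set(ids)) != len(ids):
            raise ValueError("edge ids must be unique")

    def edge_ids(self) -> list[str]:
        return [e.id for e in self.edges]


def bearing(origin: Point | Sequence[float], target: Point | Sequence[float]) -> float:
    """Compass bearing from origin to target, degrees in [0, 360)."""
    ox, oy = (origin.x, origin.y) if isinstance(origin, Point) else origin
    tx, ty = (target.x, target.y) if isinstance(target, Point) else target
    dx, dy = tx - ox, ty - oy
    if dx == 0.0 and dy == 0.0:
        raise ValueError("bearing undefined for coincident points")
    return float(np.degrees(np.arctan2(dx, dy)) % 360.0)


def bearing_array(origin: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Vectorized compass bearings from one origin to many points (degrees)."""
    return np.degrees(np.arctan2(xs - origin[0], ys - origin[1])) % 360.0


def sector_index(bearing_deg: float | np.ndarray, n_sectors: int = 16) -> int | np.ndarray:
    """Index of the compass sector containing a bearing.

    Sector 0 is centered on north: with width w = 360/n it spans
    [360 − w/2, 360) ∪ [0, w/2); sectors are half-open and ordered
    clockwise (N, NNE, NE, … for n = 16).
    """
    if n_sectors < 2:
        raise ValueError("need at least 2 sectors")
    w = 360.0 / n_sectors
    idx = np.floor(((np.asarray(bearing_deg) + w / 2.0) % 360.0) / w).astype(int)
    # guard against float roundoff at the upper wrap
    idx = np.where(idx == n_sectors, 0, idx)
    if np.isscalar(bearing_deg):
        return int(idx)
    return idx


def _segment_distances(xs: np.ndarray, ys: np.ndarray, verts: np.ndarray) -> np.ndarray:
    """Distances from points (xs, ys) to each segment of a polyline.

    Returns an (n_points, n_segments) array.
    """
    a = verts[:-1]  # (s, 2)
    b = verts[1:]
    ab = b - a
    ab2 = np.einsum("ij,ij->i", ab, ab)  # squared segment lengths, > 0
    px = xs[:, None] - a[None, :, 0]
    py = ys[:, None] - a[None, :, 1]
    t = (px * ab[None, :, 0] + py * ab[None, :, 1]) / ab2[None, :]
    t = np.clip(t, 0.0, 1.0)
    cx = px - t * ab[None, :, 0]
    cy = py - t * ab[None, :, 1]
    return np.hypot(cx, cy)


def polyline_distances(xs: np.ndarray, ys: np.ndarray, edge: Edge) -> np.ndarray:
    """Minimum distance from each point to a polyline edge (vectorized)."""
    d = _segment_distances(np.asarray(xs, float), np.asarray(ys, float), edge.vertex_array())
    return d.min(axis=1)


def polyline_nearest_segment(xs: np.ndarray, ys: np.ndarray, edge: Edge) -> tuple[np.ndarray, np.ndarray]:
    """Per point: (min distance, index of the nearest segment) for one edge."""
    d = _segment_distances(np.asarray(xs, float), np.asarray(ys, float), edge.vertex_array())
    seg = d.argmin(axis=1)
    return d[np.arange(d.shape[0]), seg], seg


def point_to_edge_distance(p: Point, e: Edge) -> float:
    """Minimum Euclidean distance from a point to a polyline edge (meters)."""
    return float(polyline_distances(np.array([p.x]), np.array([p.y]), e)[0])


def nearest_edge(p: Point, landscape: Landscape) -> tuple[str, float]:
    """Closest edge (by Euclidean distance) to a point; ties go to the
    lowest-index edge."""
    if not landscape.edges:
        raise ValueError("landscape has no edges")
    dists = [point_to_edge_distance(p, e) for e in landscape.edges]
    i = int(np.argmin(dists))  # argmin returns the first minimum: tie-break rule
    return landscape.edges[i].id, float(dists[i])


def nearest_edge_arrays(
    xs: np.ndarray, ys: np.ndarray, landscape: Landscape
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized nearest-edge assignment.

    Returns (edge index, distance, nearest segment index on that edge)
    per point.  Ties break to the lowest edge index.
    """
    if not landscape.edges:
        raise ValueError("landscape has no edges")
    n = len(xs)
    dmat = np.empty((n, len(landscape.edges)))
    segs = np.empty((n, len(landscape.edges)), dtype=int)
    for j, e in enumerate(landscape.edges):
        dj, sj = polyline_nearest_segment(xs, ys, e)
        dmat[:, j] = dj
        segs[:, j] = sj
    ei = dmat.argmin(axis=1)
    rows = np.arange(n)
    return ei, dmat[rows, ei], segs[rows, ei]


def _in_blanking(bearing_deg: np.ndarray, radar: RadarSpec) -> np.ndarray:
    lo, hi = radar.blank_from_deg % 360.0, radar.blank_to_deg % 360.0
    b = np.asarray(bearing_deg) % 360.0
    if lo <= hi:
        return (b >= lo) & (b < hi)
    return (b >= lo) | (b < hi)


def is_scanned(p: Point | tuple[float, float], radar: RadarSpec) -> bool:
    """Whether a point is visible to the radar (within range and outside
    the blanking sector).  The radar position itself counts as scanned."""
    x, y = (p.x, p.y) if isinstance(p, Point) else p
    return bool(is_scanned_arrays(np.array([x]), np.array([y]), radar)[0])


def is_scanned_arrays(xs: np.ndarray, ys: np.ndarray, radar: RadarSpec) -> np.ndarray:
    """Vectorized radar visibility mask."""
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    dx = xs - radar.position.x
    dy = ys - radar.position.y
    dist = np.hypot(dx, dy)
    at_radar = dist == 0.0
    with np.errstate(invalid="ignore"):
        brg = np.degrees(np.arctan2(dx, dy)) % 360.0
    visible = (dist <= radar.range_m) & ~_in_blanking(brg, radar)
    return visible | at_radar


# ---------------------------------------------------------------------------
# Landscape (de)serialization


def landscape_to_dict(ls: Landscape) -> dict:
    return {
        "release": [ls.release.x, ls.release.y],
        "radar": {
            "position": [ls.radar.position.x, ls.radar.position.y],
            "range_m": ls.radar.range_m,
            "blank_from_deg": ls.radar.blank_from_deg,
            "blank_to_deg": ls.radar.blank_to_deg,
        },
        "edges": [
            {"id": e.id, "vertices": [[p.x, p.y] for p in e.vertices]} for e in ls.edges
        ],
    }


def landscape_from_dict(d: dict) -> Landscape:
    radar_d = d.get("radar", {})
    defaults = RadarSpec()
    pos = radar_d.get("position", [defaults.position.x, defaults.position.y])
    radar = RadarSpec(
        position=Point(*map(float, pos)),
        range_m=float(radar_d.get("range_m", defaults.range_m)),
        blank_from_deg=float(radar_d.get("blank_from_deg", defaults.blank_from_deg)),
        blank_to_deg=float(radar_d.get("blank_to_deg", defaults.blank_to_deg)),
    )
    edges = tuple(
        Edge(str(e["id"]), tuple(Point(float(x), float(y)) for x, y in e["vertices"]))
        for e in d.get("edges", [])
    )
    release = Point(*map(float, d.get("release", [0.0, 0.0])))
    return Landscape(edges=edges, radar=radar, release=release)


def write_landscape(ls: Landscape, path: str | Path) -> None:
    """Write a landscape to YAML (or JSON if the suffix is .json)."""
    path = Path(path)
    d = landscape_to_dict(ls)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def read_landscape(path: str | Path) -> Landscape:
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return landscape_from_dict(d)
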