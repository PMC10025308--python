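"""Looping random-search flight simulator for a central-place forager.

The null model emulates a bee released at an unfamiliar site: it flies
unit-length steps whose heading increments are the arctangent of Gaussian
noise passed through a low-pass Butterworth filter, and it is folded back
toward the release site whenever it strays beyond an excursion envelope
that grows with the loop index k (threshold 1 + k/10 unit lengths), or
re-enters an inner disk of 0.1 unit lengths around the release.  The raw
path is smoothed with a centered moving average and scaled to meters.

Model S keeps all fixes; Model R is the same path restricted to the
radar-scanned sector.  A biased variant steers headings toward (or at a
preferred angle to) a chosen edge, providing synthetic cohorts with a
known, tunable edge-guidance effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, lfilter

from beesearch.geometry import Landscape, RadarSpec, is_scanned_arrays
from beesearch.preprocess import Cohort, Trajectory

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class SimulatorConfig:
    """Parameters of the random-search null model.

    Defaults are the study conditions: 10 000 unit steps, heading noise
    sd 0.25, 10th-order Butterworth filter with normalized cutoff 0.05,
    excursion threshold 1 + k/10 unit lengths, inner radius 0.1, moving
    average window 25, unit length 2.22 m, one fix per 3 s.
    """

    n_steps: int = 10_000
    heading_noise_sd: float = 0.25
    filter_order: int = 10
    filter_cutoff: float = 0.05
    loop_growth: float = 0.1
    inner_radius: float = 0.1
    smooth_window: int = 25
    unit_length_m: float = 2.22
    sample_period_s: float = 3.0
    seed: int | None = None
    fold_mode: str = "persistent"  # "persistent": 180° at every step in the zone; "event": once per crossing
    loop_increment: str = "outer"  # advance k at "outer" fold events or at "inner"-disk returns

    def __post_init__(self) -> None:
        if min(self.n_steps, self.filter_order, self.smooth_window) < 1:
            raise ValueError("counts must be ≥ 1")
        if self.unit_length_m <= 0:
            raise ValueError("unit length must be positive")
        if not 0.0 < self.filter_cutoff < 1.0:
            raise ValueError("normalized filter cutoff must lie in (0, 1)")
        if self.fold_mode not in ("event", "persistent"):
            raise ValueError("fold_mode must be 'event' or 'persistent'")
        if self.loop_increment not in ("outer", "inner"):
            raise ValueError("loop_increment must be 'outer' or 'inner'")


@dataclass(frozen=True)
class BiasConfig:
    """Synthetic edge-guidance bias.

    ``attraction_weight`` blends each heading increment toward the bearing
    of the nearest point of ``target_edge`` (weight 0 reproduces the
    unbiased model bitwise).  If ``preferred_angle_deg`` is set, the bee
    instead steers toward the heading that makes that (acute) angle with
    the local edge direction.
    """

    target_edge: str | None = None
    attraction_weight: float = 0.0
    preferred_angle_deg: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.attraction_weight <= 1.0:
            raise ValueError("attraction weight must lie in [0, 1]")
        if self.preferred_angle_deg is not None and not 0.0 <= self.preferred_angle_deg <= 90.0:
            raise ValueError("preferred angle must lie in [0°, 90°]")


@dataclass(frozen=True)
class GroupSpec:
    """One group of a synthetic cohort."""

    label: str
    n_bees: int
    config: SimulatorConfig = SimulatorConfig()
    bias: BiasConfig | None = None
    radar_masked: bool = False

    def __post_init__(self) -> None:
        if self.n_bees < 1:
            raise ValueError("each group needs at least one bee")


def _wrap(angle: float) -> float:
    """Wrap an angle difference into (−π, π]."""
    return (angle + math.pi) % TWO_PI - math.pi


class _EdgeSteer:
    """Per-step steering target for a biased bee (scalar math: called
    once per simulation step)."""

    def __init__(self, bias: BiasConfig, landscape: Landscape, unit_length_m: float):
        ids = landscape.edge_ids()
        if bias.target_edge not in ids:
            raise ValueError(f"unknown target edge {bias.target_edge!r}; landscape has {ids}")
        edge = landscape.edges[ids.index(bias.target_edge)]
        v = edge.vertex_array()
        self.ax = v[:-1, 0].tolist()
        self.ay = v[:-1, 1].tolist()
        dx = (v[1:, 0] - v[:-1, 0]).tolist()
        dy = (v[1:, 1] - v[:-1, 1]).tolist()
        self.dx, self.dy = dx, dy
        self.len2 = [ddx * ddx + ddy * ddy for ddx, ddy in zip(dx, dy)]
        # compass direction (radians) of each segment
        self.seg_dir = [math.atan2(ddx, ddy) for ddx, ddy in zip(dx, dy)]
        self.u = unit_length_m
        self.preferred = (
            math.radians(bias.preferred_angle_deg) if bias.preferred_angle_deg is not None else None
        )

    def target_heading(self, x_u: float, y_u: float, heading: float) -> float | None:
        """Steering heading given position (unit lengths) and current heading."""
        px, py = x_u * self.u, y_u * self.u
        best_d2 = math.inf
        best = 0
        qx = qy = 0.0
        for i in range(len(self.ax)):
            t = ((px - self.ax[i]) * self.dx[i] + (py - self.ay[i]) * self.dy[i]) / self.len2[i]
            t = 0.0 if t < 0.0 else (1.0 if t > 1.0 else t)
            cx = self.ax[i] + t * self.dx[i]
            cy = self.ay[i] + t * self.dy[i]
            d2 = (px - cx) ** 2 + (py - cy) ** 2
            if d2 < best_d2:
                best_d2, best, qx, qy = d2, i, cx, cy
        if self.preferred is None:
            if best_d2 == 0.0:
                return None  # on the edge: attraction bearing undefined
            return math.atan2(qx - px, qy - py)
        base = self.seg_dir[best]
        pa = self.preferred
        candidates = (base + pa, base - pa, base + math.pi + pa, base + math.pi - pa)
        return min(candidates, key=lambda c: abs(_wrap(c - heading)))


def _filtered_increments(config: SimulatorConfig, rng: np.random.Generator) -> tuple[float, np.ndarray]:
    """Initial heading and the filtered per-step heading increments (radians)."""
    heading0 = rng.uniform(0.0, TWO_PI)
    raw = np.arctan(rng.normal(0.0, config.heading_noise_sd, config.n_steps))
    b, a = butter(config.filter_order, config.filter_cutoff)
    # forward-only filtering, zero initial conditions
    return heading0, lfilter(b, a, raw)


def simulate_raw(
    config: SimulatorConfig,
    seed: int | np.random.Generator | None = None,
    bias: BiasConfig | None = None,
    landscape: Landscape | None = None,
) -> tuple[np.ndarray, dict]:
    """Integrate the raw unit-length path (pre-smoothing, unit lengths).

    Returns an (n_steps + 1, 2) position array starting at the origin and
    an info dict with the number of inner-disk returns and the final loop
    index k.  Under the default semantics the 180° fold-back applies at
    every step spent beyond the outer threshold (or inside the inner
    disk), and k — which grows the excursion envelope 1 + k/10 — advances
    at each outer fold, so the envelope ratchets outward loop by loop and
    the walker can never escape it.  ``fold_mode="event"`` instead fires
    once per boundary crossing (re-arming on leaving the zone) and
    ``loop_increment="inner"`` advances k at inner-disk returns; that
    reading produces occasional boundary-trap escapes and heavy-tailed
    ranges, and is kept for sensitivity analysis.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        config.seed if seed is None else seed
    )
    heading0, incs = _filtered_increments(config, rng)

    steer = None
    weight = 0.0
    if bias is not None and bias.attraction_weight > 0.0:
        if bias.target_edge is None:
            raise ValueError("bias with positive weight needs a target edge")
        if landscape is None:
            raise ValueError("biased simulation needs a landscape")
        steer = _EdgeSteer(bias, landscape, config.unit_length_m)
        weight = bias.attraction_weight

    n = config.n_steps
    xs = np.empty(n + 1)
    ys = np.empty(n + 1)
    xs[0] = ys[0] = 0.0
    x = y = 0.0
    h = heading0
    k = 1
    inner_r = config.inner_radius
    growth = config.loop_growth
    outer_armed = True
    inner_armed = False  # the walker starts inside the inner disk
    persistent = config.fold_mode == "persistent"
    k_at_outer = config.loop_increment == "outer"
    returns = 0
    inc_list = incs.tolist()
    for i in range(n):
        dh = inc_list[i]
        if steer is not None:
            tgt = steer.target_heading(x, y, h)
            if tgt is not None:
                dh += weight * _wrap(tgt - h)
        h += dh
        x += math.sin(h)
        y += math.cos(h)
        xs[i + 1] = x
        ys[i + 1] = y
        d = math.hypot(x, y)
        outer = 1.0 + k * growth
        if d > outer:
            if outer_armed or persistent:
                h += math.pi
                outer_armed = False
                if k_at_outer:
                    k += 1
        else:
            outer_armed = True
        if d < inner_r:
            if inner_armed or persistent:
                if inner_armed:
                    returns += 1
                    if not k_at_outer:
                        k += 1
                h += math.pi
                inner_armed = False
        else:
            inner_armed = True
    return np.column_stack([xs, ys]), {"inner_returns": returns, "loop_index": k}


def _moving_average(a: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with window truncation at both ends."""
    kernel = np.ones(window)
    num = np.convolve(a, kernel, mode="same")
    den = np.convolve(np.ones(len(a)), kernel, mode="same")
    return num / den


def _finish_trajectory(
    raw_units: np.ndarray, config: SimulatorConfig, bee_id: str, group: str
) -> Trajectory:
    sx = _moving_average(raw_units[:, 0], config.smooth_window) * config.unit_length_m
    sy = _moving_average(raw_units[:, 1], config.smooth_window) * config.unit_length_m
    # anchor the smoothed path at the release site
    sx -= sx[0]
    sy -= sy[0]
    t = np.arange(len(sx)) * config.sample_period_s
    return Trajectory(bee_id, group, t, sx, sy)


def simulate_random_bee(
    config: SimulatorConfig,
    landscape: Landscape | None = None,
    bee_id: str = "S01",
    group: str = "S",
    seed: int | np.random.Generator | None = None,
) -> Trajectory:
    """Simulate one unbiased random-search flight (Model S).

    The path is independent of the landscape; the argument exists only
    for interface symmetry with the biased variant.  Deterministic given
    the seed.
    """
    raw, _ = simulate_raw(config, seed=seed)
    return _finish_trajectory(raw, config, bee_id, group)


def simulate_biased_bee(
    config: SimulatorConfig,
    bias: BiasConfig,
    landscape: Landscape,
    bee_id: str = "B01",
    group: str = "B",
    seed: int | np.random.Generator | None = None,
) -> Trajectory:
    """Simulate a flight steered toward (or at a preferred angle to) an
    edge; weight 0 reproduces the unbiased model under the same seed."""
    if bias.attraction_weight > 0.0 and bias.target_edge is not None:
        ids = landscape.edge_ids()
        if bias.target_edge not in ids:
            raise ValueError(f"unknown target edge {bias.target_edge!r}; landscape has {ids}")
    raw, _ = simulate_raw(config, seed=seed, bias=bias, landscape=landscape)
    return _finish_trajectory(raw, config, bee_id, group)


def apply_radar_mask(traj: Trajectory, radar: RadarSpec) -> Trajectory:
    """Restrict a trajectory to radar-visible fixes (Model R): same path,
    fixes in the blanking sector or beyond range removed, timestamps kept."""
    keep = is_scanned_arrays(traj.x, traj.y, radar)
    return Trajectory(traj.bee_id, traj.group, traj.t[keep], traj.x[keep], traj.y[keep])


def _bee_rng(master_seed: int, group_index: int, bee_index: int) -> np.random.Generator:
    # splittable per-bee stream: independent of generation order
    return np.random.default_rng(np.random.SeedSequence([master_seed, group_index, bee_index]))


def generate_cohort(
    spec: list[GroupSpec],
    landscape: Landscape,
    seed: int = 0,
) -> Cohort:
    """Generate a labeled multi-group cohort of simulated flights.

    Each bee gets its own RNG stream derived from (seed, group index,
    bee index), so cohorts are reproducible bee-by-bee.
    """
    labels = [g.label for g in spec]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate group labels in cohort spec")
    trajectories: list[Trajectory] = []
    for gi, g in enumerate(spec):
        for bi in range(g.n_bees):
            rng = _bee_rng(seed, gi, bi)
            bee_id = f"{g.label}{bi + 1:02d}"
            if g.bias is not None and g.bias.attraction_weight > 0.0:
                tr = simulate_biased_bee(g.config, g.bias, landscape, bee_id, g.label, seed=rng)
            else:
                tr = simulate_random_bee(g.config, landscape, bee_id, g.label, seed=rng)
            if g.radar_masked:
                tr = apply_radar_mask(tr, landscape.radar)
            trajectories.append(tr)
    return Cohort(trajectories)


def calibrate_unit_length(
    reference: Cohort,
    config: SimulatorConfig,
    n_sim: int = 200,
    seed: int = 0,
) -> float:
    """Fit the simulator's unit length so the median distance from the
    release site over simulated fixes matches the reference cohort's.

    Distances scale exactly linearly with the unit length (same seeds),
    so a single simulation batch at u = 1 suffices: u = d_ref / m₁.
    """
    if len(reference) == 0 or all(tr.n_fixes == 0 for tr in reference):
        raise ValueError("reference cohort is empty")
    ref_d = np.concatenate([np.hypot(tr.x, tr.y) for tr in reference if tr.n_fixes])
    ref_median = float(np.median(ref_d))
    unit_cfg = replace(config, unit_length_m=1.0)
    sims = []
    for i in range(n_sim):
        rng = _bee_rng(seed, 0, i)
        tr = simulate_random_bee(unit_cfg, seed=rng)
        sims.append(np.hypot(tr.x, tr.y))
    m1 = float(np.median(np.concatenate(sims)))
    return ref_median / m1
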