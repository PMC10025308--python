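"""End-to-end orchestration: simulate/load → preprocess → features →
effect-size discrimination → PLS/SVM embedding, with all artifacts
written as CSV/JSON.  Deterministic given the master seed."""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from beesearch.embedding import (
    fit_pls,
    fit_separatrix,
    group_indicator,
    min_volume_ellipsoid,
    separatrix_in_tile_space,
    signed_distances,
    support_vector_heatmap,
)
from beesearch.features import (
    DISTANCE_BOUNDS_M,
    Grid,
    N_ANGLE_BINS,
    directional_matrix,
    edge_feature_matrix,
    heatmap_matrix,
    normalize_additive,
)
from beesearch.geometry import Edge, Landscape, Point, RadarSpec, landscape_from_dict, read_landscape
from beesearch.preprocess import Cohort, read_fixes, resample_cohort
from beesearch.simulator import BiasConfig, GroupSpec, SimulatorConfig, generate_cohort
from beesearch.stats import pairwise_discrimination, top_discriminants

_version = "0.1.0"

logger = logging.getLogger(__name__)


def _line_through(point: tuple[float, float], bearing_deg: float, half_length_m: float) -> tuple[Point, Point]:
    b = math.radians(bearing_deg)
    dx, dy = math.sin(b), math.cos(b)
    x, y = point
    return (
        Point(x - half_length_m * dx, y - half_length_m * dy),
        Point(x + half_length_m * dx, y + half_length_m * dy),
    )


def make_fixture(kind: str) -> Landscape:
    """Deterministic demo landscapes.

    * ``test-area``: four SW→NE polylines — a borderline through the
      release site (E1), two parallel irrigation channels 611 m apart on
      either side (E2 NW, E3 SE), and a row of bushes 30 m SE of the
      radar (E4).
    * ``two-edge-toy``: two short perpendicular segments crossing at the
      origin, for hand-checkable nearest-edge assignments.
    * ``edgeless``: radar and release only.
    """
    radar = RadarSpec()
    if kind == "test-area":
        half = 1400.0
        sep = 611.0
        # perpendicular offsets toward NW (bearing 315°) and SE (135°)
        off = sep / 2.0 / math.sqrt(2.0)
        bush = (
            radar.position.x + 30.0 / math.sqrt(2.0),
            radar.position.y - 30.0 / math.sqrt(2.0),
        )
        edges = (
            Edge("E1", _line_through((0.0, 0.0), 45.0, half)),
            Edge("E2", _line_through((-off, off), 45.0, half)),
            Edge("E3", _line_through((off, -off), 45.0, half)),
            Edge("E4", _line_through(bush, 45.0, half)),
        )
        return Landscape(edges=edges, radar=radar)
    if kind == "two-edge-toy":
        return Landscape(
            edges=(
                Edge("E1", (Point(-200.0, 0.0), Point(200.0, 0.0))),
                Edge("E2", (Point(0.0, -200.0), Point(0.0, 200.0))),
            ),
            radar=radar,
        )
    if kind == "edgeless":
        return Landscape(edges=(), radar=radar)
    raise ValueError(f"unknown fixture kind {kind!r}")


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    landscape: Landscape | str
    out_dir: str
    seed: int = 0
    cohort_csv: str | None = None
    simulate: list[GroupSpec] = field(default_factory=list)
    k_extra: int = 10
    n_sectors: int = 16
    half_width_m: float = 50.0
    grid: Grid = field(default_factory=Grid)
    distance_bounds_m: tuple[float, ...] = DISTANCE_BOUNDS_M
    n_angle_bins: int = N_ANGLE_BINS
    delta_threshold: float = 0.3
    n_components: int = 3
    reference_group: str | None = None  # additive-normalization reference (default: "R" if present)
    separatrices: list[tuple[list[str], list[str]]] = field(default_factory=list)
    top_k: int = 25

    @staticmethod
    def from_dict(d: dict) -> "RunConfig":
        d = dict(d)
        ls = d["landscape"]
        if isinstance(ls, dict):
            d["landscape"] = landscape_from_dict(ls)
        sims = []
        for g in d.get("simulate", []):
            cfg = SimulatorConfig(**g.get("config", {}))
            bias = BiasConfig(**g["bias"]) if g.get("bias") else None
            sims.append(
                GroupSpec(
                    label=str(g["label"]),
                    n_bees=int(g["n_bees"]),
                    config=cfg,
                    bias=bias,
                    radar_masked=bool(g.get("radar_masked", False)),
                )
            )
        d["simulate"] = sims
        if "grid" in d and isinstance(d["grid"], dict):
            d["grid"] = Grid(**d["grid"])
        if "separatrices" in d:
            d["separatrices"] = [(list(a), list(b)) for a, b in d["separatrices"]]
        if "distance_bounds_m" in d:
            d["distance_bounds_m"] = tuple(d["distance_bounds_m"])
        return RunConfig(**d)

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        return RunConfig.from_dict(yaml.safe_load(Path(path).read_text()))


def _resolve_landscape(config: RunConfig) -> Landscape:
    if isinstance(config.landscape, Landscape):
        return config.landscape
    path = Path(config.landscape)
    if not path.exists():
        raise FileNotFoundError(f"landscape file not found: {path}")
    return read_landscape(path)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


@_stage("cohort")
def _build_cohort(config: RunConfig, landscape: Landscape) -> Cohort:
    trajectories = []
    if config.cohort_csv is not None:
        trajectories.extend(read_fixes(config.cohort_csv).trajectories)
    if config.simulate:
        trajectories.extend(generate_cohort(config.simulate, landscape, seed=config.seed).trajectories)
    if not trajectories:
        raise ValueError("no cohort source: provide cohort_csv and/or simulate specs")
    return Cohort(trajectories)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write artifacts under ``config.out_dir``.

    Returns a report dict (paths, counts, PLS variance, separatrix
    effect sizes).  Idempotent given the seed.
    """
    landscape = _resolve_landscape(config)  # validated before any simulation
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "version": _version}

    cohort = _build_cohort(config, landscape)
    cohort.to_csv(out / "cohort.csv")
    report["groups"] = cohort.groups
    report["counts"] = cohort.counts().to_dict("records")

    resampled = resample_cohort(cohort, config.k_extra)

    # directional analysis
    Xd, groups = directional_matrix(resampled, config.n_sectors)
    ref = config.reference_group or ("R" if "R" in cohort.groups else cohort.groups[0])
    ref_rows = Xd.loc[groups[groups == ref].index]
    Xd_norm = normalize_additive(Xd, ref_rows)
    Xd.assign(group=groups).to_csv(out / "directional_profiles.csv")
    Xd_norm.assign(group=groups).to_csv(out / "directional_profiles_normalized.csv")
    tab_d = pairwise_discrimination(Xd, groups)
    tab_d.table.to_csv(out / "directional_pairwise.csv", index=False)
    tab_d.counts(config.delta_threshold).rename("n_significant").to_csv(out / "directional_pair_counts.csv")
    report["directional_significant"] = int(tab_d.counts(config.delta_threshold).sum())

    # heat maps
    Xh, _ = heatmap_matrix(resampled, config.grid, config.half_width_m)
    Xh.assign(group=groups).to_csv(out / "heatmaps.csv")
    tab_h = pairwise_discrimination(Xh, groups)
    tab_h.counts(config.delta_threshold).rename("n_significant").to_csv(out / "heatmap_pair_counts.csv")

    # edge features
    if landscape.edges:
        Xe, _ = edge_feature_matrix(resampled, landscape, config.distance_bounds_m, config.n_angle_bins)
        Xe.assign(group=groups).to_csv(out / "edge_features.csv")
        tab_e = pairwise_discrimination(Xe.drop(columns=["rest"]), groups)
        tab_e.table.to_csv(out / "edge_pairwise.csv", index=False)
        tops = top_discriminants(tab_e, k=config.top_k)
        tops["top"].to_csv(out / "edge_top_discriminants.csv", index=False)
        tops["per_edge"].to_csv(out / "edge_top_per_edge.csv", index=False)

    # embedding
    model = fit_pls(Xh, group_indicator(groups), config.n_components)
    pd.DataFrame(
        model.scores, index=Xh.index, columns=[f"PLS{i + 1}" for i in range(model.n_components)]
    ).assign(group=groups).to_csv(out / "pls_scores.csv")
    pd.DataFrame(
        model.x_loadings, index=Xh.columns, columns=[f"PLS{i + 1}" for i in range(model.n_components)]
    ).to_csv(out / "pls_loadings.csv")
    report["pls_variance_explained"] = model.variance_explained.tolist()
    report["pls_cumulative_variance"] = model.cumulative_variance.tolist()
    for i in range(model.n_components):
        hv = support_vector_heatmap(model.x_loadings[:, i], config.grid)
        np.savetxt(out / f"pls_support_vector_{i + 1}.csv", hv, delimiter=",")

    ellipsoids = {}
    for g in cohort.groups:
        pts = model.scores[(groups == g).to_numpy()]
        ellipsoids[g] = min_volume_ellipsoid(pts)
    with open(out / "ellipsoids.json", "w") as fh:
        json.dump(
            {
                g: {"center": e.center.tolist(), "shape": e.shape.tolist(), "degenerate": e.degenerate}
                for g, e in ellipsoids.items()
            },
            fh,
            indent=2,
        )

    report["separatrices"] = []
    for si, (side1, side2) in enumerate(config.separatrices):
        sep = fit_separatrix(
            [ellipsoids[g] for g in side1],
            [ellipsoids[g] for g in side2],
            side1_labels=side1,
            side2_labels=side2,
        )
        dists, pairwise = signed_distances(sep, model.scores, groups)
        dists.insert(0, "bee_id", Xh.index)
        dists.to_csv(out / f"separatrix_{si + 1}_distances.csv", index=False)
        hv = support_vector_heatmap(separatrix_in_tile_space(sep, model), config.grid)
        np.savetxt(out / f"separatrix_{si + 1}_heatmap.csv", hv, delimiter=",")
        report["separatrices"].append(
            {
                "sides": [side1, side2],
                "normal": sep.normal.tolist(),
                "offset": sep.offset,
                "pairwise_delta": {f"{a}-{b}": r.delta for (a, b), r in pairwise.items()},
                "median_distance_by_group": dists.groupby("group")["distance"].median().to_dict(),
            }
        )

    manifest = {
        "version": _version,
        "seed": config.seed,
        "parameters": {
            "k_extra": config.k_extra,
            "n_sectors": config.n_sectors,
            "half_width_m": config.half_width_m,
            "distance_bounds_m": list(config.distance_bounds_m),
            "n_angle_bins": config.n_angle_bins,
            "delta_threshold": config.delta_threshold,
            "n_components": config.n_components,
            "reference_group": ref,
        },
        "note": "effect sizes are reported without multiple-testing correction",
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    report["out_dir"] = str(out)
    return report
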