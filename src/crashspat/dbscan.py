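"""Density-based clustering (DBSCAN) of planar crash locations.

Crash hotspots are regions where crash points pile up more densely than the
surrounding background.  DBSCAN finds them without fixing the number of
clusters in advance: a point is a *core* point when at least ``min_pts``
points (itself included) lie strictly within radius ``eps`` of it; clusters
are the maximal sets of points density-connected through core points;
everything left over is *noise*.  A *border* point is a non-core point lying
inside some core point's eps-neighbourhood.

Two conventions are fixed deliberately and differ from some libraries:

* the eps-neighbourhood uses the **strict** inequality ``d(p, q) < eps``
  (many implementations, scikit-learn included, use ``<=``);
* ``min_pts`` counts the query point itself, since every point belongs to
  its own eps-neighbourhood.

Coordinates are planar/projected units (e.g. feet in a state-plane
projection); distances are Euclidean.  No geodesy is performed anywhere.
"""

from __future__ import annotations

import json
import logging
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, MultiPoint, Point, mapping

logger = logging.getLogger(__name__)

#: Sentinel cluster id for noise points.
NOISE = -1

#: Point classes.
CORE, BORDER, NOISE_CLASS = "core", "border", "noise"

# Brute force below this size; uniform grid of cell size eps above it.
_GRID_THRESHOLD = 1000


@dataclass(frozen=True)
class DBSCANParams:
    """Radius (eps, a.k.a. R) and density threshold (min_pts, a.k.a. D)."""

    eps: float
    min_pts: int

    def __post_init__(self) -> None:
        if not (self.eps > 0):
            raise ValueError(f"eps must be > 0, got {self.eps}")
        if self.min_pts < 1:
            raise ValueError(f"min_pts must be >= 1, got {self.min_pts}")


class PointSet:
    """Planar point pattern: an (n, 2) coordinate array with parallel ids."""

    def __init__(self, coords, ids=None):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError(f"coords must be (n, 2), got {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        if ids is None:
            ids = np.arange(len(coords))
        ids = np.asarray(ids)
        if len(ids) != len(coords):
            raise ValueError("ids and coords length mismatch")
        if len(np.unique(ids)) != len(ids):
            raise ValueError("ids must be unique")
        self.coords = coords
        self.ids = ids

    def __len__(self) -> int:
        return len(self.coords)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, x: str = "x", y: str = "y",
                       id_col: str | None = "id") -> "PointSet":
        ids = df[id_col].to_numpy() if id_col and id_col in df.columns else None
        return cls(np.column_stack([df[x].to_numpy(float), df[y].to_numpy(float)]), ids)


@dataclass
class ClusterResult:
    """Per-point labels and per-cluster membership from one DBSCAN run.

    ``cluster_id`` holds :data:`NOISE` (-1) for noise points and a
    non-negative integer otherwise.  ``border_ties`` records border points
    that were reachable from core points of more than one cluster; they stay
    with the first cluster discovered (deterministic index order).
    """

    point_class: np.ndarray          # per point: "core" | "border" | "noise"
    cluster_id: np.ndarray           # per point: int, NOISE for noise
    clusters: list[np.ndarray]       # member indices per cluster
    params: DBSCANParams
    border_ties: list[tuple[int, int, int]] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def core_count(self) -> int:
        return int(np.sum(self.point_class == CORE))

    @property
    def noise_count(self) -> int:
        return int(np.sum(self.point_class == NOISE_CLASS))


def _neighborhoods_brute(coords: np.ndarray, eps: float) -> list[np.ndarray]:
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
    eps2 = eps * eps
    return [np.flatnonzero(row < eps2) for row in d2]


def _neighborhoods_grid(coords: np.ndarray, eps: float) -> list[np.ndarray]:
    """Uniform grid of cell size eps: candidates come from the 3x3 block."""
    cells = np.floor(coords / eps).astype(np.int64)
    buckets: dict[tuple[int, int], list[int]] = {}
    for i, (cx, cy) in enumerate(map(tuple, cells)):
        buckets.setdefault((cx, cy), []).append(i)
    eps2 = eps * eps
    out: list[np.ndarray] = []
    for i in range(len(coords)):
        cx, cy = cells[i]
        cand: list[int] = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                cand.extend(buckets.get((cx + dx, cy + dy), ()))
        cand_arr = np.asarray(cand, dtype=np.int64)
        d2 = np.sum((coords[cand_arr] - coords[i]) ** 2, axis=1)
        out.append(np.sort(cand_arr[d2 < eps2]))
    return out


def _all_neighborhoods(coords: np.ndarray, eps: float) -> list[np.ndarray]:
    if len(coords) < _GRID_THRESHOLD:
        return _neighborhoods_brute(coords, eps)
    return _neighborhoods_grid(coords, eps)


def eps_neighborhood(points: PointSet, index: int, eps: float) -> np.ndarray:
    """Indices strictly within ``eps`` of point ``index`` (itself included)."""
    if not (eps > 0):
        raise ValueError("eps must be > 0")
    d2 = np.sum((points.coords - points.coords[index]) ** 2, axis=1)
    return np.flatnonzero(d2 < eps * eps)


def classify_points(points: PointSet, params: DBSCANParams) -> np.ndarray:
    """Label every point core / border / noise without forming clusters.

    core: |N_eps(p)| >= min_pts (self included); border: non-core inside a
    core point's neighbourhood (equivalently, has a core neighbour — the
    metric is symmetric); noise: the rest.
    """
    nbrs = _all_neighborhoods(points.coords, params.eps)
    counts = np.fromiter((len(nb) for nb in nbrs), dtype=int, count=len(points))
    is_core = counts >= params.min_pts
    out = np.full(len(points), NOISE_CLASS, dtype=object)
    out[is_core] = CORE
    for i in np.flatnonzero(~is_core):
        if np.any(is_core[nbrs[i]]):
            out[i] = BORDER
    return out.astype(str)


def dbscan(points: PointSet, params: DBSCANParams) -> ClusterResult:
    """Cluster a point pattern by density connectivity.

    Points are scanned in index order; each unassigned core point seeds a
    new cluster which is expanded breadth-first through the eps-neighbourhoods
    of its core members (Maximality), so clusters are exactly the maximal
    density-connected sets.  Border points keep the first cluster that
    reaches them; competing claims are logged in ``border_ties``.
    """
    n = len(points)
    if n == 0:
        return ClusterResult(np.array([], dtype=str), np.array([], dtype=int),
                             [], params)
    nbrs = _all_neighborhoods(points.coords, params.eps)
    counts = np.fromiter((len(nb) for nb in nbrs), dtype=int, count=n)
    is_core = counts >= params.min_pts

    labels = np.full(n, NOISE, dtype=int)
    ties: list[tuple[int, int, int]] = []
    cid = 0
    for seed in range(n):
        if not is_core[seed] or labels[seed] != NOISE:
            continue
        labels[seed] = cid
        queue = deque([seed])
        while queue:
            p = queue.popleft()
            for q in nbrs[p]:
                if labels[q] == NOISE:
                    labels[q] = cid
                    if is_core[q]:
                        queue.append(q)
                elif labels[q] != cid and not is_core[q]:
                    # border point already claimed by an earlier cluster
                    ties.append((int(q), int(labels[q]), cid))
        cid += 1

    point_class = np.full(n, NOISE_CLASS, dtype=object)
    point_class[is_core] = CORE
    point_class[(labels != NOISE) & ~is_core] = BORDER
    clusters = [np.flatnonzero(labels == c) for c in range(cid)]
    if ties:
        logger.info("dbscan: %d border-point tie(s) kept with first cluster", len(ties))
    return ClusterResult(point_class.astype(str), labels, clusters, params, ties)


def sensitivity_sweep(points: PointSet, eps_values, min_pts_values) -> pd.DataFrame:
    """One DBSCAN run per (eps, min_pts) grid cell.

    Mirrors the hotspot-calibration protocol of sweeping the radius R over
    e.g. {100, 150, 200} ft and the density threshold D over {5, 10, 15} and
    inspecting the resulting cluster counts.  Rows are ordered by
    (eps, min_pts).
    """
    eps_values = sorted(eps_values)
    min_pts_values = sorted(min_pts_values)
    if not eps_values or not min_pts_values:
        raise ValueError("eps_values and min_pts_values must be non-empty")
    rows = []
    for eps in eps_values:
        for mp in min_pts_values:
            res = dbscan(points, DBSCANParams(eps, mp))
            rows.append({
                "eps": eps, "min_pts": mp,
                "n_clusters": res.n_clusters,
                "n_core": res.core_count,
                "n_border": int(np.sum(res.point_class == BORDER)),
                "n_noise": res.noise_count,
            })
    return pd.DataFrame(rows)


@dataclass
class ClusterHull:
    """Convex hull of one cluster's member points.

    ``degenerate`` flags clusters with fewer than 3 non-collinear members,
    whose hull collapses to a segment or a single point.
    """

    cluster_id: int
    geometry: object  # shapely Polygon / LineString / Point
    member_count: int
    core_count: int
    degenerate: bool

    @property
    def area(self) -> float:
        return float(self.geometry.area)


def cluster_hulls(points: PointSet, result: ClusterResult) -> list[ClusterHull]:
    """Convex hull polygon per cluster (hotspot footprint)."""
    hulls = []
    for cid, members in enumerate(result.clusters):
        if len(members) == 0:
            raise ValueError(f"cluster {cid} is empty")
        geom = MultiPoint(points.coords[members]).convex_hull
        degenerate = isinstance(geom, (Point, LineString))
        n_core = int(np.sum(result.point_class[members] == CORE))
        hulls.append(ClusterHull(cid, geom, len(members), n_core, degenerate))
    return hulls


def hulls_to_geojson(hulls: list[ClusterHull]) -> dict:
    """FeatureCollection with one feature per cluster hull."""
    feats = []
    for h in hulls:
        feats.append({
            "type": "Feature",
            "geometry": mapping(h.geometry),
            "properties": {
                "cluster_id": h.cluster_id,
                "member_count": h.member_count,
                "core_count": h.core_count,
                "degenerate": h.degenerate,
            },
        })
    return {"type": "FeatureCollection", "features": feats}


def write_hulls(hulls: list[ClusterHull], path) -> None:
    with open(path, "w") as fh:
        json.dump(hulls_to_geojson(hulls), fh, indent=1)


def write_labels(points: PointSet, result: ClusterResult, path) -> None:
    """Per-point label file: id, x, y, point_class, cluster_id (CSV)."""
    pd.DataFrame({
        "id": points.ids,
        "x": points.coords[:, 0],
        "y": points.coords[:, 1],
        "point_class": result.point_class,
        "cluster_id": result.cluster_id,
    }).to_csv(path, index=False)
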