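"""Synthetic crash data with known ground truth.

Two layers, mirroring the two analysis stages:

1. **Point pattern** — planted circular hotspots (points uniform in a disc)
   over a uniform background inside a planar bounding box, with the true
   hotspot membership of every point recorded.  This gives the density
   clustering stage a known answer.

2. **Crash table** — covariates drawn per a configurable schema (by default
   the coded category structure and marginal proportions of the Nevada
   older-driver summary, independent across columns), and a binary severity
   outcome drawn from a spatial lag probit data-generating process:

       y* = (I - rho W)^(-1) (X beta + eps),   eps ~ N(0, I),
       y_i = 1  iff  y*_i > 0,

   with W row-standardized weights built from the generated coordinates.
   The latent field is obtained by a dense solve of (I - rho W) y* = X beta
   + eps — exact at desk scale (n up to a few thousand).  The error
   variance is fixed at 1 (probit identification) and is deliberately not
   configurable.  The latent values, true coefficients and true rho are
   stored so estimation stages can be scored against truth.

Categorical covariates are coded as small non-negative integers with code 0
the "Unknown"/"Other" bucket, and enter the design ordinally by default
(one column per covariate); dummy expansion is available downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import nevada
from .dbscan import PointSet
from .weights import WeightMatrix, distance_band_weights, knn_weights, row_standardize

#: Ground-truth label for background (non-hotspot) points.
BACKGROUND = -1


class GeometryError(ValueError):
    """A hotspot disc does not fit inside the bounding box."""


@dataclass(frozen=True)
class Hotspot:
    """A planted circular crash cluster: centre, radius, point count."""
    x: float
    y: float
    radius: float
    n: int

    def __post_init__(self):
        if not (self.radius > 0):
            raise ValueError("hotspot radius must be > 0")
        if self.n < 1:
            raise ValueError("hotspot point count must be >= 1")


@dataclass(frozen=True)
class Categorical:
    """Coded categorical covariate: level probabilities for codes 0..k-1."""
    name: str
    probs: tuple

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if (p < 0).any() or not np.isclose(p.sum(), 1.0, atol=1e-8):
            raise ValueError(f"{self.name}: level probabilities must be "
                             f"non-negative and sum to 1 (sum={p.sum()})")


@dataclass(frozen=True)
class Continuous:
    """Normal covariate; optionally rounded to an integer with a floor."""
    name: str
    mean: float
    sd: float
    integer: bool = False
    minimum: float | None = None


@dataclass(frozen=True)
class WeightsSpec:
    """Neighbour rule used by the data-generating process."""
    rule: str = "knn"          # "knn" | "distance_band"
    k: int = 5
    threshold: float | None = None

    def build(self, coords) -> WeightMatrix:
        if self.rule == "knn":
            return row_standardize(knn_weights(coords, self.k))
        if self.rule == "distance_band":
            if self.threshold is None:
                raise ValueError("distance_band rule needs a threshold")
            return row_standardize(distance_band_weights(coords, self.threshold))
        raise ValueError(f"unknown weights rule {self.rule!r}")


def default_covariate_schema() -> list:
    """Schema mirroring the Nevada older-driver summary's coding."""
    schema: list = [Categorical(name, tuple(nevada.category_proportions(name)))
                    for name in nevada.CATEGORY_PERCENTAGES]
    schema.append(Continuous("total_vehicles", nevada.TOTAL_VEHICLES_MEAN,
                             nevada.TOTAL_VEHICLES_SD, integer=True, minimum=1))
    return schema


def default_beta() -> np.ndarray:
    """True coefficients for the default schema.

    Intercept and retained-covariate values are the published Clark County
    spatial-probit posterior means; covariates that were pruned from that
    model get a true coefficient of 0.
    """
    by_name = {
        "crash_type": -0.106, "vehicle1_type": -0.063,
        "vehicle1_action": 0.146, "vehicle1_driver_condition": 0.045,
        "vehicle1_condition": -0.040, "vehicle2_action": -0.020,
        "vehicle2_condition": -0.028, "road_condition": -0.534,
        "weather": -0.055,
    }
    schema = default_covariate_schema()
    return np.array([1.541] + [by_name.get(c.name, 0.0) for c in schema])


@dataclass
class SyntheticConfig:
    """Full specification of a synthetic crash data-generating process."""

    hotspots: list = field(default_factory=list)
    background_count: int = 0
    bounding_box: tuple = (0.0, 0.0, 10_000.0, 10_000.0)
    beta: np.ndarray | None = None
    rho: float = 0.5
    covariate_schema: list | None = None
    weights_spec: WeightsSpec = field(default_factory=WeightsSpec)
    seed: int = 0
    age_range: tuple = (65.0, 95.0)
    n_points: int | None = None   # optional cross-check against the counts

    def __post_init__(self):
        if self.covariate_schema is None:
            self.covariate_schema = default_covariate_schema()
        if self.beta is None:
            if len(self.covariate_schema) == len(default_covariate_schema()):
                self.beta = default_beta()
            else:
                raise ValueError("beta must be given for a custom schema")
        self.beta = np.asarray(self.beta, dtype=float)
        if len(self.beta) != 1 + len(self.covariate_schema):
            raise ValueError(
                f"beta has {len(self.beta)} entries; expected intercept + "
                f"{len(self.covariate_schema)} covariates")
        if not (-1.0 < self.rho < 1.0):
            raise ValueError(f"rho must lie in (-1, 1), got {self.rho}")
        total = sum(h.n for h in self.hotspots) + self.background_count
        if self.n_points is not None and self.n_points != total:
            raise ValueError(f"n_points={self.n_points} but hotspot + "
                             f"background counts give {total}")
        xmin, ymin, xmax, ymax = self.bounding_box
        if not (xmax > xmin and ymax > ymin):
            raise ValueError("bounding box is degenerate")

    @property
    def total_points(self) -> int:
        return sum(h.n for h in self.hotspots) + self.background_count


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    true_cluster: np.ndarray           # hotspot index per point, -1 background
    true_beta: np.ndarray | None = None
    true_rho: float | None = None
    latent_ystar: np.ndarray | None = None


def generate_point_pattern(config: SyntheticConfig,
                           rng: np.random.Generator | None = None
                           ) -> tuple[PointSet, GroundTruth]:
    """Planted-hotspot point pattern with uniform background.

    Hotspot points are uniform in the stated disc (radius * sqrt(u) law);
    background points are uniform over the bounding box.  Reproducible for
    a fixed config seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    xmin, ymin, xmax, ymax = config.bounding_box
    coords, labels = [], []
    for h_idx, h in enumerate(config.hotspots):
        if (h.x - h.radius < xmin or h.x + h.radius > xmax
                or h.y - h.radius < ymin or h.y + h.radius > ymax):
            raise GeometryError(
                f"hotspot {h_idx} disc (centre ({h.x}, {h.y}), radius "
                f"{h.radius}) is not contained in the bounding box")
        r = h.radius * np.sqrt(rng.random(h.n))
        theta = rng.random(h.n) * 2 * np.pi
        coords.append(np.column_stack([h.x + r * np.cos(theta),
                                       h.y + r * np.sin(theta)]))
        labels.append(np.full(h.n, h_idx))
    if config.background_count:
        bg = np.column_stack([
            rng.uniform(xmin, xmax, config.background_count),
            rng.uniform(ymin, ymax, config.background_count)])
        coords.append(bg)
        labels.append(np.full(config.background_count, BACKGROUND))
    if coords:
        xy = np.concatenate(coords)
        lab = np.concatenate(labels)
    else:
        xy = np.empty((0, 2))
        lab = np.empty(0, dtype=int)
    return PointSet(xy), GroundTruth(true_cluster=lab.astype(int))


def _draw_covariates(schema, n, rng) -> pd.DataFrame:
    cols: dict = {}
    if not schema:
        return pd.DataFrame(index=pd.RangeIndex(n))
    for cov in schema:
        if isinstance(cov, Categorical):
            p = np.asarray(cov.probs, dtype=float)
            cols[cov.name] = rng.choice(len(p), size=n, p=p / p.sum())
        elif isinstance(cov, Continuous):
            v = rng.normal(cov.mean, cov.sd, size=n)
            if cov.integer:
                v = np.round(v)
            if cov.minimum is not None:
                v = np.maximum(v, cov.minimum)
            cols[cov.name] = v.astype(int) if cov.integer else v
        else:
            raise TypeError(f"unknown schema entry {cov!r}")
    return pd.DataFrame(cols)


def generate_crash_table(config: SyntheticConfig
                         ) -> tuple[pd.DataFrame, GroundTruth]:
    """Crash table from the spatial lag probit data-generating process.

    Returns the table (columns: id, x, y, severity, age, then covariates)
    and the ground truth holding the latent field, true beta and true rho.
    The binary severity equals the indicator latent > 0 exactly.
    """
    rng = np.random.default_rng(config.seed)
    points, truth = generate_point_pattern(config, rng)
    n = len(points)
    if n == 0:
        raise ValueError("config generates no points")
    cov = _draw_covariates(config.covariate_schema, n, rng)
    X = np.ones((n, 1))
    if len(cov.columns):
        X = np.hstack([X, cov.to_numpy(dtype=float)])
    eta = X @ config.beta
    eps = rng.standard_normal(n)

    if config.rho != 0.0:
        W = config.weights_spec.build(points.coords)
        lo, hi = W.eigen_support
        if not (lo < config.rho < hi):
            raise ValueError(f"rho={config.rho} outside the support "
                             f"({lo:.4f}, {hi:.4f}) of the standardized weights")
        lam = W.eigenvalues
        bad = np.abs(1.0 - config.rho * lam)
        if bad.min() < 1e-10:
            raise np.linalg.LinAlgError(
                f"(I - rho W) is singular: rho={config.rho} hits eigenvalue "
                f"{lam[np.argmin(bad)]}")
        A = np.eye(n) - config.rho * W.toarray()
        ystar = np.linalg.solve(A, eta + eps)
    else:
        # no spatial mixing: the latent field is exactly X beta + eps
        ystar = eta + eps

    severity = (ystar > 0).astype(int)
    age = rng.uniform(*config.age_range, size=n)
    table = pd.DataFrame({"id": np.arange(n),
                          "x": points.coords[:, 0],
                          "y": points.coords[:, 1],
                          "severity": severity,
                          "age": age})
    table = pd.concat([table, cov], axis=1)
    truth.true_beta = config.beta.copy()
    truth.true_rho = config.rho
    truth.latent_ystar = ystar
    return table, truth


# ---------------------------------------------------------------------------
# text I/O

def write_crash_table(table: pd.DataFrame, path) -> None:
    # %.17g round-trips doubles exactly, so a written table re-read from
    # disk reproduces the in-memory analysis bit for bit
    table.to_csv(path, index=False, float_format="%.17g")


def read_crash_table(path) -> pd.DataFrame:
    # round_trip parsing: together with the %.17g writer, a table survives
    # the disk round trip bit for bit
    return pd.read_csv(path, float_precision="round_trip")


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Sidecar file keyed by record id; beta/rho in commented header lines."""
    with open(path, "w") as fh:
        if truth.true_rho is not None:
            fh.write(f"# true_rho={float(truth.true_rho)!r}\n")
        if truth.true_beta is not None:
            fh.write("# true_beta="
                     + ",".join(repr(float(b)) for b in truth.true_beta) + "\n")
        n = len(truth.true_cluster)
        ystar = truth.latent_ystar if truth.latent_ystar is not None else [""] * n
        fh.write("id,true_cluster,latent_ystar\n")
        for i in range(n):
            fh.write(f"{i},{truth.true_cluster[i]},{ystar[i]}\n")


def read_ground_truth(path) -> GroundTruth:
    rho, beta = None, None
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        body_start += 1
        key, val = line.lstrip("# ").rstrip().split("=", 1)
        if key == "true_rho":
            rho = float(val)
        elif key == "true_beta":
            beta = np.array([float(v) for v in val.split(",")])
    import io
    df = pd.read_csv(io.StringIO("".join(lines[body_start:])))
    ystar = df["latent_ystar"].to_numpy(float) if df["latent_ystar"].notna().all() else None
    return GroundTruth(df["true_cluster"].to_numpy(int), beta, rho, ystar)


def config_to_doc(config: SyntheticConfig) -> dict:
    """Plain-dict form of a config (the YAML document schema)."""
    return {
        "hotspots": [{"x": h.x, "y": h.y, "radius": h.radius, "n": h.n}
                     for h in config.hotspots],
        "background_count": config.background_count,
        "bounding_box": list(config.bounding_box),
        "beta": [float(b) for b in config.beta],
        "rho": float(config.rho),
        "covariate_schema": [
            {"name": c.name, "type": "categorical", "probs": [float(p) for p in c.probs]}
            if isinstance(c, Categorical) else
            {"name": c.name, "type": "continuous", "mean": c.mean, "sd": c.sd,
             "integer": c.integer, "minimum": c.minimum}
            for c in config.covariate_schema],
        "weights_spec": {"rule": config.weights_spec.rule,
                         "k": config.weights_spec.k,
                         "threshold": config.weights_spec.threshold},
        "seed": config.seed,
        "age_range": list(config.age_range),
    }


def config_to_yaml(config: SyntheticConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_doc(config), fh, sort_keys=False)


def config_from_doc(doc: dict) -> SyntheticConfig:
    schema = []
    for c in doc["covariate_schema"]:
        if c["type"] == "categorical":
            schema.append(Categorical(c["name"], tuple(c["probs"])))
        else:
            schema.append(Continuous(c["name"], c["mean"], c["sd"],
                                     c.get("integer", False), c.get("minimum")))
    ws = doc.get("weights_spec", {})
    return SyntheticConfig(
        hotspots=[Hotspot(**h) for h in doc.get("hotspots", [])],
        background_count=doc.get("background_count", 0),
        bounding_box=tuple(doc["bounding_box"]),
        beta=np.array(doc["beta"], dtype=float),
        rho=doc["rho"],
        covariate_schema=schema,
        weights_spec=WeightsSpec(ws.get("rule", "knn"), ws.get("k", 5),
                                 ws.get("threshold")),
        seed=doc.get("seed", 0),
        age_range=tuple(doc.get("age_range", (65.0, 95.0))),
    )


def config_from_yaml(path) -> SyntheticConfig:
    with open(path) as fh:
        return config_from_doc(yaml.safe_load(fh))
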