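"""End-to-end workflow: simulate or ingest, preprocess, cluster, fit, compare.

One call runs the whole two-stage analysis: (1) density-based hotspot
identification over the crash point pattern, with the (eps, min_pts)
sensitivity sweep and convex-hull export, and (2) Bayesian probit vs
spatial lag probit fits on the binarized severity outcome, compared by DIC
(differences above 10 treated as decisive).  Every stage logs its
input/output record counts; all artifacts are plain-text files in the
output directory; the run is fully determined by the config and its seed.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import preprocessing as prep
from . import synthetic as synth
from .dbscan import (DBSCANParams, PointSet, cluster_hulls, dbscan,
                     sensitivity_sweep, write_hulls, write_labels)
from .spatial_probit import (DICResult, McmcConfig, compute_dic, fit_probit,
                             fit_spatial_probit, fit_report_text,
                             stepwise_prune, summarize, write_trace)
from .synthetic import SyntheticConfig, WeightsSpec

logger = logging.getLogger(__name__)

#: columns of the crash-table contract that are never predictors
_NON_PREDICTORS = {"id", "x", "y", "severity", "age"}


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one full run."""

    synthetic: SyntheticConfig | None = None
    input_path: str | None = None
    age_threshold: float = 65.0
    eps_values: tuple = (100.0, 150.0, 200.0)
    min_pts_values: tuple = (5, 10, 15)
    chosen_eps: float = 200.0
    chosen_min_pts: int = 15
    weights_spec: WeightsSpec = field(default_factory=WeightsSpec)
    predictors: tuple | None = None     # None -> every covariate column
    encoding: str = "ordinal"
    r_threshold: float = 0.7
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    prune: bool = False
    dic_threshold: float = 10.0

    def __post_init__(self):
        if (self.synthetic is None) == (self.input_path is None):
            raise ValueError("give exactly one of synthetic config or input path")
        if not self.eps_values or not self.min_pts_values:
            raise ValueError("sweep grids must be non-empty")

    def digest(self) -> str:
        doc = {
            "synthetic_seed": None if self.synthetic is None else self.synthetic.seed,
            "synthetic_rho": None if self.synthetic is None else self.synthetic.rho,
            "input_path": self.input_path,
            "age_threshold": self.age_threshold,
            "eps_values": list(self.eps_values),
            "min_pts_values": list(self.min_pts_values),
            "chosen": [self.chosen_eps, self.chosen_min_pts],
            "weights": [self.weights_spec.rule, self.weights_spec.k,
                        self.weights_spec.threshold],
            "predictors": None if self.predictors is None else list(self.predictors),
            "encoding": self.encoding,
            "r_threshold": self.r_threshold,
            "mcmc": [self.mcmc.n_draws, self.mcmc.burn_in, self.mcmc.thin,
                     self.mcmc.seed],
            "prune": self.prune,
        }
        return hashlib.sha256(
            yaml.safe_dump(doc, sort_keys=True).encode()).hexdigest()[:16]


def pipeline_config_to_yaml(config: PipelineConfig, path) -> None:
    """Write a run config as YAML (synthetic DGP inlined if present)."""
    doc = {
        "input_path": config.input_path,
        "age_threshold": config.age_threshold,
        "eps_values": list(config.eps_values),
        "min_pts_values": list(config.min_pts_values),
        "chosen_eps": config.chosen_eps,
        "chosen_min_pts": config.chosen_min_pts,
        "weights_spec": {"rule": config.weights_spec.rule,
                         "k": config.weights_spec.k,
                         "threshold": config.weights_spec.threshold},
        "predictors": None if config.predictors is None
                      else list(config.predictors),
        "encoding": config.encoding,
        "r_threshold": config.r_threshold,
        "mcmc": {"n_draws": config.mcmc.n_draws,
                 "burn_in": config.mcmc.burn_in,
                 "thin": config.mcmc.thin, "seed": config.mcmc.seed},
        "prune": config.prune,
        "dic_threshold": config.dic_threshold,
    }
    if config.synthetic is not None:
        doc["synthetic"] = synth.config_to_doc(config.synthetic)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def pipeline_config_from_yaml(path) -> PipelineConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    syn = None
    if doc.get("synthetic") is not None:
        syn = synth.config_from_doc(doc["synthetic"])
    ws = doc.get("weights_spec", {})
    mc = doc.get("mcmc", {})
    return PipelineConfig(
        synthetic=syn,
        input_path=doc.get("input_path"),
        age_threshold=doc.get("age_threshold", 65.0),
        eps_values=tuple(doc.get("eps_values", (100.0, 150.0, 200.0))),
        min_pts_values=tuple(doc.get("min_pts_values", (5, 10, 15))),
        chosen_eps=doc.get("chosen_eps", 200.0),
        chosen_min_pts=doc.get("chosen_min_pts", 15),
        weights_spec=WeightsSpec(ws.get("rule", "knn"), ws.get("k", 5),
                                 ws.get("threshold")),
        predictors=None if doc.get("predictors") is None
                   else tuple(doc["predictors"]),
        encoding=doc.get("encoding", "ordinal"),
        r_threshold=doc.get("r_threshold", 0.7),
        mcmc=McmcConfig(n_draws=mc.get("n_draws", 6000),
                        burn_in=mc.get("burn_in", 1000),
                        thin=mc.get("thin", 1), seed=mc.get("seed", 0)),
        prune=doc.get("prune", False),
        dic_threshold=doc.get("dic_threshold", 10.0),
    )


@dataclass
class ModelComparison:
    preferred: str
    delta: float          # DIC(other) - DIC(preferred), always >= 0
    substantial: bool
    verdict: str


def compare_models(dic_a: DICResult, dic_b: DICResult,
                   label_a: str = "model A", label_b: str = "model B",
                   threshold: float = 10.0) -> ModelComparison:
    """Lower DIC wins; a gap above the threshold is called decisive."""
    for d in (dic_a.dic, dic_b.dic):
        if not np.isfinite(d):
            raise ValueError("DIC values must be finite")
    if dic_a.dic <= dic_b.dic:
        preferred, delta = label_a, dic_b.dic - dic_a.dic
    else:
        preferred, delta = label_b, dic_a.dic - dic_b.dic
    substantial = delta > threshold
    verdict = (f"{preferred} preferred (DIC {min(dic_a.dic, dic_b.dic):.3f} vs "
               f"{max(dic_a.dic, dic_b.dic):.3f}, difference {delta:.3f} "
               f"{'>' if substantial else '<='} {threshold:g} -> "
               f"{'decisive' if substantial else 'not decisive'})")
    return ModelComparison(preferred, float(delta), substantial, verdict)


@dataclass
class RunReport:
    """Everything one run computed, plus provenance."""

    counts: dict
    sweep: pd.DataFrame
    hotspot_summary: pd.DataFrame
    probit_summary: pd.DataFrame
    spatial_summary: pd.DataFrame
    probit_dic: DICResult
    spatial_dic: DICResult
    comparison: ModelComparison
    config_digest: str
    seed: int
    warnings: list = field(default_factory=list)
    removal_log: list = field(default_factory=list)

    def body_text(self) -> str:
        """Deterministic report body (no timestamps)."""
        lines = ["# crashspat run report",
                 f"config digest: {self.config_digest}",
                 f"seed: {self.seed}", "",
                 "## record counts"]
        for stage, cnt in self.counts.items():
            lines.append(f"  {stage:24s} {cnt}")
        lines += ["", "## sensitivity sweep (eps, min_pts)",
                  self.sweep.to_string(index=False), "",
                  "## hotspots (chosen parameters)",
                  self.hotspot_summary.to_string(index=False) if len(
                      self.hotspot_summary) else "  (no clusters)", "",
                  "## probit fit", self.probit_summary.to_string(), "",
                  "## spatial probit fit", self.spatial_summary.to_string(), "",
                  "## model comparison",
                  f"  DIC probit          {self.probit_dic.dic:.3f}",
                  f"  DIC spatial probit  {self.spatial_dic.dic:.3f}",
                  f"  {self.comparison.verdict}"]
        if self.removal_log:
            lines += ["", "## stepwise removals"]
            for entry in self.removal_log:
                lines.append(f"  removed {entry['removed']} "
                             f"(mean {entry['mean']:.3f}, BCI {entry['bci']})")
        if self.warnings:
            lines += ["", "## warnings"]
            lines += [f"  {w}" for w in self.warnings]
        return "\n".join(lines) + "\n"


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise PipelineStageError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig, out_dir=None) -> RunReport:
    """Execute the full workflow; write artifacts if ``out_dir`` is given."""
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        fh = logging.FileHandler(out / "run.log", mode="w")
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logging.getLogger("crashspat").addHandler(fh)
    try:
        return _run(config, out)
    finally:
        if out is not None:
            logging.getLogger("crashspat").removeHandler(fh)
            fh.close()


def _run(config: PipelineConfig, out: Path | None) -> RunReport:
    counts: dict = {}
    warnings: list = []

    # -- ingest -------------------------------------------------------------
    @_stage("ingest")
    def ingest():
        if config.synthetic is not None:
            table, truth = synth.generate_crash_table(config.synthetic)
            if out is not None:
                synth.write_crash_table(table, out / "crash_table.csv")
                synth.write_ground_truth(truth, out / "ground_truth.csv")
            return table
        return synth.read_crash_table(config.input_path)

    table = ingest()
    counts["raw records"] = len(table)
    logger.info("ingest: %d records", len(table))

    # -- preprocess ---------------------------------------------------------
    @_stage("preprocess")
    def preprocess(t):
        t = prep.filter_older_drivers(t, config.age_threshold)
        counts["age >= threshold"] = len(t)
        t = prep.binarize_severity(t)
        counts["severity binarized"] = len(t)
        return t

    table = preprocess(table)

    # -- clustering ---------------------------------------------------------
    @_stage("cluster")
    def cluster(t):
        points = PointSet.from_dataframe(t)
        sweep = sensitivity_sweep(points, config.eps_values,
                                     config.min_pts_values)
        chosen = dbscan(points, DBSCANParams(config.chosen_eps,
                                                   config.chosen_min_pts))
        hulls = cluster_hulls(points, chosen)
        if chosen.border_ties:
            warnings.append(f"{len(chosen.border_ties)} border-point tie(s) "
                            f"kept with first cluster")
        if out is not None:
            sweep.to_csv(out / "sweep.csv", index=False)
            write_labels(points, chosen, out / "labels.csv")
            write_hulls(hulls, out / "hulls.geojson")
        hs = pd.DataFrame([{"cluster_id": h.cluster_id,
                            "members": h.member_count,
                            "core": h.core_count,
                            "hull_area": h.area,
                            "degenerate": h.degenerate} for h in hulls])
        return sweep, hs

    sweep, hotspot_summary = cluster(table)

    # -- design -------------------------------------------------------------
    @_stage("design")
    def design_stage(t):
        preds = (list(config.predictors) if config.predictors is not None
                 else [c for c in t.columns if c not in _NON_PREDICTORS])
        if len(preds) >= 2:
            retained, report = prep.collinearity_screen(t, preds,
                                                        config.r_threshold)
            if out is not None:
                report.to_csv(out / "collinearity.csv", index=False)
            if len(retained) < len(preds):
                warnings.append(f"collinearity screen dropped "
                                f"{len(preds) - len(retained)} predictor(s)")
            preds = retained
        elif not preds:
            warnings.append("empty predictor list: intercept-only models")
            logger.warning("design: empty predictor list; intercept-only")
        return prep.build_design(t, preds, config.encoding)

    design = design_stage(table)
    counts["design rows"] = design.n

    # -- weights ------------------------------------------------------------
    @_stage("weights")
    def weights_stage():
        W = config.weights_spec.build(design.coords)
        if len(W.isolated):
            warnings.append(f"{len(W.isolated)} isolated row(s) in W")
        return W

    W = weights_stage()
    counts["weight matrix rows"] = W.n

    # -- fits ---------------------------------------------------------------
    @_stage("fit")
    def fits():
        removal_log: list = []
        if config.prune:
            pfit, plog, pdesign = stepwise_prune(design, None, config.mcmc)
            sfit, slog, sdesign = stepwise_prune(design, W, config.mcmc)
            removal_log = [{"model": "probit", **e} for e in plog] + \
                          [{"model": "spatial", **e} for e in slog]
        else:
            pdesign = sdesign = design
            pfit = fit_probit(design, config.mcmc)
            sfit = fit_spatial_probit(design, W, config.mcmc)
        pdic = compute_dic(pfit, pdesign)
        sdic = compute_dic(sfit, sdesign, W)
        return pfit, sfit, pdic, sdic, removal_log, pdesign, sdesign

    pfit, sfit, pdic, sdic, removal_log, pdesign, sdesign = fits()
    warnings.extend(pfit.warnings)
    warnings.extend(sfit.warnings)

    comparison = compare_models(pdic, sdic, "probit", "spatial probit",
                                config.dic_threshold)
    logger.info("compare: %s", comparison.verdict)

    report = RunReport(counts=counts, sweep=sweep,
                       hotspot_summary=hotspot_summary,
                       probit_summary=summarize(pfit),
                       spatial_summary=summarize(sfit),
                       probit_dic=pdic, spatial_dic=sdic,
                       comparison=comparison,
                       config_digest=config.digest(),
                       seed=config.mcmc.seed,
                       warnings=warnings, removal_log=removal_log)

    if out is not None:
        (out / "report.txt").write_text(report.body_text())
        (out / "probit_fit.txt").write_text(fit_report_text(pfit, pdic))
        (out / "spatial_fit.txt").write_text(fit_report_text(sfit, sdic))
        write_trace(pfit, out / "probit_trace.csv")
        write_trace(sfit, out / "spatial_trace.csv")
    return report
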