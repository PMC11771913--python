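"""Simulation studies validating the estimation stack on its own DGP.

Each experiment generates data from the spatial lag probit data-generating
process at a known parameter point, runs the package's samplers, and
reports recovery/comparison statistics.  Problem sizes (n of a few
hundred, a handful of replicates) are desk-scale versions of the study
design: large enough for the properties under test to be visible, small
enough to run in minutes.

Replicate seeds are derived deterministically from one base seed so an
entire study is reproducible from a single integer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import binarize_severity, build_design
from .spatial_probit import McmcConfig, compute_dic, fit_probit, \
    fit_spatial_probit, summarize
from .synthetic import Continuous, SyntheticConfig, WeightsSpec
from .synthetic import generate_crash_table


def derive_seed(base_seed: int, index: int) -> int:
    """Deterministic per-replicate seed, kept below 2**31."""
    return int((base_seed * 9973 + 7919 * index + 1) % (2 ** 31 - 1))


def _simulate_design(n: int, rho: float, beta, seed: int, k: int = 5):
    cfg = SyntheticConfig(
        hotspots=[], background_count=n, bounding_box=(0, 0, 1000, 1000),
        covariate_schema=[Continuous("x1", 0.0, 1.0)],
        beta=list(beta), rho=rho, weights_spec=WeightsSpec("knn", k),
        seed=seed)
    table, truth = generate_crash_table(cfg)
    design = build_design(binarize_severity(table), ["x1"])
    W = WeightsSpec("knn", k).build(design.coords)
    return design, W, truth


@dataclass
class NullRhoResult:
    """Reduction-law study: DGP at rho = 0, spatial vs plain probit.

    ``beta_diff_free`` compares the free-rho spatial fit to the probit fit;
    it contains a small systematic term of order E[rho^2]*beta because the
    spatial fit averages over nonzero rho values.  ``beta_diff_fixed``
    compares the spatial sampler with rho held at 0 — whose conditionals
    coincide exactly with the probit sampler's — so it differs from the
    probit fit by Monte Carlo error only.
    """

    rho_means: np.ndarray          # per replicate (free-rho fit)
    beta_diff_free: np.ndarray     # mean over replicates of beta differences
    beta_diff_fixed: np.ndarray
    combined_mcse: np.ndarray      # MC standard error of those means

    @property
    def mean_rho(self) -> float:
        return float(self.rho_means.mean())


def null_rho_study(base_seed: int, n: int = 400, replicates: int = 5,
                   mcmc: McmcConfig | None = None) -> NullRhoResult:
    """Fit both models on rho = 0 data; measure rho bias and beta agreement.

    beta differences are averaged across replicates; combined_mcse is the
    quadrature-combined Monte Carlo standard error of that average
    (per-replicate MCSEs of both fits, combined and divided by sqrt(R)).
    """
    rho_means, diffs_free, diffs_fixed, mcse_sq = [], [], [], []
    for r in range(replicates):
        seed = derive_seed(base_seed, r)
        design, W, _ = _simulate_design(n, 0.0, (0.5, -1.0), seed)
        cfg = mcmc or McmcConfig()
        sfit = fit_spatial_probit(design, W, McmcConfig(
            n_draws=cfg.n_draws, burn_in=cfg.burn_in, seed=seed))
        ffit = fit_spatial_probit(design, W, McmcConfig(
            n_draws=cfg.n_draws, burn_in=cfg.burn_in, seed=seed + 2,
            fix_rho=0.0))
        pfit = fit_probit(design, McmcConfig(
            n_draws=cfg.n_draws, burn_in=cfg.burn_in, seed=seed + 1))
        rho_means.append(sfit.rho_draws.mean())
        diffs_free.append(sfit.posterior_mean() - pfit.posterior_mean())
        diffs_fixed.append(ffit.posterior_mean() - pfit.posterior_mean())
        f_mcse = summarize(ffit)["mcse"].to_numpy()[:len(design.names)]
        p_mcse = summarize(pfit)["mcse"].to_numpy()
        mcse_sq.append(f_mcse ** 2 + p_mcse ** 2)
    R = len(diffs_free)
    return NullRhoResult(
        rho_means=np.array(rho_means),
        beta_diff_free=np.array(diffs_free).mean(axis=0),
        beta_diff_fixed=np.array(diffs_fixed).mean(axis=0),
        combined_mcse=np.sqrt(np.mean(mcse_sq, axis=0) / R))


@dataclass
class RecoveryResult:
    """Parameter-recovery study at a spatially dependent truth."""

    true_rho: float
    true_beta: np.ndarray
    rho_means: np.ndarray          # per seed
    beta_means: np.ndarray         # (seeds, k)
    rho_covered: np.ndarray        # bool per seed: 95% BCI contains truth
    beta_covered: np.ndarray       # (seeds, k)

    @property
    def rho_bias(self) -> float:
        return float(self.rho_means.mean() - self.true_rho)

    @property
    def beta_bias(self) -> np.ndarray:
        return self.beta_means.mean(axis=0) - self.true_beta


def recovery_study(base_seed: int, n: int = 400, rho: float = 0.5,
                   beta=(1.0, -1.0), seeds: int = 5, k: int = 5,
                   mcmc: McmcConfig | None = None) -> RecoveryResult:
    """Recover (rho, beta) across replicate datasets from the spatial DGP."""
    beta = np.asarray(beta, float)
    rho_means, beta_means, rho_cov, beta_cov = [], [], [], []
    for r in range(seeds):
        seed = derive_seed(base_seed, 100 + r)
        design, W, _ = _simulate_design(n, rho, beta, seed, k)
        cfg = mcmc or McmcConfig()
        fit = fit_spatial_probit(design, W, McmcConfig(
            n_draws=cfg.n_draws, burn_in=cfg.burn_in, seed=seed))
        summ = summarize(fit)
        rho_means.append(float(summ.loc["rho", "mean"]))
        beta_means.append(fit.posterior_mean())
        rho_cov.append(summ.loc["rho", "bci_lower"] <= rho
                       <= summ.loc["rho", "bci_upper"])
        beta_cov.append([
            summ.iloc[j]["bci_lower"] <= beta[j] <= summ.iloc[j]["bci_upper"]
            for j in range(len(beta))])
    return RecoveryResult(rho, beta, np.array(rho_means),
                          np.array(beta_means), np.array(rho_cov),
                          np.array(beta_cov))


@dataclass
class DicStudyResult:
    """Model-selection study: DIC ordering under a strongly spatial DGP."""

    spatial_preferred: np.ndarray   # bool per replicate
    dic_probit: np.ndarray
    dic_spatial: np.ndarray

    @property
    def preference_rate(self) -> float:
        return float(self.spatial_preferred.mean())


def dic_study(base_seed: int, n: int = 300, rho: float = 0.6,
              beta=(0.25, -1.0), replicates: int = 20,
              mcmc: McmcConfig | None = None) -> DicStudyResult:
    """How often does DIC prefer the spatial model when the DGP is spatial?"""
    preferred, dics_p, dics_s = [], [], []
    for r in range(replicates):
        seed = derive_seed(base_seed, 200 + r)
        design, W, _ = _simulate_design(n, rho, beta, seed)
        cfg = mcmc or McmcConfig()
        sfit = fit_spatial_probit(design, W, McmcConfig(
            n_draws=cfg.n_draws, burn_in=cfg.burn_in, seed=seed))
        pfit = fit_probit(design, McmcConfig(
            n_draws=cfg.n_draws, burn_in=cfg.burn_in, seed=seed + 1))
        sdic = compute_dic(sfit, design, W)
        pdic = compute_dic(pfit, design)
        preferred.append(sdic.dic < pdic.dic)
        dics_p.append(pdic.dic)
        dics_s.append(sdic.dic)
    return DicStudyResult(np.array(preferred), np.array(dics_p),
                          np.array(dics_s))
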