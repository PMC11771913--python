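import numpy as np
import pytest

import crashspat as cs


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def two_disc_config():
    """Two well-separated 50-point discs plus sparse background."""
    return cs.SyntheticConfig(
        hotspots=[cs.Hotspot(2000, 2000, 50, 50),
                  cs.Hotspot(7000, 2000, 50, 50)],
        background_count=20,
        bounding_box=(0, 0, 10_000, 10_000),
        covariate_schema=[cs.Categorical("a", (0.5, 0.5))],
        beta=[0.0, 0.5],
        rho=0.0,
        seed=7,
    )


@pytest.fixture
def two_disc_points(two_disc_config):
    points, truth = cs.generate_point_pattern(two_disc_config)
    return points, truth


def simple_table(n=400, rho=0.0, seed=0, k=5, beta=(1.0, -1.0)):
    """Crash table from a one-covariate spatial lag probit DGP."""
    cfg = cs.SyntheticConfig(
        hotspots=[], background_count=n, bounding_box=(0, 0, 1000, 1000),
        covariate_schema=[cs.Continuous("x1", 0.0, 1.0)],
        beta=list(beta), rho=rho, weights_spec=cs.WeightsSpec("knn", k),
        seed=seed)
    return cs.generate_crash_table(cfg)


def simple_design(n=400, rho=0.0, seed=0, k=5, beta=(1.0, -1.0)):
    table, truth = simple_table(n, rho, seed, k, beta)
    design = cs.build_design(cs.binarize_severity(table), ["x1"])
    W = cs.WeightsSpec("knn", k).build(design.coords)
    return design, W, truth


@pytest.fixture
def quick_mcmc():
    """Short chains for unit tests (still >= 100 retained draws)."""
    return cs.McmcConfig(n_draws=1500, burn_in=300, seed=5)
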