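import warnings

import numpy as np
import pandas as pd
import pytest

import vernalseq as vs

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def leaf():
    return vs.leaf_grid()


@pytest.fixture(scope="session")
def meristem():
    return vs.meristem_grid()


@pytest.fixture(scope="session")
def leaf_scenario():
    """Moderate leaf simulation shared by unit tests (500 genes, seed 1)."""
    cfg = vs.SimulationConfig(n_genes=500, seed=1)
    counts, samples, truth = vs.generate_timecourse(cfg)
    return cfg, counts, samples, truth


@pytest.fixture(scope="session")
def leaf_de(leaf_scenario, leaf):
    """Pairwise DE results on the shared leaf scenario."""
    _, counts, samples, _ = leaf_scenario
    cm = vs.CountMatrix(counts=counts, samples=samples)
    results, union, info = vs.pairwise_de(cm, leaf, alpha=0.05)
    return results, union, info


def simulate_null_counts(
    n_genes: int,
    n_samples: int,
    a0: float,
    a1: float,
    seed: int,
    size_factor_sd: float = 0.2,
    mean_log2_range=(4.0, 12.0),
):
    """Direct NB sampler used as independent input for DE-module tests.

    Draws per-gene constant means (no planted signal) and library
    scalings, then NB counts with variance mu + (a0 + a1/mu) mu^2.
    """
    rng = np.random.default_rng(seed)
    mu = 2.0 ** rng.uniform(*mean_log2_range, n_genes)
    sf = np.exp(rng.normal(0.0, size_factor_sd, n_samples))
    alpha = a0 + a1 / mu
    mean = mu[:, None] * sf[None, :]
    if a0 == 0 and a1 == 0:
        k = rng.poisson(mean)
    else:
        var = mean + alpha[:, None] * mean**2
        n = mean**2 / (var - mean)
        p = n / (n + mean)
        k = rng.negative_binomial(n, p)
    counts = pd.DataFrame(
        k, index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    return counts, pd.Series(sf, index=counts.columns), mu
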