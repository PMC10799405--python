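import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid

from photoqtl import (SimulationDesign, default_light_grid, simulate_study)
from photoqtl.growth import HDEEParams, eval_hdee


@pytest.fixture(scope="session")
def grid11():
    """The 11-level log-spaced light ladder used throughout."""
    return default_light_grid(11)


@pytest.fixture(scope="session")
def etr_params():
    return HDEEParams(K=30.0, a=8.0, b=1.2, c=1.5, d=0.8)


@pytest.fixture(scope="session")
def etr_mean(grid11, etr_params):
    """Noiseless ETR-like composite mean trajectory."""
    return eval_hdee("logistic", etr_params, grid11.log_levels)


@pytest.fixture(scope="session")
def small_study():
    """98-sample study with 120 SNPs and 2 planted QTLs per trait."""
    return simulate_study(SimulationDesign(n_samples=98, n_snps=120, n_causal=2, seed=11))


@pytest.fixture(scope="session")
def chain_curves():
    """5-node directed chain: node 1 drives 2 drives 3 ... with coupling +0.8.

    Built on a fine grid (trapezoid integration error ~1e-7) and subsampled
    to the 30-point dense axis the network stage uses.
    """
    fine = np.linspace(2.0, 7.9, 2901)
    curves_f = {1: 0.45 + 0.25 * np.sin(1.5 * fine)}
    for p in range(1, 5):
        integ = np.concatenate([[0.0], cumulative_trapezoid(0.8 * curves_f[p], fine)])
        curves_f[p + 1] = 0.2 + integ
    grid = fine[::100]
    return grid, {p: v[::100] for p, v in curves_f.items()}
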