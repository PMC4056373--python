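import numpy as np
import pandas as pd
import pytest

from dgi.normalize import residuals_pipeline
from dgi.scoring import compute_differentials
from dgi.simulate import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def null_screen():
    """Mid-sized paired screen with no injected interactions."""
    cfg = SimulationConfig(
        n_queries=20, n_arrays=100, n_replicates=6,
        sigma_shared=0.15, sigma_cond=0.05, seed=11,
    )
    table, truth = simulate_experiment(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def null_residuals(null_screen):
    _, table, _ = null_screen
    residuals, model = residuals_pipeline(table)
    return residuals, model


@pytest.fixture(scope="session")
def null_diffs(null_screen, null_residuals):
    cfg, _, _ = null_screen
    residuals, _ = null_residuals
    return compute_differentials(residuals, cfg.treatment, cfg.reference)


@pytest.fixture(scope="session")
def effect_screen():
    """Screen with differential effects of 4*sigma_cond in 5% of pairs."""
    cfg = SimulationConfig(
        n_queries=20, n_arrays=100, n_replicates=6,
        sigma_shared=0.15, sigma_cond=0.05,
        differential_frac=0.05, effect_size=4 * 0.05, seed=21,
    )
    table, truth = simulate_experiment(cfg)
    residuals, _ = residuals_pipeline(table)
    diffs = compute_differentials(residuals, cfg.treatment, cfg.reference)
    return cfg, truth, residuals, diffs


def iid_residual_frame(n_queries, n_arrays, n_replicates, seed, sd=1.0):
    """Long-format residual table with iid Normal(0, sd) residuals."""
    rng = np.random.default_rng(seed)
    q, a, r, c = np.meshgrid(
        np.arange(n_queries), np.arange(n_arrays),
        np.arange(n_replicates), np.arange(2), indexing="ij",
    )
    return pd.DataFrame(
        {
            "query_id": np.char.add("Q", (q.ravel() + 1).astype(str)),
            "array_id": np.char.add("A", (a.ravel() + 1).astype(str)),
            "replicate": r.ravel() + 1,
            "condition": np.where(c.ravel() == 0, "UT", "MMS"),
            "residual": rng.normal(0.0, sd, size=q.size),
        }
    )
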