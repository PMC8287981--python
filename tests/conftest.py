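import numpy as np
import pandas as pd
import pytest
from anndata import AnnData
from hypothesis import HealthCheck, settings

from cafpaths.pipeline import default_config, run_all
from cafpaths.syndata import SimConfig

settings.register_profile(
    "deterministic", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


def small_sim_config(**overrides) -> SimConfig:
    """A scaled-down simulation for fast unit tests (~1,400 cells)."""
    params = dict(
        n_cells_tumour=700, n_cells_normal=700, n_genes=800,
        n_marker_genes_per_program=10, marker_fold_change=10.0, seed=11,
    )
    params.update(overrides)
    return SimConfig(**params)


def small_pipeline_config(seed: int = 11, **sim_overrides) -> dict:
    """Full pipeline config over a small simulation.

    The QC gene floor is lowered to match the smaller gene universe
    (detected genes scale with n_genes).
    """
    cfg = default_config(seed=seed)
    cfg["simulate"].update(dict(
        n_cells_tumour=1000, n_cells_normal=1000, n_genes=800,
        n_marker_genes_per_program=15,
    ))
    cfg["simulate"].update(sim_overrides)
    cfg["prep"]["min_genes_per_cell"] = 60
    cfg["cluster"]["n_pc"] = 10
    return cfg


def make_adata(X, sample_id="S1", tissue="tumour", gene_prefix="G") -> AnnData:
    """Wrap a dense nonnegative matrix as a normalized-expression AnnData."""
    X = np.asarray(X, dtype=float)
    n, g = X.shape
    obs = pd.DataFrame({
        "sample_id": [sample_id] * n if isinstance(sample_id, str) else sample_id,
        "tissue": [tissue] * n if isinstance(tissue, str) else tissue,
    }, index=pd.Index([f"c{i:04d}" for i in range(n)], name="cell_id"))
    var = pd.DataFrame(index=pd.Index([f"{gene_prefix}{j}" for j in range(g)],
                                      name="gene"))
    return AnnData(X=X, obs=obs, var=var)


@pytest.fixture(scope="session")
def default_report():
    """One full pipeline run under the default study conditions (seed 1)."""
    return run_all(default_config(seed=1))


@pytest.fixture(scope="session")
def multi_seed_reports():
    """Twenty independent full pipeline runs (seeds 1..20)."""
    return [run_all(default_config(seed=s)) for s in range(1, 21)]
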