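import anndata as ad
import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from tamkit import synthdata
from tamkit.core import lognormalize

settings.register_profile(
    "tamkit", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("tamkit")


def make_adata(counts, clusters=None, normalize=True, **obs_cols) -> ad.AnnData:
    """AnnData from a dense count array with optional obs columns."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    obs = pd.DataFrame(index=[f"cell{i}" for i in range(n_cells)])
    if clusters is not None:
        obs["cluster"] = list(clusters)
    for key, vals in obs_cols.items():
        obs[key] = list(vals)
    adata = ad.AnnData(
        X=counts.astype(np.int64), obs=obs,
        var=pd.DataFrame(index=[f"g{j}" for j in range(n_genes)]))
    if normalize:
        lognormalize(adata)
    return adata


@pytest.fixture(scope="session")
def planted_atlas():
    """Small simulated atlas with strong planted markers, shared by tests."""
    cfg = synthdata.SCSimConfig(
        n_studies=3, n_samples_per_study=4, n_clusters=4, n_genes=600,
        cells_per_sample=(60, 120), marker_log2fc=2.0, seed=11)
    adata, truth = synthdata.simulate_sc_atlas(cfg)
    lognormalize(adata)
    return adata, truth
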