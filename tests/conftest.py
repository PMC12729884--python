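import numpy as np
import pandas as pd
import pytest
from anndata import AnnData

from oxstrata.scoring import NormalizedExpression


def make_adata(counts, **obs_cols):
    """AnnData from a dense count array plus per-cell metadata columns."""
    counts = np.asarray(counts)
    n, g = counts.shape
    obs = pd.DataFrame(index=[f"C{i}" for i in range(n)])
    obs["donor"] = obs_cols.get("donor", ["D0"] * n)
    obs["sample"] = obs_cols.get("sample", ["S0"] * n)
    obs["condition"] = obs_cols.get("condition", ["AMI"] * n)
    obs["percent_mt"] = obs_cols.get("percent_mt", np.full(n, 5.0))
    obs["n_count"] = counts.sum(axis=1)
    obs["n_feature"] = (counts > 0).sum(axis=1)
    obs["cell_type"] = obs_cols.get("cell_type", ["Cardiomyocyte"] * n)
    for k, v in obs_cols.items():
        if k not in obs.columns:
            obs[k] = v
    return AnnData(
        X=counts.astype(np.float64),
        obs=obs,
        var=pd.DataFrame(index=[f"G{i:05d}" for i in range(g)]),
    )


def make_expr(values, scale=1e4):
    """NormalizedExpression wrapping an explicit value matrix (no transform)."""
    values = np.asarray(values, dtype=float)
    n, g = values.shape
    return NormalizedExpression(
        X=values,
        genes=pd.Index([f"G{i:05d}" for i in range(g)]),
        cells=pd.Index([f"C{i}" for i in range(n)]),
        scale=scale,
    )


@pytest.fixture(scope="session")
def small_sc_dataset():
    """A modest default-config dataset shared by several tests."""
    from oxstrata.simulate import default_sc_dataset

    return default_sc_dataset(seed=11, n_cells=2000, n_genes=800)


@pytest.fixture(scope="session")
def small_bulk_cohort():
    from oxstrata.simulate import BulkSimConfig, generate_bulk

    return generate_bulk(BulkSimConfig(seed=5))
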