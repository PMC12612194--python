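import numpy as np
import pandas as pd
import pytest
import anndata as ad
from scipy import sparse

import tallscout as ts


@pytest.fixture(scope="session")
def default_cfg():
    return ts.SimConfig(seed=1)


@pytest.fixture(scope="session")
def sc_cohort(default_cfg):
    """Default simulated cohort after QC and normalisation, annotated from
    ground truth (blast vs T), plus the truth object."""
    adata, truth = ts.simulate_sc_cohort(default_cfg)
    adata, _ = ts.qc_filter(adata)
    adata = ts.normalize_log(adata)
    states = truth.cell_truth.loc[adata.obs_names, "latent_state"]
    adata.obs["annotation"] = np.where(states == "normal", "T", "blast")
    return adata, truth


@pytest.fixture(scope="session")
def blasts(sc_cohort):
    adata, truth = sc_cohort
    return adata[(adata.obs["annotation"] == "blast").to_numpy()].copy(), truth


@pytest.fixture(scope="session")
def derived_module(sc_cohort):
    """Module derivation pipeline run once on the default cohort."""
    adata, truth = sc_cohort
    module, trend, contrast = ts.derive_module_pipeline(adata, seed=0)
    return module, trend, contrast, truth


@pytest.fixture(scope="session")
def bulk_cohort():
    cfg = ts.SimConfig(seed=3)
    counts, samples, truth = ts.simulate_bulk_cohort(cfg)
    return counts, samples, truth


def make_adata(counts, genes=None, cells=None, **obs_cols):
    """Small AnnData from a dense count array (cells x genes)."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    genes = genes or [f"g{j}" for j in range(n_genes)]
    cells = cells or [f"c{i}" for i in range(n_cells)]
    obs = pd.DataFrame(index=pd.Index(cells, name="cell_id"))
    for k, v in obs_cols.items():
        obs[k] = v
    var = pd.DataFrame(index=pd.Index(genes, name="gene"))
    var["mito"] = var.index.str.startswith("MT-")
    return ad.AnnData(X=sparse.csr_matrix(counts), obs=obs, var=var)
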