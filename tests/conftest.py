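import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from spnblur import syndata


def make_adata(X, samples, phenotypes, subtypes, is_mito=None):
    """Small labelled AnnData from a dense cells x genes array."""
    X = np.asarray(X)
    n_obs, n_var = X.shape
    obs = pd.DataFrame({
        "sample": samples, "phenotype": phenotypes, "subtype": subtypes,
    }, index=pd.Index([f"c{i}" for i in range(n_obs)], name="cell_id"))
    var = pd.DataFrame({
        "is_mito": np.zeros(n_var, bool) if is_mito is None else np.asarray(is_mito),
    }, index=pd.Index([f"g{j}" for j in range(n_var)], name="gene"))
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ad.AnnData(X=sparse.csr_matrix(X), obs=obs, var=var)


@pytest.fixture(scope="session")
def small_config():
    return syndata.SimConfig(
        n_genes=300, n_samples_per_phenotype=3,
        cells_per_sample_per_subtype=30, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return syndata.generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_null_dataset():
    cfg = syndata.null_config(
        n_genes=300, n_samples_per_phenotype=3,
        cells_per_sample_per_subtype=30, seed=12)
    return syndata.generate_dataset(cfg)
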