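import numpy as np
import pandas as pd
import pytest
from anndata import AnnData
from scipy import sparse

import dopametab as dm


@pytest.fixture(scope="session")
def metabo_default():
    """Default-condition metabolomics simulation (6+6, 200 features)."""
    return dm.simulate_metabolomics(dm.MetaboSimConfig(seed=0))


@pytest.fixture(scope="session")
def sn_default():
    """Default-condition single-nucleus simulation with a composition shift."""
    cfg = dm.SnSimConfig(composition_shift={"SG": 0.05, "KCs": -0.05}, seed=0)
    return dm.simulate_snrna(cfg)


def make_adata(counts, cell_types=None, conditions=None, mito=None) -> AnnData:
    """Small dense-count AnnData builder for hand fixtures."""
    counts = np.asarray(counts)
    n_obs, n_vars = counts.shape
    obs = pd.DataFrame(index=[f"bc{i}" for i in range(n_obs)])
    if cell_types is not None:
        obs["cell_type"] = list(cell_types)
    if conditions is not None:
        obs["condition"] = list(conditions)
    var = pd.DataFrame(index=[f"g{j}" for j in range(n_vars)])
    var["mito"] = np.zeros(n_vars, bool) if mito is None else np.asarray(mito, bool)
    return AnnData(X=sparse.csr_matrix(counts), obs=obs, var=var)


@pytest.fixture
def adata_builder():
    return make_adata
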