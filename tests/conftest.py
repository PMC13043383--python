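import warnings

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from coelomyx import simdata

warnings.filterwarnings("ignore", message=".*fragmented.*")


def make_adata(X, clusters=None, samples=None, conditions=None, gene_names=None):
    """Small AnnData builder for hand-crafted fixtures."""
    X = np.asarray(X)
    n, g = X.shape
    obs = pd.DataFrame(index=[f"c{i}" for i in range(n)])
    obs["cluster"] = clusters if clusters is not None else "cl0"
    obs["sample"] = samples if samples is not None else "s1"
    obs["condition"] = conditions if conditions is not None else "control"
    var = pd.DataFrame(index=gene_names or [f"g{j}" for j in range(g)])
    return ad.AnnData(X=sp.csr_matrix(X), obs=obs, var=var)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest seeded cohort with planted markers, DE genes and DC pairs."""
    model = simdata.default_latent_model(n_genes=120, seed=11)
    design = simdata.CohortDesign(n_cells_per_sample=300, seed=11)
    adata, cells, truth = simdata.simulate_single_cell_cohort(design, model)
    return adata, cells, truth
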