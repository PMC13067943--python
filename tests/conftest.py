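import numpy as np
import pandas as pd
import pytest
from anndata import AnnData
from hypothesis import HealthCheck, settings
from scipy import sparse

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def small_if_cohort():
    """Three-patient IF cohort with extreme/intermediate DLL3 fractions."""
    from ctcdll3 import synth
    params = synth.IFCohortParams(
        n_patients=3, dll3_fraction=[0.0, 0.5, 0.9], ctc_abundance=250.0,
        seed=7)
    events, truth = synth.simulate_if_cohort(params)
    return params, events, truth


@pytest.fixture
def small_counts():
    """Small tumor/reference count matrix with default parameters."""
    from ctcdll3 import synth
    params = synth.SCCountParams(
        n_cells={"tumor": 300, "reference": 150}, n_genes=800, seed=13)
    adata, truth = synth.simulate_counts(params)
    return params, adata, truth


def make_adata(counts: np.ndarray, gene_names=None, cell_names=None,
               var_extra=None) -> AnnData:
    """Dense counts (cells x genes) -> AnnData with optional annotation."""
    n_cells, n_genes = counts.shape
    gene_names = list(gene_names) if gene_names is not None else \
        [f"G{j:04d}" for j in range(n_genes)]
    cell_names = list(cell_names) if cell_names is not None else \
        [f"C{i:04d}" for i in range(n_cells)]
    var = pd.DataFrame(index=pd.Index(gene_names, name="gene"))
    if var_extra:
        for key, vals in var_extra.items():
            var[key] = vals
    return AnnData(X=sparse.csr_matrix(np.asarray(counts)),
                   obs=pd.DataFrame(index=cell_names), var=var)
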