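import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from limbdual import SimConfig, log_normalize, simulate_counts


def make_adata(counts, genes=None, barcodes=None, normalize=True):
    """AnnData from a dense cells x genes count array, optionally with the
    log-normalized layer attached."""
    counts = np.asarray(counts, dtype=np.int64)
    n_cells, n_genes = counts.shape
    genes = list(genes) if genes is not None else [f"G{i}" for i in range(n_genes)]
    barcodes = list(barcodes) if barcodes is not None else [f"C{i:04d}" for i in range(n_cells)]
    adata = ad.AnnData(
        X=sparse.csr_matrix(counts),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene_id")),
    )
    if normalize:
        log_normalize(adata)
    return adata


def small_sim_config(seed=7, **overrides):
    """A fast, reduced-scale simulator configuration for unit tests."""
    base = dict(
        n_cells_per_population={"CT": 400, "M": 400, "OTHER_1": 250},
        n_genes_total=400,
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    """One small simulated dataset with doublets and transitional cells."""
    return simulate_counts(small_sim_config())
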