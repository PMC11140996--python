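import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
import anndata as ad

from ctxneu.simulate import SyntheticDesign, GeneProgram, CnvSegment, default_design, generate_dataset


def make_adata(counts, chromosomes=None, positions=None, mito=None, **obs_cols):
    """Hand-built AnnData from a dense count array (cells x genes)."""
    counts = np.asarray(counts, dtype=np.int64)
    n_cells, n_genes = counts.shape
    var = pd.DataFrame(
        {
            "chromosome": chromosomes if chromosomes is not None else ["chr1"] * n_genes,
            "start_position": positions if positions is not None else np.arange(1, n_genes + 1) * 1000,
            "is_mitochondrial": mito if mito is not None else [False] * n_genes,
        },
        index=pd.Index([f"G{i:04d}" for i in range(n_genes)], name="gene_id"),
    )
    obs = pd.DataFrame(
        {k: v for k, v in obs_cols.items()},
        index=pd.Index([f"C{i:04d}" for i in range(n_cells)], name="cell_id"),
    )
    return ad.AnnData(X=sp.csr_matrix(counts), obs=obs, var=var)


@pytest.fixture(scope="session")
def default_dataset():
    """One realisation of the default multi-tissue study design."""
    return generate_dataset(default_design(seed=11))


@pytest.fixture(scope="session")
def clean_dataset():
    """Default design without doublets or damaged cells (pure-signal variant)."""
    return generate_dataset(default_design(seed=12, doublet_rate=0.0, mito_high_fraction=0.0))
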