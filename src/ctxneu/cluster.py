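"""Delegating clustering stage: HVG selection, PCA, kNN graph and Leiden
community detection via scanpy. Deliberately thin — the bespoke analyses
consume its labels; nothing here is re-implemented."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp

__all__ = ["ClusterAssignment", "cluster_cells"]


@dataclass
class ClusterAssignment:
    """Per-cell cluster labels plus the parameter record that produced them."""

    labels: pd.Series
    parameters: dict

    @property
    def n_clusters(self) -> int:
        return self.labels.nunique()


def cluster_cells(
    adata: ad.AnnData,
    n_hvg: int = 2000,
    n_pcs: int = 30,
    resolution: float = 0.8,
    k_neighbors: int = 15,
    seed: int = 0,
) -> ClusterAssignment:
    """Graph-based clustering of QC-passing cells; deterministic given seed."""
    if adata.n_obs <= n_pcs:
        raise ValueError(f"need more than n_pcs={n_pcs} cells, got {adata.n_obs}")
    work = ad.AnnData(
        X=sp.csr_matrix(adata.X, dtype=np.float64),
        obs=adata.obs[[]].copy(),
        var=adata.var[[]].copy(),
    )
    sc.pp.normalize_total(work, target_sum=1e4)
    sc.pp.log1p(work)
    if np.allclose(work.X.toarray().std(axis=0), 0):
        # all cells identical: no variable gene, one cluster
        labels = pd.Series(["0"] * adata.n_obs, index=adata.obs_names, name="cluster")
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sc.pp.highly_variable_genes(work, n_top_genes=min(n_hvg, work.n_vars), flavor="seurat")
        work = work[:, work.var["highly_variable"]].copy()
        n_comp = min(n_pcs, work.n_obs - 1, work.n_vars - 1)
        sc.pp.pca(work, n_comps=n_comp, random_state=seed)
        sc.pp.neighbors(work, n_neighbors=min(k_neighbors, work.n_obs - 1), random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sc.tl.leiden(
                work, resolution=resolution, random_state=seed,
                flavor="leidenalg", key_added="cluster",
            )
        labels = pd.Series(
            work.obs["cluster"].astype(str).to_numpy(), index=adata.obs_names, name="cluster"
        )
    return ClusterAssignment(
        labels=labels,
        parameters={
            "n_hvg": n_hvg,
            "n_pcs": n_pcs,
            "resolution": resolution,
            "k_neighbors": k_neighbors,
            "seed": seed,
        },
    )
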